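# vtbind

Modelling and analysis tools for **visuotactile temporal binding**: how the
brain decides whether what it sees and what it feels belong together — the
computational question behind the rubber hand illusion and visuotactile
simultaneity judgments.

The package implements, as a reusable and fully testable pipeline:

- **A Bayesian causal inference (BCI) observer model.** On each trial with a
  signed visuotactile asynchrony *s* (ms), the observer draws a noisy
  measurement *x* ~ N(*s*, σ²) and infers whether vision and touch share a
  common cause (*C* = 1, true asynchrony 0) or separate causes (*C* = 2,
  *s* ~ N(0, σₛ²) with a fixed stimulus SD σₛ). With prior *p*(C = 1) =
  *p*_same, the observer reports "yes" exactly when |*x*| < √K, where

  K = σ²(σₛ² + σ²)/σₛ² · [ 2 log(*p*_same/(1 − *p*_same)) + log((σₛ² + σ²)/σ²) ]

  so the predicted yes-probability at asynchrony *s*, with lapse rate λ, is

  p(yes | s) = 0.5 λ + (1 − λ)[Φ((k − s)/σ) − Φ((−k − s)/σ)],  k = √K.

  Fitting is bounded multistart maximum likelihood (statsmodels-style:
  `BCIModel(trials, sigma_s).fit()` returns a `BCIResults` with estimates,
  pseudo-R², AIC/BIC and a `summary()`), with condition-varying variants
  (σ per stimulation condition, or *p*_same per task × condition) compared
  by summed ΔAIC/ΔBIC with a bootstrap confidence interval.
- **Psychophysical measures.** The temporal binding window (TBW) as the SD
  of a scaled Gaussian fitted to yes-proportions; signal-detection
  sensitivity d′ = z(H) − z(FA) and bias = −0.5(z(H) + z(FA)) per collapsed
  |asynchrony| with half-trial padding; and the area under the d′ curve.
- **Individual alpha frequency (IAF).** Welch spectra (6-s Hann windows,
  50% overlap, ≤0.167 Hz bins), relative alpha power, classic peak-picking
  and an aperiodic-corrected (1/f-subtracted) peak estimate with ROI
  averaging.
- **Synthetic observers, cohorts and EEG** with known ground truth,
  including a cohort generator that couples sensory noise σ to alpha
  frequency so the whole pipeline can be validated end to end.
- **Small inferential utilities**: Pearson/Spearman correlations and the
  Fisher-z sample-size calculation for a correlation.

## Worked example

```python
import vtbind as v
import pandas as pd

# simulate one participant of the EEG experiment (both tasks, 45
# trials/block, 3 blocks per task) from a known observer
obs = v.BCIObserver(p_same_own=0.8, p_same_sim=0.6, sigma=150, lapse=0.02)
tabs = []
for task in ("ownership", "simultaneity"):
    design = v.build_design("E2", task)
    trials = v.enumerate_trials(design, seed=1)
    tabs.append(v.simulate_bci_responses(obs, trials, seed=2))
trials = pd.concat(tabs, ignore_index=True)

res = v.fit_bci(trials, sigma_s=293.0, n_starts=100, seed=0)
print(res.summary())
```

prints

```
Bayesian causal inference observer fit
==============================================
variant: single         sigma_s: 293 ms
n_trial: 270            n_par:   4
logL:    -127.824       pseudo-R2: 0.4741
AIC:     263.65         BIC:     278.04
starts:  100 (best: #89, converged: True)
----------------------------------------------
p_same_own                 0.8505
p_same_sim                 0.6578
sigma                    125.5273 ms
lapse                      0.0405
```

The fitted common-cause priors sit near their generating values (0.85 vs
0.8 for ownership, 0.66 vs 0.6 for simultaneity), the sensory noise
estimate (126 ms vs 150 ms generating) reflects the sampling error expected
at 270 binary trials, and the pseudo-R² of 0.47 says the model explains
about half of the attainable likelihood improvement over a coin-flip null —
typical for a stochastic observer at these trial counts.

The decision threshold itself is available directly:

```python
>>> v.decision_threshold(0.5, 290.0, 290.0).k
341.449  # ms; equals 290 * sqrt(2 ln 2) for an even prior and sigma = sigma_s
```

A command-line interface mirrors the library
(`vtbind design / simulate / psychofit / bcifit / compare / iaf / recover /
end-to-end`); every subcommand reads and writes plain CSV/YAML.

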