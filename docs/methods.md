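# Methods

## The causal-inference observer

The generative model has three variables: the causal category *C* (common
cause vs. separate causes), the physical visuotactile asynchrony *s* (ms),
and the observer's internal measurement *x*. Under *C* = 1 the true
asynchrony is 0; under *C* = 2 it is drawn from N(0, σₛ²), where σₛ is a
fixed property of the stimulus set (293 ms for the E2 designs, 290 ms for
E3). The measurement is *x* ~ N(*s*, σ²) with sensory noise σ shared
between the ownership and simultaneity tasks (the stimulation is the same;
only the judgment differs). The observer reports "yes" (common cause) when
the posterior log-odds of *C* = 1 are positive, which reduces to
|*x*| < √K with

    K = σ²(σₛ² + σ²)/σₛ² · (2 log(p_same/(1 − p_same)) + log((σₛ² + σ²)/σ²)).

When the bracketed term is non-positive (a sufficiently low common-cause
prior), no measurement favours *C* = 1: the threshold is *undefined* and
the model predicts yes only through lapses. This is a valid parameter
state, not an error, and the simulator and the predicted psychometric
function handle it identically (`predict_p_yes` returns 0.5 λ).

The predicted yes-probability is the probability mass of N(*s*, σ²) inside
(−k, k), mixed with a fair-coin lapse:

    p(yes | s) = 0.5 λ + (1 − λ)[Φ((k − s)/σ) − Φ((−k − s)/σ)].

This is even in *s*, nonincreasing in |*s*|, and bounded in
[0.5 λ, 1 − 0.5 λ]. A published rendering of this equation writes the
bracket as Φ(s; k, σ²) − Φ(s; −k, σ²), which is negative under the usual
reading of Φ(·; mean, variance); the form above is the one consistent with
the decision rule and with the posterior-equality point, and the test suite
verifies it against both a Monte-Carlo simulator and a numerical solve of
the posterior log-odds.

σₛ is stored as an opaque constant. It does not equal the SD of a uniform
draw over the printed asynchrony grids (e.g. the E2 grid would give
≈258 ms), so it is never recomputed from a design.

### Fitting

`BCIModel` aggregates trials into (task, condition, level) cells and
maximizes the binomial log-likelihood with L-BFGS-B (analytic gradient,
differentiated through the threshold k; verified against numerical
differentiation in the tests) restarted from 100 uniform draws within
bounds (default bounds: p_same ∈ [0.001, 0.999],
σ ∈ [1, 1000] ms, λ ∈ [0, 0.3]); the best restart wins and the count plus
winning start index are recorded in the results object. Predicted
probabilities are clamped to [1e−9, 1 − 1e−9] so λ = 0 fits remain finite.
Three parameterisations are supported: `single` (p_same per task, one σ,
one λ; 4 parameters), `sigma_varies` (σ per stimulation condition, shared
p_same and λ; 6), and `psame_varies` (p_same per task × condition, shared σ
and λ; 8). When a trial table contains only one task, the unused prior is
dropped rather than left unidentifiable (a single-task fit has 3
parameters).

Goodness of fit is the likelihood-based R² against a fair-coin null,
normalized by its maximum attainable value given the null likelihood, and
clipped to [0, 1]. Model comparison uses AIC = 2·n_par − 2 log L* and
BIC = n_par·log(n_trial) − 2 log L*. One published rendering of the BIC
swaps n_par and n_trial in the penalty; `bic(..., exact_printed_form=True)`
reproduces that variant, but the standard form is the default. Summed
participant-level ΔAIC/ΔBIC get a percentile bootstrap CI (10,000 resamples
of `resample_size` differences with replacement; `resample_size` defaults
to the cohort size, and can be set to smaller values such as 15 to match
bootstrap conventions that subsample the cohort).

### Identifiability at realistic trial counts

At the E2 design's printed numbers (15 trials per level per task, 270
trials per participant) the 4-parameter model has a pronounced likelihood
ridge along which a higher lapse trades off against higher p_same and lower
σ: the tested grid (±400 ms) does not reach far enough into the tails for
the lapse to be pinned independently. A Fisher-information calculation at
a representative observer (p_same = 0.8/0.6, σ = 150 ms, λ = 0.02) gives
asymptotic SDs of roughly 0.12–0.18 for the priors, ~37 ms for σ and ~0.13
for λ. Parameter-recovery studies at these counts therefore show
substantial spread — this is a property of the design, not of the
optimizer (in failing replicates the likelihood at the estimate exceeds the
likelihood at the generating parameters). Tight recovery (priors to
±0.05, σ to a few percent) requires on the order of 200 trials per level.
The acceptance studies report recovery rates at the printed counts as
measured.

## Psychophysical measures

The **temporal binding window** is the SD of p(s) = A·exp(−(s − μ)²/2sd²)
fitted to yes-proportions by unweighted least squares (trust-region
reflective with analytic Jacobian, 20 seeded restarts plus a moment-based
start; bounds A ∈ (0, 1], μ within the level range, sd ∈ [1, 2000] ms).
The amplitude is free: yes-rates at true synchrony rarely reach 1, and
pinning A at 1 (or at the observed maximum) biases the width. A flat curve
leaves the width unidentifiable; the fit is then flagged unconverged with
sd pinned at the bound. R² is reported on the proportions.

**Signal detection**: 0-ms trials are signal, each collapsed |s| > 0 a
noise level; ± levels are pooled by summing counts (not by averaging two
d′ values). Rates of exactly 0 or 1 are padded by half a trial
(0 → 0.5/n, n → (n − 0.5)/n); interior rates are untouched. z is the
exact inverse normal CDF. The AUC of d′ over |s| is a plain trapezoid and
is deliberately not normalized by the asynchrony span — it is used for
rank/linear correlations, where scale is immaterial.

## Spectral analysis and IAF

`welch_psd` uses Hann-tapered segments of 6 s with 50% overlap, zero-padded
so the bin spacing is at most 0.167 Hz; signals shorter than one window
(e.g. 1-s task epochs) are zero-padded to the window length and analyzed
as a single segment. Relative alpha power is the 8–13 Hz sum over the
total-range sum, invariant under signal rescaling.

Two IAF estimators:

- *classic*: argmax of raw power in the band, ties to the lower frequency.
  A band-edge argmax that is not a local maximum of the full spectrum is
  flagged unsuccessful — on a peakless 1/f background the band maximum is
  always the lower edge, and reporting 8 Hz as an "alpha peak" would be an
  artifact.
- *aperiodic-corrected*: a least-squares line in log10 power vs. log10
  frequency over 3–40 Hz, excluding 7–14 Hz (so the alpha bump cannot tilt
  the background estimate), is subtracted; the IAF is the largest residual
  local maximum in the band with prominence ≥ 0.1 log10 units (1 dB), with
  parabolic interpolation around the winning bin for sub-bin precision.
  When nothing clears the prominence floor the estimate reports failure —
  expected for a genuine fraction of recordings. This deliberately
  replaces a full spectral-parameterisation mixture model: for peak
  *location* over smooth 1/f backgrounds the linear fit is sufficient, and
  its recovery is validated directly (injected exponents recovered to
  ±0.1; injected peaks to well under 0.2 Hz).

A z-scored decibel transform (10·log10 then z over bins) is provided for
normalized reporting only; peak picking never depends on it, since peak
locations are invariant to monotone per-spectrum transforms. ROI
aggregation averages the successful per-electrode peak frequencies.

## Synthetic data

The generators define the conditions under which every validation study
runs:

- **Designs**: the four printed asynchrony grids with their repetition and
  block structure (36, 180, 45 and 35 trials per block); trial order is a
  uniform permutation within block, deterministic per seed. Inter-tap
  jitter ranges are recorded as metadata but have no computational role.
- **BCI observer**: defaults p_same_own = 0.8, p_same_sim = 0.6,
  σ = 150 ms, λ = 0.02 — a mid-range plausible observer for this paradigm
  (clear illusion at synchrony, laxer ownership than simultaneity prior,
  noise well inside the tested ±400 ms range, near-zero guessing). Lapses
  replace the decision with a fair coin, matching the 0.5 λ term.
- **Cohorts**: participant parameters drawn uniformly from
  p_same_own ∈ [0.55, 0.95], p_same_sim ∈ [0.3, 0.9], σ ∈ [60, 350] ms,
  λ ∈ [0, 0.1], alpha ∈ [8.5, 12.5] Hz. The optional IAF link replaces the
  σ draw with σ = 490 − 30·alpha + N(0, 20) ms (truncated positive): a
  ~1 Hz alpha advantage buys ~30 ms less sensory noise, spanning roughly
  115–235 ms over the alpha range — a moderate, plausible coupling whose
  magnitude is a fixture choice, not an empirical claim. The stimulation
  cohort scales σ by 1.25 (low), 1.0 (sham) and 0.8 (high) with constant
  priors, making the σ-varying model variant the ground truth.
- **EEG**: an alpha sinusoid (amplitude 0.7, random phase) over a 1/f
  background realized by spectrally shaping white noise (one-sided PSD
  10^offset/f^exponent, defaults offset 0, exponent 1), plus white sensor
  noise (SD 0.1), 240 s at 512 Hz — mimicking a preprocessed resting-state
  recording with a conspicuous alpha peak. What it does *not* emulate:
  nonstationarity, artifacts, multichannel covariance, harmonics, or peak
  width variation. Passing IAF tests therefore demonstrate correctness of
  the spectral pipeline, not robustness to messy real recordings.

All simulators are deterministic given their inputs and a seed.

## Correlation utilities

Pearson and Spearman (Pearson on average ranks) coefficients with
two-sided p-values from the exact t transform on n − 2 df. The sample-size
calculation inverts the bias-corrected Fisher-z power function (critical r
from the t distribution; z_r = atanh r + r/(2(n − 1)); SD 1/√(n − 3)) and
returns the smallest n reaching the target power — the standard
power-software convention, giving n = 29 for ρ = 0.5, α = 0.05 two-sided,
power 0.80. The repeated-measures ANOVA power analysis used for the
stimulation experiment's sample size depends on unprinted assumptions
(measure correlations, nonsphericity) and is intentionally not provided.

## Problem sizes in the validation studies

The test suite and `scripts/acceptance.py` size their simulations for a
few minutes of total runtime on one core: Monte-Carlo model/simulator
consistency uses 20,000 trials per level over 5 random parameter sets;
parameter recovery runs 50 replicates at the printed E2 trial counts with
100 optimizer starts; model selection runs cohorts of 15 stimulation
participants (5 replicates in the script, 10 in the test suite) with both
variants at 100 starts; the end-to-end study runs cohorts of 46 with 10
optimizer starts per fit (the 4-parameter surface is smooth enough that
further restarts change nothing at the reported precision), 50 seeds in
the test suite and 12 in the script.

## Known limitations

- The observer model assumes a single shared σ per condition and symmetric
  measurement noise; asymmetries (order effects between rubber-hand-first
  and hand-first asynchronies) are not representable.
- The aperiodic correction is a straight line in log-log space; strongly
  curved (knee-type) backgrounds would bias it, though peak *location* is
  fairly insensitive.
- The bootstrap CI for summed information-criterion differences resamples
  participants with replacement and inherits the usual percentile-bootstrap
  small-sample caveats.
- Group-level inference (ANOVAs, post-hoc corrections) is out of scope;
  only correlation utilities are provided.
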