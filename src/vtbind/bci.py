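"""Bayesian causal inference (BCI) observer model of visuotactile binding.

The observer measures the signed visuotactile asynchrony ``s`` (ms) with
Gaussian noise, ``x ~ N(s, sigma^2)``, and infers whether vision and touch
share a common cause (C = 1, in which case the true asynchrony is 0) or
arise from separate causes (C = 2, in which case ``s ~ N(0, sigma_s^2)``
with the fixed stimulus SD ``sigma_s``). The prior probability of a common
cause, ``p_same``, is task specific (ownership vs. simultaneity). The
posterior log-odds of C = 1 exceed zero exactly when ``|x| < sqrt(K)`` with

    K = sigma^2 (sigma_s^2 + sigma^2) / sigma_s^2
        * ( 2 log(p_same / (1 - p_same)) + log((sigma_s^2 + sigma^2) / sigma^2) )

so the predicted probability of a "yes" (common-cause) report at
asynchrony ``s``, with lapse rate ``lambda``, is

    p(yes | s) = 0.5 lambda + (1 - lambda) [ Phi((k - s)/sigma) - Phi((-k - s)/sigma) ]

where ``k = sqrt(K)`` (and the bracket is 0 when K <= 0: the prior is so
low that a common cause is never the maximum-a-posteriori report).

Fitting follows a statsmodels-like pattern: build a :class:`BCIModel` from
a trial table, call :meth:`BCIModel.fit` (bounded multistart maximum
likelihood), and read estimates, pseudo-R^2, AIC/BIC and a ``summary()``
off the returned :class:`BCIResults`.

Three variants are supported, mirroring the tACS analysis:

``single``        one sigma, one p_same per task (4 parameters)
``sigma_varies``  sigma differs by stimulation condition (6 parameters)
``psame_varies``  p_same differs by task x condition (8 parameters)

In both variants the lapse rate is shared, and the parameters not keyed by
condition are shared across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr

__all__ = [
    "BCIParams",
    "BCIModel",
    "BCIResults",
    "ComparisonResult",
    "DecisionThreshold",
    "FitError",
    "aic",
    "bic",
    "compare_models",
    "decision_threshold",
    "fit_bci",
    "log_likelihood",
    "predict_p_yes",
    "pseudo_r2",
]

_EPS = 1e-9  # likelihood clamp; keeps lapse = 0 fits finite

DEFAULT_BOUNDS = {
    "p_same": (1e-3, 1 - 1e-3),
    "sigma": (1.0, 1000.0),
    "lapse": (0.0, 0.3),
}

VARIANTS = ("single", "sigma_varies", "psame_varies")
_TACS_CONDITIONS = ("low", "sham", "high")


@dataclass(frozen=True)
class BCIParams:
    """Single-condition observer parameters (the 4-parameter model)."""

    p_same_own: float
    p_same_sim: float
    sigma: float
    lapse: float

    def __post_init__(self) -> None:
        for p in (self.p_same_own, self.p_same_sim):
            if not 0.0 < p < 1.0:
                raise ValueError("p_same must lie strictly in (0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must lie in [0, 1]")

    def p_same(self, task: str) -> float:
        return self.p_same_own if task == "ownership" else self.p_same_sim


@dataclass(frozen=True)
class DecisionThreshold:
    """Decision boundary on |x| for reporting a common cause."""

    K: float
    defined: bool

    @property
    def k(self) -> float:
        """sqrt(K) in ms; NaN when the threshold is undefined (K <= 0)."""
        return float(np.sqrt(self.K)) if self.defined else float("nan")


def decision_threshold(p_same: float, sigma: float, sigma_s: float) -> DecisionThreshold:
    """Squared decision threshold K for the common-cause report.

    ``defined`` is False when the bracketed log-odds term is <= 0, i.e. the
    common-cause prior is so low that no measurement makes C = 1 the
    maximum-a-posteriori category.
    """
    if not 0.0 < p_same < 1.0:
        raise ValueError("p_same must lie strictly in (0, 1)")
    if sigma <= 0 or sigma_s <= 0:
        raise ValueError("sigma and sigma_s must be positive")
    v, vs = sigma**2, sigma_s**2
    K = v * (vs + v) / vs * (2.0 * np.log(p_same / (1.0 - p_same)) + np.log((vs + v) / v))
    return DecisionThreshold(K=float(K), defined=K > 0)


def _p_yes(s, p_same, sigma, lapse, sigma_s):
    """Vectorized predicted yes-probability; all inputs broadcastable."""
    s = np.asarray(s, dtype=float)
    p_same = np.asarray(p_same, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    v, vs = sigma**2, sigma_s**2
    K = v * (vs + v) / vs * (2.0 * np.log(p_same / (1.0 - p_same)) + np.log((vs + v) / v))
    k = np.sqrt(np.maximum(K, 0.0))
    inside = ndtr((k - s) / sigma) - ndtr((-k - s) / sigma)
    inside = np.where(K > 0, inside, 0.0)
    return 0.5 * lapse + (1.0 - lapse) * inside


def predict_p_yes(
    s,
    params: BCIParams,
    task: str,
    sigma_s: float,
    condition: str = "none",
) -> np.ndarray | float:
    """Predicted probability of a common-cause ("yes") report at asynchrony s.

    ``condition`` is accepted for interface symmetry with the condition-keyed
    variants; a plain :class:`BCIParams` observer ignores it.
    """
    out = _p_yes(s, params.p_same(task), params.sigma, params.lapse, sigma_s)
    return float(out) if np.ndim(s) == 0 else out


# ---------------------------------------------------------------------------
# goodness of fit and information criteria


def pseudo_r2(logL: float, n_trial: int) -> float:
    """Likelihood-based R^2 against a fair-coin null, normalized by its max.

    R^2 = 1 - exp(-(2/n)(logL - logL0)) with logL0 = n log 0.5, divided by
    max(R^2) = 1 - exp((2/n) logL0). Equals 0 at chance and 1 for perfect
    prediction of binary responses.
    """
    if n_trial <= 0:
        raise ValueError("n_trial must be positive")
    logL0 = n_trial * np.log(0.5)
    r2 = 1.0 - np.exp(-2.0 / n_trial * (logL - logL0))
    r2_max = 1.0 - np.exp(2.0 / n_trial * logL0)
    return float(np.clip(r2 / r2_max, 0.0, 1.0))


def aic(logL: float, n_par: int) -> float:
    """Akaike information criterion 2 n_par - 2 logL."""
    if n_par < 1:
        raise ValueError("n_par must be >= 1")
    return 2.0 * n_par - 2.0 * logL


def bic(logL: float, n_par: int, n_trial: int, exact_printed_form: bool = False) -> float:
    """Bayesian information criterion n_par log(n_trial) - 2 logL.

    ``exact_printed_form`` swaps the roles of n_par and n_trial in the
    penalty (n_trial log n_par), a nonstandard variant kept for
    reproducibility of one published formula rendering.
    """
    if n_par < 1 or n_trial < 1:
        raise ValueError("n_par and n_trial must be >= 1")
    if exact_printed_form:
        return n_trial * np.log(n_par) - 2.0 * logL
    return n_par * np.log(n_trial) - 2.0 * logL


# ---------------------------------------------------------------------------
# the model


class FitError(RuntimeError):
    """All optimizer starts failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class BCIModel:
    """Causal-inference observer model bound to one participant's trials.

    Parameters
    ----------
    trials : DataFrame
        Trial table with columns ``task``, ``asynchrony_ms``, ``condition``
        and ``response`` ("yes"/"no"; "missing" rows are dropped).
    sigma_s : float
        Fixed stimulus-distribution SD in ms (e.g. 293 for the EEG
        experiment, 290 for the tACS experiment).
    variant : {"single", "sigma_varies", "psame_varies"}
        Which parameters are allowed to differ across stimulation
        conditions.
    lapse_max : float
        Upper bound of the lapse rate during fitting.
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        sigma_s: float,
        variant: str = "single",
        lapse_max: float = DEFAULT_BOUNDS["lapse"][1],
        bounds: dict | None = None,
    ):
        if variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if sigma_s <= 0:
            raise ValueError("sigma_s must be positive")
        self.sigma_s = float(sigma_s)
        self.variant = variant
        self.bounds_spec = dict(DEFAULT_BOUNDS)
        if bounds:
            self.bounds_spec.update(bounds)
        self.bounds_spec["lapse"] = (self.bounds_spec["lapse"][0], lapse_max)

        df = trials[trials["response"].isin(["yes", "no"])]
        if df.empty:
            raise ValueError("no answered trials")
        self.tasks = tuple(sorted(df["task"].unique()))
        conds = tuple(c for c in _TACS_CONDITIONS if c in set(df["condition"]))
        if not conds:
            conds = tuple(sorted(df["condition"].unique()))
        self.conditions = conds
        if variant != "single" and len(self.conditions) < 2:
            raise ValueError(f"variant {variant!r} needs >= 2 conditions")

        grouped = (
            df.assign(yes=(df["response"] == "yes").astype(int))
            .groupby(["task", "condition", "asynchrony_ms"], sort=True)
            .agg(n=("yes", "size"), n_yes=("yes", "sum"))
            .reset_index()
        )
        self._s = grouped["asynchrony_ms"].to_numpy(float)
        self._n = grouped["n"].to_numpy(float)
        self._n_yes = grouped["n_yes"].to_numpy(float)
        self._task_idx = np.array([self.tasks.index(t) for t in grouped["task"]])
        self._cond_idx = np.array(
            [self.conditions.index(c) for c in grouped["condition"]]
        )
        self.n_trial = int(self._n.sum())
        self.param_names = self._build_param_names()
        self._psame_idx, self._sigma_idx = self._build_theta_maps()

    # -- parameterisation ---------------------------------------------------

    def _build_param_names(self) -> list[str]:
        names: list[str] = []
        short = {"ownership": "own", "simultaneity": "sim"}
        if self.variant == "psame_varies":
            for t in self.tasks:
                for c in self.conditions:
                    names.append(f"p_same_{short.get(t, t)}_{c}")
        else:
            for t in self.tasks:
                names.append(f"p_same_{short.get(t, t)}")
        if self.variant == "sigma_varies":
            for c in self.conditions:
                names.append(f"sigma_{c}")
        else:
            names.append("sigma")
        names.append("lapse")
        return names

    @property
    def n_par(self) -> int:
        return len(self.param_names)

    def bounds(self) -> list[tuple[float, float]]:
        out = []
        for name in self.param_names:
            key = "p_same" if name.startswith("p_same") else (
                "sigma" if name.startswith("sigma") else "lapse"
            )
            out.append(self.bounds_spec[key])
        return out

    def _build_theta_maps(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell indices into the parameter vector for p_same and sigma."""
        names = self.param_names
        short = {"ownership": "own", "simultaneity": "sim"}
        psame_idx = np.empty(len(self._s), dtype=int)
        sigma_idx = np.empty(len(self._s), dtype=int)
        for cell in range(len(self._s)):
            t = self.tasks[self._task_idx[cell]]
            c = self.conditions[self._cond_idx[cell]]
            if self.variant == "psame_varies":
                psame_idx[cell] = names.index(f"p_same_{short.get(t, t)}_{c}")
            else:
                psame_idx[cell] = names.index(f"p_same_{short.get(t, t)}")
            if self.variant == "sigma_varies":
                sigma_idx[cell] = names.index(f"sigma_{c}")
            else:
                sigma_idx[cell] = names.index("sigma")
        return psame_idx, sigma_idx

    def _cell_params(self, theta: np.ndarray):
        """Map a parameter vector to per-cell (p_same, sigma, lapse)."""
        return theta[self._psame_idx], theta[self._sigma_idx], theta[-1]

    # -- likelihood ---------------------------------------------------------

    def loglike(self, theta: Sequence[float]) -> float:
        """Binomial log-likelihood of the aggregated trial counts."""
        theta = np.asarray(theta, dtype=float)
        p_same, sigma, lapse = self._cell_params(theta)
        p = np.clip(_p_yes(self._s, p_same, sigma, lapse, self.sigma_s), _EPS, 1 - _EPS)
        return float(
            np.sum(self._n_yes * np.log(p) + (self._n - self._n_yes) * np.log1p(-p))
        )

    def loglike_and_grad(self, theta: Sequence[float]) -> tuple[float, np.ndarray]:
        """Log-likelihood and its analytic gradient in the parameter vector.

        Differentiates p(yes|s) = 0.5 lapse + (1 - lapse) [Phi(a) - Phi(b)],
        a = (k - s)/sigma, b = (-k - s)/sigma, through the threshold
        k = sqrt(K(p_same, sigma)). Cells with K <= 0 contribute only
        through the lapse term.
        """
        theta = np.asarray(theta, dtype=float)
        p_same, sigma, lapse = self._cell_params(theta)
        p_same = np.broadcast_to(np.asarray(p_same, float), self._s.shape)
        sigma = np.broadcast_to(np.asarray(sigma, float), self._s.shape)
        s = self._s
        v, vs = sigma**2, self.sigma_s**2
        A = v * (vs + v) / vs
        B = 2.0 * np.log(p_same / (1.0 - p_same)) + np.log((vs + v) / v)
        K = A * B
        defined = K > 0
        k = np.sqrt(np.where(defined, K, 1.0))
        a = (k - s) / sigma
        b = (-k - s) / sigma
        inside = np.where(defined, ndtr(a) - ndtr(b), 0.0)
        p_raw = 0.5 * lapse + (1.0 - lapse) * inside
        p = np.clip(p_raw, _EPS, 1 - _EPS)
        ll = float(np.sum(self._n_yes * np.log(p) + (self._n - self._n_yes) * np.log1p(-p)))

        # dLL/dp per cell (zero where the clip is active)
        g_cell = np.where(
            (p_raw > _EPS) & (p_raw < 1 - _EPS),
            self._n_yes / p - (self._n - self._n_yes) / (1.0 - p),
            0.0,
        )
        inv_sqrt2pi = 1.0 / np.sqrt(2.0 * np.pi)
        phi_a = inv_sqrt2pi * np.exp(-0.5 * a**2)
        phi_b = inv_sqrt2pi * np.exp(-0.5 * b**2)
        dp_dlapse = 0.5 - inside
        dp_dk = np.where(defined, (1.0 - lapse) * (phi_a + phi_b) / sigma, 0.0)
        dp_dsigma_fixed_k = np.where(
            defined,
            (1.0 - lapse) * (-phi_a * (k - s) - phi_b * (k + s)) / v,
            0.0,
        )
        dk_dK = np.where(defined, 0.5 / k, 0.0)
        dK_dpsame = A * 2.0 / (p_same * (1.0 - p_same))
        dA_dsigma = 2.0 * sigma * (vs + 2.0 * v) / vs
        dB_dsigma = 2.0 * sigma / (vs + v) - 2.0 / sigma
        dK_dsigma = dA_dsigma * B + A * dB_dsigma
        dp_dpsame = dp_dk * dk_dK * dK_dpsame
        dp_dsigma = dp_dsigma_fixed_k + dp_dk * dk_dK * dK_dsigma

        grad = np.zeros_like(theta)
        np.add.at(grad, self._psame_idx, g_cell * dp_dpsame)
        np.add.at(grad, self._sigma_idx, g_cell * dp_dsigma)
        grad[-1] = float(np.sum(g_cell * dp_dlapse))
        return ll, grad

    # -- fitting ------------------------------------------------------------

    def fit(self, n_starts: int = 100, seed: int = 0, method: str = "L-BFGS-B") -> "BCIResults":
        """Maximize the likelihood from ``n_starts`` seeded uniform starts."""
        bounds = np.asarray(self.bounds(), dtype=float)
        rng = np.random.default_rng(seed)

        def neg(th):
            ll, grad = self.loglike_and_grad(th)
            return -ll, -grad

        best = None
        best_start = -1
        failures = []
        for i in range(n_starts):
            x0 = rng.uniform(bounds[:, 0], bounds[:, 1])
            try:
                res = optimize.minimize(neg, x0, method=method, jac=True, bounds=bounds)
            except Exception as exc:  # pragma: no cover - optimizer blowups
                failures.append((i, repr(exc)))
                continue
            if not np.isfinite(res.fun):
                failures.append((i, "non-finite objective"))
                continue
            if best is None or res.fun < best.fun:
                best, best_start = res, i
        if best is None:
            raise FitError(
                f"all {n_starts} starts failed for variant {self.variant!r}",
                diagnostics=failures,
            )
        return BCIResults(self, best.x, -best.fun, n_starts, best_start, bool(best.success))


def fit_bci(
    trials: pd.DataFrame,
    sigma_s: float,
    variant: str = "single",
    n_starts: int = 100,
    seed: int = 0,
    lapse_max: float = DEFAULT_BOUNDS["lapse"][1],
    bounds: dict | None = None,
) -> "BCIResults":
    """Convenience wrapper: build a :class:`BCIModel` and fit it."""
    model = BCIModel(trials, sigma_s, variant=variant, lapse_max=lapse_max, bounds=bounds)
    return model.fit(n_starts=n_starts, seed=seed)


def log_likelihood(params: BCIParams, trials: pd.DataFrame, sigma_s: float) -> float:
    """Log-likelihood of a fixed single-condition observer on a trial table."""
    model = BCIModel(trials, sigma_s, variant="single")
    short = {"ownership": "own", "simultaneity": "sim"}
    theta = []
    for name in model.param_names:
        if name == "sigma":
            theta.append(params.sigma)
        elif name == "lapse":
            theta.append(params.lapse)
        else:
            task = "ownership" if name == f"p_same_{short['ownership']}" else "simultaneity"
            theta.append(params.p_same(task))
    return model.loglike(theta)


class BCIResults:
    """Maximum-likelihood fit of a :class:`BCIModel`.

    Attributes
    ----------
    params : dict
        Estimated parameters keyed by name (e.g. ``p_same_own``, ``sigma``,
        ``lapse``; condition-suffixed in the tACS variants).
    llf : float
        Maximized log-likelihood.
    r2 : float
        Normalized likelihood-based pseudo-R^2 against a fair-coin null.
    aic, bic : float
        Information criteria of the fit.
    """

    def __init__(self, model: BCIModel, theta, llf, n_starts, best_start, converged):
        self.model = model
        self.theta = np.asarray(theta, dtype=float)
        self.params = dict(zip(model.param_names, self.theta))
        self.llf = float(llf)
        self.n_par = model.n_par
        self.n_trial = model.n_trial
        self.n_starts = int(n_starts)
        self.best_start = int(best_start)
        self.converged = bool(converged)
        self.r2 = pseudo_r2(self.llf, self.n_trial)
        self.aic = aic(self.llf, self.n_par)
        self.bic = bic(self.llf, self.n_par, self.n_trial)

    def p_same(self, task: str, condition: str = "sham") -> float:
        short = {"ownership": "own", "simultaneity": "sim"}[task]
        if self.model.variant == "psame_varies":
            return self.params[f"p_same_{short}_{condition}"]
        return self.params[f"p_same_{short}"]

    def sigma(self, condition: str = "sham") -> float:
        if self.model.variant == "sigma_varies":
            return self.params[f"sigma_{condition}"]
        return self.params["sigma"]

    def predict(self, s, task: str, condition: str = "sham") -> np.ndarray:
        """Predicted yes-probabilities at asynchronies ``s``."""
        return _p_yes(
            s,
            self.p_same(task, condition),
            self.sigma(condition),
            self.params["lapse"],
            self.model.sigma_s,
        )

    def to_frame(self, participant: str = "") -> pd.DataFrame:
        row = {"participant": participant, "variant": self.model.variant}
        row.update(self.params)
        row.update(
            logL=self.llf, n_par=self.n_par, n_trial=self.n_trial,
            r2=self.r2, aic=self.aic, bic=self.bic,
        )
        return pd.DataFrame([row])

    def summary(self) -> str:
        lines = [
            "Bayesian causal inference observer fit",
            "=" * 46,
            f"variant: {self.model.variant:<14} sigma_s: {self.model.sigma_s:g} ms",
            f"n_trial: {self.n_trial:<14} n_par:   {self.n_par}",
            f"logL:    {self.llf:<14.3f} pseudo-R2: {self.r2:.4f}",
            f"AIC:     {self.aic:<14.2f} BIC:     {self.bic:.2f}",
            f"starts:  {self.n_starts} (best: #{self.best_start}, "
            f"converged: {self.converged})",
            "-" * 46,
        ]
        for name, val in self.params.items():
            unit = " ms" if name.startswith("sigma") else ""
            lines.append(f"{name:<20} {val:>12.4f}{unit}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<BCIResults variant={self.model.variant} llf={self.llf:.2f} "
            f"r2={self.r2:.3f}>"
        )


# ---------------------------------------------------------------------------
# model comparison


@dataclass
class ComparisonResult:
    """Summed AIC/BIC differences (sigma-variant minus p_same-variant).

    Negative sums favour the sigma-varying model. The 95% CI comes from a
    percentile bootstrap: ``resample_size`` participant-level differences
    drawn with replacement and summed, repeated ``n_boot`` times.
    """

    delta_aic: np.ndarray
    delta_bic: np.ndarray
    sum_delta_aic: float
    sum_delta_bic: float
    ci_aic: tuple[float, float]
    ci_bic: tuple[float, float]
    n_boot: int
    resample_size: int

    def summary(self) -> str:
        return (
            f"model comparison over {len(self.delta_aic)} participants "
            f"(bootstrap n={self.n_boot}, resample={self.resample_size})\n"
            f"  sum dAIC = {self.sum_delta_aic:10.2f}  "
            f"95% CI [{self.ci_aic[0]:.2f}, {self.ci_aic[1]:.2f}]\n"
            f"  sum dBIC = {self.sum_delta_bic:10.2f}  "
            f"95% CI [{self.ci_bic[0]:.2f}, {self.ci_bic[1]:.2f}]"
        )


def _boot_ci(deltas: np.ndarray, n_boot: int, resample_size: int, rng) -> tuple[float, float]:
    idx = rng.integers(0, len(deltas), size=(n_boot, resample_size))
    sums = deltas[idx].sum(axis=1)
    lo, hi = np.percentile(sums, [2.5, 97.5])
    return float(lo), float(hi)


def compare_models(
    fits_sigma: Sequence[BCIResults],
    fits_psame: Sequence[BCIResults],
    n_boot: int = 10_000,
    resample_size: int | None = None,
    seed: int = 0,
) -> ComparisonResult:
    """Compare the sigma-varying and p_same-varying variants across a cohort.

    ``fits_sigma`` and ``fits_psame`` must be paired by participant (same
    order, same length). ``resample_size`` defaults to the cohort size.
    """
    if len(fits_sigma) != len(fits_psame) or not fits_sigma:
        raise ValueError("fits must be non-empty and paired by participant")
    d_aic = np.array([a.aic - b.aic for a, b in zip(fits_sigma, fits_psame)])
    d_bic = np.array([a.bic - b.bic for a, b in zip(fits_sigma, fits_psame)])
    if resample_size is None:
        resample_size = len(d_aic)
    if n_boot < 1 or resample_size < 1:
        raise ValueError("n_boot and resample_size must be >= 1")
    rng = np.random.default_rng(seed)
    ci_a = _boot_ci(d_aic, n_boot, resample_size, rng)
    ci_b = _boot_ci(d_bic, n_boot, resample_size, rng)
    return ComparisonResult(
        delta_aic=d_aic,
        delta_bic=d_bic,
        sum_delta_aic=float(d_aic.sum()),
        sum_delta_bic=float(d_bic.sum()),
        ci_aic=ci_a,
        ci_bic=ci_b,
        n_boot=n_boot,
        resample_size=resample_size,
    )
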