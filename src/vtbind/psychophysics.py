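"""Behavioral measures: yes-proportion curves, Gaussian TBW, SDT, AUC of d'.

The temporal binding window (TBW) is defined as the standard deviation of a
scaled Gaussian, ``p(s) = A exp(-(s - mu)^2 / (2 sd^2))``, fitted by
unweighted least squares to the proportion of "yes" responses as a function
of the signed asynchrony. The amplitude A is left free (yes-rates at true
synchrony rarely reach 1, and pinning A biases the width estimate).

Signal-detection measures treat 0-ms trials as signal and each collapsed
|asynchrony| > 0 as a noise level: hits are "yes" at 0 ms, false alarms are
"yes" at the nonzero level, rates of exactly 0 or 1 are padded by half a
trial, and

    d'   =  z(H) - z(FA)
    bias = -0.5 (z(H) + z(FA))

with z the exact inverse standard-normal CDF. Sensitivity is summarized by
the trapezoidal area under d' versus |asynchrony| (AUC d', units d' * ms).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtri

__all__ = [
    "PsychometricFit",
    "PsychometricModel",
    "SDTTable",
    "auc_dprime",
    "fit_gaussian_tbw",
    "pad_rate",
    "proportion_yes",
    "sdt_by_asynchrony",
]

logger = logging.getLogger(__name__)

TBW_BOUNDS = {"amplitude": (1e-6, 1.0), "sd": (1.0, 2000.0)}


def proportion_yes(trials: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a trial table into a per-level yes-proportion curve.

    Returns a DataFrame with columns ``asynchrony_ms``, ``n``, ``n_yes``
    and ``p_yes`` sorted by level. Rows with response ``missing`` are
    dropped (count logged).
    """
    answered = trials[trials["response"].isin(["yes", "no"])]
    n_dropped = len(trials) - len(answered)
    if n_dropped:
        logger.info("proportion_yes: dropped %d unanswered trials", n_dropped)
    if answered.empty:
        return pd.DataFrame(columns=["asynchrony_ms", "n", "n_yes", "p_yes"])
    g = (
        answered.assign(yes=(answered["response"] == "yes").astype(int))
        .groupby("asynchrony_ms", sort=True)
        .agg(n=("yes", "size"), n_yes=("yes", "sum"))
        .reset_index()
    )
    g["p_yes"] = g["n_yes"] / g["n"]
    return g


@dataclass
class PsychometricFit:
    """Scaled-Gaussian fit; ``sd`` is the temporal binding window in ms."""

    amplitude: float
    mu: float
    sd: float
    r2: float
    converged: bool
    n_starts: int = 0

    @property
    def tbw(self) -> float:
        return self.sd

    def predict(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return self.amplitude * np.exp(-((s - self.mu) ** 2) / (2.0 * self.sd**2))

    def summary(self) -> str:
        return (
            "Gaussian psychometric fit\n"
            f"  amplitude {self.amplitude:8.4f}\n"
            f"  mu        {self.mu:8.2f} ms\n"
            f"  TBW (sd)  {self.sd:8.2f} ms\n"
            f"  R^2       {self.r2:8.4f}   converged: {self.converged}"
        )


class PsychometricModel:
    """Scaled-Gaussian psychometric model for a yes-proportion curve."""

    def __init__(self, curve: pd.DataFrame):
        if len(curve) < 4:
            raise ValueError("need >= 4 distinct asynchrony levels")
        self.levels = curve["asynchrony_ms"].to_numpy(float)
        self.p_yes = curve["p_yes"].to_numpy(float)

    @classmethod
    def from_trials(cls, trials: pd.DataFrame) -> "PsychometricModel":
        return cls(proportion_yes(trials))

    def _r2(self, pred: np.ndarray) -> float:
        ss_res = float(np.sum((self.p_yes - pred) ** 2))
        ss_tot = float(np.sum((self.p_yes - self.p_yes.mean()) ** 2))
        if ss_tot == 0.0:
            return 0.0
        return 1.0 - ss_res / ss_tot

    def fit(self, n_starts: int = 20, seed: int = 0) -> PsychometricFit:
        """Bounded least squares from ``n_starts`` seeded initial guesses."""
        lv, py = self.levels, self.p_yes
        if np.ptp(py) < 1e-12:  # flat curve: width unidentifiable
            return PsychometricFit(
                amplitude=float(py.mean()) if py.mean() > 0 else TBW_BOUNDS["amplitude"][0],
                mu=0.0,
                sd=TBW_BOUNDS["sd"][1],
                r2=0.0,
                converged=False,
                n_starts=0,
            )
        lo = [TBW_BOUNDS["amplitude"][0], lv.min(), TBW_BOUNDS["sd"][0]]
        hi = [TBW_BOUNDS["amplitude"][1], lv.max(), TBW_BOUNDS["sd"][1]]
        rng = np.random.default_rng(seed)

        def resid(theta):
            a, mu, sd = theta
            return a * np.exp(-((lv - mu) ** 2) / (2.0 * sd**2)) - py

        def jac(theta):
            a, mu, sd = theta
            g = np.exp(-((lv - mu) ** 2) / (2.0 * sd**2))
            return np.column_stack(
                [g, a * g * (lv - mu) / sd**2, a * g * (lv - mu) ** 2 / sd**3]
            )

        # moment-based guess first, then random restarts
        guesses = [
            np.clip(
                [py.max(), lv[np.argmax(py)], 0.5 * (abs(lv).max() + 1)], lo, hi
            )
        ]
        for _ in range(max(n_starts - 1, 0)):
            guesses.append(rng.uniform(lo, hi))
        best = None
        for x0 in guesses:
            try:
                res = optimize.least_squares(resid, x0, jac=jac, bounds=(lo, hi))
            except Exception:  # pragma: no cover
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:  # pragma: no cover - least_squares is robust
            return PsychometricFit(np.nan, np.nan, np.nan, np.nan, False, len(guesses))
        a, mu, sd = best.x
        fit = PsychometricFit(
            amplitude=float(a),
            mu=float(mu),
            sd=float(sd),
            r2=self._r2(resid(best.x) + py),
            converged=bool(best.success),
            n_starts=len(guesses),
        )
        return fit


def fit_gaussian_tbw(curve: pd.DataFrame, n_starts: int = 20, seed: int = 0) -> PsychometricFit:
    """Fit the scaled Gaussian to a yes-proportion curve; sd is the TBW."""
    return PsychometricModel(curve).fit(n_starts=n_starts, seed=seed)


def pad_rate(count: int, n: int) -> float:
    """Rate with half-trial edge correction: 0 -> 0.5/n, n -> (n-0.5)/n."""
    if n < 1:
        raise ValueError("cannot compute a rate from zero trials")
    if not 0 <= count <= n:
        raise ValueError("count must lie in [0, n]")
    if count == 0:
        return 0.5 / n
    if count == n:
        return (n - 0.5) / n
    return count / n


@dataclass
class SDTTable:
    """Per-|asynchrony| signal-detection measures plus the AUC summary."""

    table: pd.DataFrame  # abs_asynchrony_ms, n_fa_trials, fa_count, hit_rate, fa_rate, dprime, bias
    hit_rate: float
    n_signal: int
    auc: float
    mean_bias: float


def sdt_by_asynchrony(trials: pd.DataFrame) -> SDTTable:
    """Signal-detection table: 0 ms = signal, collapsed |s| > 0 = noise.

    Positive and negative asynchronies of equal magnitude are pooled before
    computing the false-alarm rate. Rates are half-trial padded so that the
    normal quantile is finite.
    """
    curve = proportion_yes(trials)
    if curve.empty or 0.0 not in set(curve["asynchrony_ms"]):
        raise ValueError("SDT analysis needs 0-ms (signal) trials")
    sig = curve[curve["asynchrony_ms"] == 0.0].iloc[0]
    H = pad_rate(int(sig["n_yes"]), int(sig["n"]))
    zH = float(ndtri(H))
    noise = curve[curve["asynchrony_ms"] != 0.0].copy()
    noise["abs_asynchrony_ms"] = noise["asynchrony_ms"].abs()
    pooled = (
        noise.groupby("abs_asynchrony_ms", sort=True)
        .agg(n=("n", "sum"), n_yes=("n_yes", "sum"))
        .reset_index()
    )
    rows = []
    for _, r in pooled.iterrows():
        fa = pad_rate(int(r["n_yes"]), int(r["n"]))
        zFA = float(ndtri(fa))
        rows.append(
            {
                "abs_asynchrony_ms": r["abs_asynchrony_ms"],
                "n_fa_trials": int(r["n"]),
                "fa_count": int(r["n_yes"]),
                "hit_rate": H,
                "fa_rate": fa,
                "dprime": zH - zFA,
                "bias": -0.5 * (zH + zFA),
            }
        )
    table = pd.DataFrame(rows)
    auc = auc_from_table(table) if len(table) >= 2 else float("nan")
    return SDTTable(
        table=table,
        hit_rate=H,
        n_signal=int(sig["n"]),
        auc=auc,
        mean_bias=float(table["bias"].mean()),
    )


def auc_from_table(table: pd.DataFrame) -> float:
    x = table["abs_asynchrony_ms"].to_numpy(float)
    y = table["dprime"].to_numpy(float)
    order = np.argsort(x)
    return float(np.trapezoid(y[order], x[order]))


def auc_dprime(sdt: SDTTable) -> float:
    """Trapezoidal area under d' over |asynchrony| (units: d' * ms)."""
    if len(sdt.table) < 2:
        raise ValueError("AUC needs >= 2 collapsed asynchrony levels")
    return auc_from_table(sdt.table)
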