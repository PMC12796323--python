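"""Correlation utilities and the correlation sample-size calculation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

__all__ = ["CorrelationResult", "correlate", "corr_power", "corr_sample_size"]


@dataclass(frozen=True)
class CorrelationResult:
    """A correlation coefficient with its two-sided p-value."""

    r: float
    n: int
    p_two_sided: float
    method: str

    def summary(self) -> str:
        return f"{self.method} r = {self.r:.3f} (n = {self.n}, p = {self.p_two_sided:.4g})"


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with a t-based two-sided p-value.

    Spearman is Pearson on (average) ranks; both p-values use the exact
    t transform with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if method == "pearson":
        r = float(np.corrcoef(x, y)[0, 1])
    elif method == "spearman":
        r = float(np.corrcoef(sstats.rankdata(x), sstats.rankdata(y))[0, 1])
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    n = len(x)
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sstats.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, n=n, p_two_sided=p, method=method)


def corr_power(n: int, rho: float, alpha: float = 0.05, two_sided: bool = True) -> float:
    """Power of the correlation test via the bias-corrected Fisher z.

    The critical r comes from the t distribution with n - 2 df; under the
    alternative the transformed statistic z_r = atanh(r) + rho / (2(n-1))
    is treated as normal with SD 1/sqrt(n-3) (the classic approximation
    used by standard power software for this test).
    """
    if n < 4:
        return 0.0
    side = 2.0 if two_sided else 1.0
    df = n - 2
    t_crit = sstats.t.isf(alpha / side, df)
    r_crit = np.sqrt(t_crit**2 / (t_crit**2 + df))
    zr = np.arctanh(rho) + rho / (2.0 * (n - 1))
    zrc = np.arctanh(r_crit)
    return float(sstats.norm.cdf((zr - zrc) * np.sqrt(n - 3)))


def corr_sample_size(
    rho: float,
    alpha: float = 0.05,
    power: float = 0.80,
    two_sided: bool = True,
    n_max: int = 10_000_000,
) -> int:
    """Smallest n whose correlation test reaches the target power.

    Uses the bias-corrected Fisher-z power function (:func:`corr_power`);
    for rho = 0.5, alpha = 0.05 two-sided and power 0.80 this gives n = 29.
    """
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must lie strictly in (0, 1)")
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise ValueError("alpha and power must lie strictly in (0, 1)")
    # closed-form Fisher-z start, then walk to the exact boundary
    side = 2.0 if two_sided else 1.0
    za = sstats.norm.isf(alpha / side)
    zb = sstats.norm.isf(1.0 - power)
    n = max(4, int(((za + zb) / np.arctanh(rho)) ** 2 + 3) - 3)
    while n < n_max and corr_power(n, rho, alpha, two_sided) < power:
        n += 1
    while n > 4 and corr_power(n - 1, rho, alpha, two_sided) >= power:
        n -= 1
    return n
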