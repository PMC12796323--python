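"""Power spectra and individual alpha frequency (IAF) estimation.

Spectra come from Welch's averaged periodogram (Hann-tapered 6-s segments,
50% overlap, zero-padded so the bin spacing is at most a target resolution,
0.167 Hz by default). The IAF — the dominant oscillation frequency inside
the alpha band, 8-13 Hz by default — is estimated two ways:

``classic``
    argmax of raw power over the band, with a guard that flags band-edge
    maxima that are not local maxima of the full spectrum (the signature of
    a peakless 1/f background leaking into the band).
``aperiodic_corrected``
    a log10-log10 line (alpha-adjacent band excluded) is fitted to the
    spectrum and subtracted; the IAF is the most prominent local maximum of
    the residual inside the band, with parabolic interpolation for sub-bin
    precision. Fails (success=False) when no residual peak clears the
    prominence floor — i.e. there is no oscillation above the background.

Per-electrode estimates are aggregated over a region of interest by
averaging the successful ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "AperiodicFit",
    "IAFEstimate",
    "Spectrum",
    "fit_aperiodic",
    "iaf_classic",
    "iaf_corrected",
    "relative_power",
    "roi_iaf",
    "welch_psd",
    "zscore_db",
]

ALPHA_BAND = (8.0, 13.0)


@dataclass
class Spectrum:
    """One-sided power spectral density on a uniform frequency grid."""

    freqs: np.ndarray
    power: np.ndarray
    window_s: float
    overlap: float
    padded_length: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")

    @property
    def resolution(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def band_slice(self, lo: float, hi: float) -> np.ndarray:
        return (self.freqs >= lo) & (self.freqs <= hi)


def welch_psd(
    x: np.ndarray,
    fs: float,
    window_s: float = 6.0,
    overlap: float = 0.5,
    target_resolution: float = 0.167,
) -> Spectrum:
    """Welch PSD with Hann windows and zero padding to a target resolution.

    Signals shorter than one window (e.g. 1-s task epochs) are zero-padded
    to the full window length and analyzed as a single segment.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    win_samples = int(round(window_s * fs))
    nperseg = min(x.size, win_samples)
    nfft = max(win_samples, int(np.ceil(fs / target_resolution)))
    freqs, power = sps.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        nfft=nfft,
        detrend="constant",
    )
    return Spectrum(
        freqs=freqs,
        power=power,
        window_s=window_s,
        overlap=overlap,
        padded_length=nfft,
    )


def relative_power(
    spec: Spectrum,
    band: tuple[float, float] = ALPHA_BAND,
    total_range: tuple[float, float] | None = None,
) -> float:
    """Band power divided by total power over the analyzed range."""
    if total_range is None:
        total_range = (float(spec.freqs[0]), float(spec.freqs[-1]))
    band_mask = spec.band_slice(*band)
    total_mask = spec.band_slice(*total_range)
    if not band_mask.any():
        raise ValueError("band contains no frequency bins")
    total = float(spec.power[total_mask].sum())
    if total == 0.0:
        return 0.0
    return float(spec.power[band_mask].sum()) / total


def zscore_db(spec: Spectrum, frange: tuple[float, float] | None = None) -> np.ndarray:
    """Reporting transform: 10 log10(power), z-scored across bins in range.

    Used for visualization/normalized reporting only; peak locations are
    invariant to this monotone per-spectrum transform, so IAF estimation
    never depends on it.
    """
    mask = spec.band_slice(*frange) if frange else np.ones_like(spec.freqs, bool)
    db = 10.0 * np.log10(np.maximum(spec.power[mask], 1e-300))
    sd = db.std()
    return (db - db.mean()) / sd if sd > 0 else db - db.mean()


@dataclass
class IAFEstimate:
    """Estimated alpha-peak frequency; ``freq`` is NaN when unsuccessful."""

    freq: float
    method: str
    success: bool
    peak_prominence: float = float("nan")


def iaf_classic(spec: Spectrum, band: tuple[float, float] = ALPHA_BAND) -> IAFEstimate:
    """Raw-power argmax over the alpha band (ties broken to lower frequency).

    The estimate is flagged unsuccessful when the argmax sits on a band
    edge without being a local maximum of the full spectrum — the expected
    outcome on a monotone 1/f background with no alpha peak.
    """
    mask = spec.band_slice(*band)
    if not mask.any():
        raise ValueError("band outside spectrum support")
    idx_band = np.flatnonzero(mask)
    sub = spec.power[idx_band]
    i_rel = int(np.argmax(sub))  # argmax returns the first (lowest-f) max
    i_full = idx_band[i_rel]
    freq = float(spec.freqs[i_full])
    success = True
    if i_rel in (0, len(idx_band) - 1):
        left = spec.power[i_full - 1] if i_full > 0 else np.inf
        right = spec.power[i_full + 1] if i_full < len(spec.power) - 1 else np.inf
        if not (spec.power[i_full] > left and spec.power[i_full] > right):
            success = False
    return IAFEstimate(freq=freq, method="classic", success=success)


@dataclass
class AperiodicFit:
    """Log-log linear background: log10 P = offset - exponent * log10 f."""

    offset: float
    exponent: float
    fit_range: tuple[float, float]

    def predict_log10(self, freqs: np.ndarray) -> np.ndarray:
        return self.offset - self.exponent * np.log10(freqs)


def fit_aperiodic(
    spec: Spectrum,
    fit_range: tuple[float, float] = (3.0, 40.0),
    exclude: tuple[float, float] = (7.0, 14.0),
) -> AperiodicFit:
    """Least-squares line in log10 power vs log10 frequency.

    Bins in ``exclude`` (the alpha-adjacent band) and bins with nonpositive
    power are dropped before the fit; the aperiodic exponent is minus the
    slope.
    """
    mask = spec.band_slice(*fit_range) & ~spec.band_slice(*exclude)
    mask &= spec.power > 0
    mask &= spec.freqs > 0
    if mask.sum() < 10:
        raise ValueError("fewer than 10 usable bins for the aperiodic fit")
    lx = np.log10(spec.freqs[mask])
    ly = np.log10(spec.power[mask])
    slope, intercept = np.polyfit(lx, ly, 1)
    return AperiodicFit(offset=float(intercept), exponent=float(-slope), fit_range=fit_range)


def _parabolic_refine(freqs: np.ndarray, y: np.ndarray, i: int) -> float:
    """Sub-bin peak location by fitting a parabola through 3 points."""
    if i <= 0 or i >= len(y) - 1:
        return float(freqs[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(freqs[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    return float(freqs[i] + delta * (freqs[1] - freqs[0]))


def iaf_corrected(
    spec: Spectrum,
    band: tuple[float, float] = ALPHA_BAND,
    aperiodic: AperiodicFit | None = None,
    min_prominence: float = 0.1,
) -> IAFEstimate:
    """IAF from the aperiodic-corrected spectrum.

    The aperiodic line is subtracted in log10 space; local maxima of the
    residual within the band are ranked by height and must have prominence
    >= ``min_prominence`` (log10-power units; 0.1 = 1 dB). Unsuccessful
    when nothing rises above the background.
    """
    if aperiodic is None:
        aperiodic = fit_aperiodic(spec)
    pos = spec.power > 0
    resid = np.full_like(spec.power, -np.inf)
    resid[pos] = np.log10(spec.power[pos]) - aperiodic.predict_log10(
        np.maximum(spec.freqs, np.finfo(float).tiny)
    )[pos]
    mask = spec.band_slice(*band)
    idx_band = np.flatnonzero(mask)
    sub = resid[idx_band]
    peaks, props = sps.find_peaks(sub, prominence=min_prominence)
    if len(peaks) == 0:
        return IAFEstimate(freq=float("nan"), method="aperiodic_corrected", success=False)
    best = peaks[int(np.argmax(sub[peaks]))]
    prom = float(props["prominences"][int(np.argmax(sub[peaks]))])
    # refine on the full-resolution residual around the winning bin
    freq = _parabolic_refine(spec.freqs, resid, int(idx_band[best]))
    freq = float(np.clip(freq, band[0], band[1]))
    return IAFEstimate(
        freq=freq, method="aperiodic_corrected", success=True, peak_prominence=prom
    )


def roi_iaf(estimates: list[IAFEstimate]) -> tuple[float, int]:
    """Mean IAF over the successful per-electrode estimates in an ROI.

    Returns ``(mean_iaf_hz, n_success)``; raises when no electrode yielded
    a usable peak.
    """
    ok = [e.freq for e in estimates if e.success]
    if not ok:
        raise ValueError("no successful IAF estimate in the ROI")
    return float(np.mean(ok)), len(ok)
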