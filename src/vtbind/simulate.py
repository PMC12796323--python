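"""Synthetic observers, cohorts and EEG-like signals.

Everything downstream (psychometric fitting, causal-inference MLE, spectral
IAF estimation) is exercised against data generated here with known ground
truth: a causal-inference observer that draws noisy asynchrony measurements
and applies the |x| < sqrt(K) decision rule, a Gaussian-psychometric
observer, and EEG-like signals composed of a 1/f aperiodic background plus
an alpha oscillation of known frequency.

The cohort generator can couple sensory noise to alpha frequency through a
linear link (sigma = intercept + slope * alpha_freq + noise), emulating the
hypothesis that a faster alpha rhythm implies a finer temporal sampling of
visuotactile input and hence less uncertain asynchrony measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bci import BCIParams, decision_threshold
from .design import SIGMA_S, build_design, enumerate_trials

__all__ = [
    "BCIObserver",
    "CohortPriors",
    "EEGSpec",
    "GaussianObserver",
    "IAFLink",
    "simulate_bci_responses",
    "simulate_cohort",
    "simulate_gaussian_observer",
    "simulate_tacs_cohort",
    "synthesize_eeg",
    "read_eeg_text",
    "write_eeg_text",
]


@dataclass(frozen=True)
class BCIObserver:
    """Generative causal-inference observer (one stimulation condition)."""

    p_same_own: float = 0.8
    p_same_sim: float = 0.6
    sigma: float = 150.0
    lapse: float = 0.02
    sigma_s: float = SIGMA_S["E2"]

    def __post_init__(self) -> None:
        BCIParams(self.p_same_own, self.p_same_sim, self.sigma, self.lapse)
        if self.sigma_s <= 0:
            raise ValueError("sigma_s must be positive")

    def params(self) -> BCIParams:
        return BCIParams(self.p_same_own, self.p_same_sim, self.sigma, self.lapse)

    def p_same(self, task: str) -> float:
        return self.p_same_own if task == "ownership" else self.p_same_sim


@dataclass(frozen=True)
class GaussianObserver:
    """Observer whose yes-probability is a scaled Gaussian in asynchrony."""

    amplitude: float = 0.95
    mu: float = 0.0
    sd: float = 150.0

    def __post_init__(self) -> None:
        if not 0.0 < self.amplitude <= 1.0:
            raise ValueError("amplitude must lie in (0, 1]")
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    def p_yes(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return self.amplitude * np.exp(-((s - self.mu) ** 2) / (2.0 * self.sd**2))


def simulate_bci_responses(
    observer: BCIObserver, trials: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Fill the ``response`` column by simulating the observer trial by trial.

    For each trial a measurement x ~ N(s, sigma^2) is drawn and "yes" is
    reported iff x^2 < K (undefined K: never via the decision rule). With
    probability ``lapse`` the decision is replaced by a fair coin flip.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    out = trials.copy()
    s = out["asynchrony_ms"].to_numpy(float)
    x = rng.normal(s, observer.sigma)
    yes = np.zeros(len(out), dtype=bool)
    for task in out["task"].unique():
        mask = (out["task"] == task).to_numpy()
        thr = decision_threshold(observer.p_same(task), observer.sigma, observer.sigma_s)
        if thr.defined:
            yes[mask] = x[mask] ** 2 < thr.K
    lapsed = rng.random(len(out)) < observer.lapse
    coin = rng.random(len(out)) < 0.5
    yes = np.where(lapsed, coin, yes)
    out["response"] = np.where(yes, "yes", "no")
    return out


def simulate_gaussian_observer(
    observer: GaussianObserver, trials: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Bernoulli responses from the scaled-Gaussian psychometric curve."""
    rng = np.random.default_rng(seed)
    out = trials.copy()
    p = observer.p_yes(out["asynchrony_ms"].to_numpy(float))
    out["response"] = np.where(rng.random(len(out)) < p, "yes", "no")
    return out


# ---------------------------------------------------------------------------
# EEG-like signals


@dataclass(frozen=True)
class EEGSpec:
    """Recipe for an EEG-like signal: alpha sinusoid over a 1/f background.

    The aperiodic background has one-sided PSD 10**offset / f**exponent
    (signal units^2 / Hz); white measurement noise of SD ``noise_sd`` is
    added on top. Defaults emulate a preprocessed resting-state recording:
    4 min at 512 Hz with a clearly visible ~10 Hz peak over a 1/f slope.
    """

    fs: float = 512.0
    duration_s: float = 240.0
    alpha_freq: float = 10.0
    alpha_amp: float = 0.7
    aperiodic_offset: float = 0.0
    aperiodic_exponent: float = 1.0
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.fs <= 2.0 * self.alpha_freq:
            raise ValueError("fs must exceed twice the alpha frequency")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.aperiodic_exponent < 0:
            raise ValueError("aperiodic_exponent must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))


def synthesize_eeg(spec: EEGSpec, seed: int = 0) -> np.ndarray:
    """Sample a signal from an :class:`EEGSpec`; deterministic per seed.

    The 1/f component is realized by spectrally shaping white Gaussian
    noise: the rFFT of a white draw is multiplied by sqrt(S(f)) with
    S(f) = 10**offset / f**exponent (f > 0; the DC bin is zeroed), scaled
    so that the one-sided PSD of the result is S(f).
    """
    rng = np.random.default_rng(seed)
    n = spec.n_samples
    t = np.arange(n) / spec.fs
    phase = rng.uniform(0.0, 2.0 * np.pi)
    sig = spec.alpha_amp * np.sin(2.0 * np.pi * spec.alpha_freq * t + phase)
    if spec.aperiodic_offset != -np.inf:
        white = rng.standard_normal(n)
        freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs)
        gain = np.zeros_like(freqs)
        nz = freqs > 0
        psd = 10.0**spec.aperiodic_offset / freqs[nz] ** spec.aperiodic_exponent
        # white noise of unit variance has one-sided PSD 2/fs
        gain[nz] = np.sqrt(psd * spec.fs / 2.0)
        sig = sig + np.fft.irfft(np.fft.rfft(white) * gain, n=n)
    if spec.noise_sd > 0:
        sig = sig + rng.normal(0.0, spec.noise_sd, size=n)
    return sig


def write_eeg_text(signal: np.ndarray, path, fs: float) -> None:
    """Write a signal as single-column text with a YAML sidecar (fs, n)."""
    import yaml

    path = str(path)
    np.savetxt(path, np.asarray(signal, dtype=float), fmt="%.10g")
    meta = {"fs": float(fs), "n_samples": int(len(signal))}
    with open(path + ".meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def read_eeg_text(path) -> tuple[np.ndarray, float]:
    """Read a signal written by :func:`write_eeg_text`; returns (signal, fs)."""
    import yaml

    path = str(path)
    signal = np.loadtxt(path)
    with open(path + ".meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    if int(meta["n_samples"]) != len(signal):
        raise ValueError("sidecar sample count does not match the signal file")
    return signal, float(meta["fs"])


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortPriors:
    """Uniform sampling ranges for participant-level parameters."""

    p_same_own: tuple[float, float] = (0.55, 0.95)
    p_same_sim: tuple[float, float] = (0.3, 0.9)
    sigma: tuple[float, float] = (60.0, 350.0)
    lapse: tuple[float, float] = (0.0, 0.1)
    alpha_freq: tuple[float, float] = (8.5, 12.5)


@dataclass(frozen=True)
class IAFLink:
    """Linear link from alpha frequency (Hz) to sensory noise sigma (ms)."""

    slope: float = -30.0
    intercept: float = 490.0
    noise_sd: float = 20.0


PARTICIPANT_COLUMNS = [
    "participant",
    "p_same_own",
    "p_same_sim",
    "sigma",
    "lapse",
    "alpha_freq",
]


def _sample_participants(
    n: int, priors: CohortPriors, iaf_link: IAFLink | None, rng
) -> pd.DataFrame:
    rows = []
    for i in range(n):
        alpha = rng.uniform(*priors.alpha_freq)
        if iaf_link is not None:
            sigma = iaf_link.intercept + iaf_link.slope * alpha
            if iaf_link.noise_sd > 0:
                sigma += rng.normal(0.0, iaf_link.noise_sd)
            sigma = max(sigma, 1.0)
        else:
            sigma = rng.uniform(*priors.sigma)
        rows.append(
            {
                "participant": f"S{i + 1:03d}",
                "p_same_own": rng.uniform(*priors.p_same_own),
                "p_same_sim": rng.uniform(*priors.p_same_sim),
                "sigma": sigma,
                "lapse": rng.uniform(*priors.lapse),
                "alpha_freq": alpha,
            }
        )
    return pd.DataFrame(rows, columns=PARTICIPANT_COLUMNS)


def simulate_cohort(
    n_participants: int,
    priors: CohortPriors | None = None,
    iaf_link: IAFLink | None = None,
    seed: int = 0,
    experiment_id: str = "E2",
    eeg_spec: EEGSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, EEGSpec]]:
    """Simulate a cohort of causal-inference observers.

    Returns ``(participants, trials, eeg_specs)``: the ground-truth
    parameter table, the pooled trial table with simulated responses for
    both tasks of ``experiment_id``, and one :class:`EEGSpec` per
    participant whose ``alpha_freq`` is that participant's true IAF.
    """
    priors = priors or CohortPriors()
    base_eeg = eeg_spec or EEGSpec()
    rng = np.random.default_rng(seed)
    participants = _sample_participants(n_participants, priors, iaf_link, rng)
    sigma_s = SIGMA_S.get(experiment_id, SIGMA_S["E2"])
    tables = []
    eeg_specs: dict[str, EEGSpec] = {}
    for _, row in participants.iterrows():
        obs = BCIObserver(
            p_same_own=row["p_same_own"],
            p_same_sim=row["p_same_sim"],
            sigma=row["sigma"],
            lapse=row["lapse"],
            sigma_s=sigma_s,
        )
        for task in ("ownership", "simultaneity"):
            design = build_design(experiment_id, task)
            trials = enumerate_trials(
                design,
                seed=int(rng.integers(2**31)),
                participant=row["participant"],
            )
            tables.append(
                simulate_bci_responses(obs, trials, seed=int(rng.integers(2**31)))
            )
        eeg_specs[row["participant"]] = EEGSpec(
            fs=base_eeg.fs,
            duration_s=base_eeg.duration_s,
            alpha_freq=row["alpha_freq"],
            alpha_amp=base_eeg.alpha_amp,
            aperiodic_offset=base_eeg.aperiodic_offset,
            aperiodic_exponent=base_eeg.aperiodic_exponent,
            noise_sd=base_eeg.noise_sd,
        )
    trials = (
        pd.concat(tables, ignore_index=True)
        if tables
        else enumerate_trials(build_design(experiment_id, "ownership"), n_blocks=0)
    )
    return participants, trials, eeg_specs


def simulate_tacs_cohort(
    n_participants: int,
    priors: CohortPriors | None = None,
    sigma_factors: dict[str, float] | None = None,
    seed: int = 0,
    experiment_id: str = "E3",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort under three stimulation conditions with condition-varying sigma.

    Each participant keeps one p_same per task across conditions while
    sigma is scaled by ``sigma_factors`` (default low 1.25, sham 1.0,
    high 0.8 — slower alpha entrainment raising, faster lowering, sensory
    uncertainty). Ground truth for model-selection studies where the
    sigma-varying model is the true one.
    """
    priors = priors or CohortPriors()
    factors = sigma_factors or {"low": 1.25, "sham": 1.0, "high": 0.8}
    rng = np.random.default_rng(seed)
    participants = _sample_participants(n_participants, priors, None, rng)
    sigma_s = SIGMA_S.get(experiment_id, SIGMA_S["E3"])
    tables = []
    for _, row in participants.iterrows():
        for cond, fac in factors.items():
            obs = BCIObserver(
                p_same_own=row["p_same_own"],
                p_same_sim=row["p_same_sim"],
                sigma=row["sigma"] * fac,
                lapse=row["lapse"],
                sigma_s=sigma_s,
            )
            for task in ("ownership", "simultaneity"):
                design = build_design(experiment_id, task)
                trials = enumerate_trials(
                    design,
                    seed=int(rng.integers(2**31)),
                    participant=row["participant"],
                    condition=cond,
                )
                tables.append(
                    simulate_bci_responses(obs, trials, seed=int(rng.integers(2**31)))
                )
    trials = (
        pd.concat(tables, ignore_index=True)
        if tables
        else enumerate_trials(build_design(experiment_id, "ownership"), n_blocks=0)
    )
    return participants, trials
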