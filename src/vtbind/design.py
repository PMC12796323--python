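"""Experimental designs for the visuotactile asynchrony tasks.

Four designs are encoded, matching the rubber-hand-illusion ownership task
and the visuotactile simultaneity-judgment task as run in three experiments:

``E1_own``
    Ownership judgments; asynchronies 0, +/-50, +/-150, +/-300, +/-500 ms,
    4 repetitions per level per block, 3 blocks (36 trials/block).
``E1_sim``
    Simultaneity judgments; 0, +/-50, +/-100, +/-150, +/-200, +/-300,
    +/-400, +/-500 ms, 12 reps/level/block, 2 blocks (180 trials/block).
``E2``
    Both tasks on the same grid 0, +/-100, +/-200, +/-300, +/-400 ms,
    5 reps/level/block, 3 blocks per task (45 trials/block).
``E3``
    tACS experiment; 0, +/-100, +/-200, +/-400 ms, 5 reps/level/block,
    2 blocks per task per stimulation condition (35 trials/block).

The fixed stimulus-distribution SD ``sigma_s`` used by the causal-inference
observer (293 ms for E2, 290 ms for E3) is stored as an opaque constant;
it is the SD the observer model assumes for asynchronies under separate
causes and is not recomputed from the level grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AsynchronyDesign",
    "ExperimentSpec",
    "SIGMA_S",
    "TRIAL_COLUMNS",
    "UnknownDesignError",
    "build_design",
    "build_experiment",
    "enumerate_trials",
    "read_trial_table",
    "write_trial_table",
]

#: Fixed stimulus-distribution SD (ms) assumed by the observer model under
#: the separate-causes hypothesis; defined only for the modelled experiments.
SIGMA_S: dict[str, float] = {"E2": 293.0, "E3": 290.0}

TRIAL_COLUMNS = [
    "participant",
    "task",
    "block",
    "trial_index",
    "asynchrony_ms",
    "condition",
    "response",
]

TASKS = ("ownership", "simultaneity")
CONDITIONS = ("low", "sham", "high", "none")


class UnknownDesignError(KeyError):
    """Raised for an experiment/task combination that was never run."""


@dataclass(frozen=True)
class AsynchronyDesign:
    """One task's asynchrony grid and block structure.

    Parameters
    ----------
    task : {"ownership", "simultaneity"}
    experiment : {"E1_own", "E1_sim", "E2", "E3"}
    levels : tuple of float
        Signed asynchronies in ms, symmetric about 0 with 0 included once.
    reps_per_block : int
        Repetitions of each level within a block.
    n_blocks : int
        Number of blocks per task (per condition, where conditions apply).
    taps_per_trial : int
        Number of visuotactile stimulus pairs per trial.
    trial_duration_s : float
        Nominal stimulation duration of one trial in seconds.
    inter_tap_jitter_ms : tuple or None
        (lo, hi) of the jittered inter-tap interval; metadata only, unused
        by the observer model.
    """

    task: str
    experiment: str
    levels: tuple[float, ...]
    reps_per_block: int
    n_blocks: int
    taps_per_trial: int = 6
    trial_duration_s: float = 12.0
    inter_tap_jitter_ms: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=float)
        if np.count_nonzero(lv == 0.0) != 1:
            raise ValueError("levels must include 0 exactly once")
        if set(lv) != set(-lv):
            raise ValueError("levels must be symmetric about 0")

    @property
    def trials_per_block(self) -> int:
        return len(self.levels) * self.reps_per_block


def _sym(*mags: float) -> tuple[float, ...]:
    out = sorted({float(m) for m in mags} | {float(-m) for m in mags} | {0.0})
    return tuple(out)


_DESIGNS: dict[tuple[str, str], AsynchronyDesign] = {}


def _register(d: AsynchronyDesign) -> None:
    _DESIGNS[(d.experiment, d.task)] = d


_register(
    AsynchronyDesign(
        task="ownership",
        experiment="E1_own",
        levels=_sym(50, 150, 300, 500),
        reps_per_block=4,
        n_blocks=3,
    )
)
_register(
    AsynchronyDesign(
        task="simultaneity",
        experiment="E1_sim",
        levels=_sym(50, 100, 150, 200, 300, 400, 500),
        reps_per_block=12,
        n_blocks=2,
        taps_per_trial=1,
        trial_duration_s=0.5,
    )
)
for _task in TASKS:
    _register(
        AsynchronyDesign(
            task=_task,
            experiment="E2",
            levels=_sym(100, 200, 300, 400),
            reps_per_block=5,
            n_blocks=3,
            inter_tap_jitter_ms=(1100.0, 1300.0),
        )
    )
    _register(
        AsynchronyDesign(
            task=_task,
            experiment="E3",
            levels=_sym(100, 200, 400),
            reps_per_block=5,
            n_blocks=2,
            inter_tap_jitter_ms=(1000.0, 1200.0),
        )
    )


@dataclass(frozen=True)
class ExperimentSpec:
    """All task designs of one experiment plus the model constant sigma_s."""

    experiment: str
    designs: Mapping[str, AsynchronyDesign] = field(default_factory=dict)
    sigma_s: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_s is not None and self.sigma_s <= 0:
            raise ValueError("sigma_s must be positive")


def build_design(experiment_id: str, task: str) -> AsynchronyDesign:
    """Return the printed design for one experiment/task combination."""
    try:
        return _DESIGNS[(experiment_id, task)]
    except KeyError:
        raise UnknownDesignError(
            f"no design for experiment {experiment_id!r}, task {task!r}; "
            f"known: {sorted(set(k[0] for k in _DESIGNS))}"
        ) from None


def build_experiment(experiment_id: str) -> ExperimentSpec:
    """Bundle every task design of an experiment with its sigma_s constant."""
    designs = {
        task: d for (exp, task), d in _DESIGNS.items() if exp == experiment_id
    }
    if not designs:
        raise UnknownDesignError(f"unknown experiment {experiment_id!r}")
    return ExperimentSpec(
        experiment=experiment_id,
        designs=designs,
        sigma_s=SIGMA_S.get(experiment_id),
    )


def enumerate_trials(
    design: AsynchronyDesign,
    n_blocks: int | None = None,
    seed: int = 0,
    participant: str = "P01",
    condition: str = "none",
) -> pd.DataFrame:
    """Generate a randomized trial table for ``n_blocks`` blocks.

    Within each block every level appears exactly ``reps_per_block`` times,
    in an order shuffled by ``seed`` (deterministic). Responses are filled
    with ``"missing"``; simulators overwrite them.
    """
    if n_blocks is None:
        n_blocks = design.n_blocks
    if n_blocks < 0:
        raise ValueError("n_blocks must be >= 0")
    rng = np.random.default_rng(seed)
    base = np.repeat(np.asarray(design.levels, float), design.reps_per_block)
    rows = []
    for b in range(n_blocks):
        order = rng.permutation(base)
        for i, s in enumerate(order):
            rows.append((participant, design.task, b, i, s, condition, "missing"))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def write_trial_table(trials: pd.DataFrame, path) -> None:
    """Write a trial table as comma-separated text with a header row."""
    trials.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def read_trial_table(path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trial_table`."""
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    df["asynchrony_ms"] = df["asynchrony_ms"].astype(float)
    return df[TRIAL_COLUMNS]
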