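import numpy as np
import pandas as pd
import pytest

import vtbind as v
from vtbind.design import TRIAL_COLUMNS


def make_trials(levels, reps, task="ownership", condition="none", participant="P1"):
    """Flat (unshuffled) trial table with `reps` trials at each level."""
    rows = []
    idx = 0
    for s in levels:
        for _ in range(reps):
            rows.append((participant, task, 0, idx, float(s), condition, "missing"))
            idx += 1
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


@pytest.fixture(scope="session")
def e2_levels():
    return [0.0, 100.0, -100.0, 200.0, -200.0, 300.0, -300.0, 400.0, -400.0]


@pytest.fixture(scope="session")
def default_observer():
    return v.BCIObserver()


@pytest.fixture(scope="session")
def e2_participant_trials(default_observer):
    """One simulated participant: both E2 tasks at printed trial counts."""
    tabs = []
    for i, task in enumerate(("ownership", "simultaneity")):
        design = v.build_design("E2", task)
        trials = v.enumerate_trials(design, seed=10 + i)
        tabs.append(v.simulate_bci_responses(default_observer, trials, seed=20 + i))
    return pd.concat(tabs, ignore_index=True)
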