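import numpy as np
import pandas as pd
import pytest

import neurocompress as nc


@pytest.fixture(scope="session")
def bank():
    return nc.make_problem_bank()


@pytest.fixture(scope="session")
def schedule(bank):
    return nc.make_trial_schedule(bank, ("high", "low", "medium"), seed=11)


@pytest.fixture(scope="session")
def sim_trials(schedule):
    """One simulated participant at the mean fitted parameter values."""
    return nc.simulate_learner(schedule, nc.SustainParams(), seed=12)


@pytest.fixture(scope="session")
def group_trials(bank):
    """Six simulated participants with counterbalanced low/medium order."""
    sims = []
    for i in range(6):
        order = ("high", "low", "medium") if i % 2 else ("high", "medium", "low")
        sched = nc.make_trial_schedule(
            bank, order, seed=40 + i, participant=f"sub-{i + 1:02d}"
        )
        sims.append(nc.simulate_learner(sched, nc.SustainParams(), seed=50 + i))
    return pd.concat(sims, ignore_index=True)


@pytest.fixture(scope="session")
def small_mask():
    return nc.spherical_mask((12, 12, 12), 5.0)
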