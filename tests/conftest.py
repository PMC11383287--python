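"""Shared fixtures: the demo model, reference signals, and small runs."""

import numpy as np
import pytest

from lineagesim import (build_demo_model, growth_media, run_population,
                        starved_average_state)
from lineagesim.cycle_progress import reference_signal


@pytest.fixture(scope="session")
def model():
    return build_demo_model()


@pytest.fixture(scope="session")
def starved_base(model):
    return starved_average_state(model)


@pytest.fixture(scope="session")
def media():
    return growth_media()


@pytest.fixture(scope="session")
def reference(model, media):
    return reference_signal(model, media)


@pytest.fixture(scope="session")
def media_trajectory(model, starved_base, media):
    """One long deterministic stimulated trajectory (several cycles)."""
    from lineagesim import simulate_cell

    return simulate_cell(starved_base.copy(cell_id="session-det"), media,
                         240.0, model=model, stochastic_death=False)


@pytest.fixture(scope="session")
def small_run(model, media):
    """A small control population with stored trajectories (>= 2 generations)."""
    res = run_population(model, 8, media, exp_time=72.0, seed=11,
                         store_trajectories=True)
    assert res.n_generations >= 2
    return res


@pytest.fixture(scope="session")
def control_run(model, media):
    """A mid-sized control population for heterogeneity analyses."""
    return run_population(model, 120, media, exp_time=72.0, seed=17)


def make_rng(seed=0):
    return np.random.default_rng(seed)
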