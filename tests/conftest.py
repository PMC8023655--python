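"""Shared fixtures: one reference forcing and one median forward run are
computed once per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import soilplant as sp

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: seed of the reference synthetic experiment used across the suite
FORCING_SEED = 101


@pytest.fixture(scope="session")
def scenario():
    return sp.default_scenario()


@pytest.fixture(scope="session")
def forcing(scenario):
    return sp.generate_forcing(seed=FORCING_SEED, scenario=scenario)


@pytest.fixture(scope="session")
def median_forward(scenario, forcing):
    """Full coupled forward run at the calibrated medians (50 elements)."""
    return sp.run_forward(scenario, forcing, n_elements=50)


@pytest.fixture(scope="session")
def grid(scenario):
    return sp.make_grid(scenario.horizons, n_elements=50)


@pytest.fixture(scope="session")
def horizon1(scenario):
    return scenario.horizons[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
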