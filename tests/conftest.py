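"""Shared fixtures: one modest synthetic study reused across test modules."""

from __future__ import annotations

import pytest

from dementia_cohorts.simulate import (
    SimulationConfig,
    assign_gold_standard,
    degrade_to_observables,
    simulate_gdp_series,
    simulate_panel,
)


@pytest.fixture(scope="session")
def default_gdp():
    return simulate_gdp_series(range(2004, 2015), ["US"], seed=7)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_individuals=2_000, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_config, default_gdp):
    return simulate_panel(small_config, default_gdp)


@pytest.fixture(scope="session")
def small_observed(small_truth):
    return degrade_to_observables(small_truth)


@pytest.fixture(scope="session")
def small_gold(small_truth):
    return assign_gold_standard(small_truth)
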