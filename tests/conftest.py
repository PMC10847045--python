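"""Shared fixtures: a small synthetic survey parameterized once per session."""

from __future__ import annotations

import numpy as np
import pytest

from rhizodeb import FixtureConfig, RunConfig, generate_isolates, generate_substrates
from rhizodeb.closure import parameterize_consumer
from rhizodeb.io import traits_from_table
from rhizodeb.substrates import substrate_table_properties


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def fixture_config() -> FixtureConfig:
    return FixtureConfig(n_isolates=8, n_substrates_per_class=2, seed=7)


@pytest.fixture(scope="session")
def isolate_table(fixture_config):
    return generate_isolates(fixture_config)


@pytest.fixture(scope="session")
def substrate_table(fixture_config):
    return generate_substrates(fixture_config)


@pytest.fixture(scope="session")
def substrates(substrate_table, run_config):
    return substrate_table_properties(substrate_table, run_config.chemistry)


@pytest.fixture(scope="session")
def traits(isolate_table):
    return traits_from_table(isolate_table)


@pytest.fixture(scope="session")
def consumers(traits, substrates, run_config):
    return [parameterize_consumer(tr, substrates, run_config) for tr in traits]


@pytest.fixture(scope="session")
def saturating_config() -> RunConfig:
    """Closure-recovery protocol: saturating substrate, reserve-poor inoculum.

    Starting below the balanced reserve density makes the growth rate
    approach its saturated value from below, so the trajectory maximum is
    the steady saturated rate itself.
    """
    cfg = RunConfig()
    cfg.protocol.substrate_mgC_L = 12500.0
    cfg.protocol.reserve_fraction = 0.001
    cfg.protocol.batch_hours = 400.0
    return cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
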