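import numpy as np
import pytest

from ervcre import synthetic_data as synth


@pytest.fixture(scope="session")
def sim_config():
    """Default study conditions, fixed seed."""
    return synth.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def genome(sim_config):
    return synth.make_genome(sim_config)


@pytest.fixture(scope="session")
def chip(sim_config, genome):
    return synth.make_chip(sim_config, genome)


@pytest.fixture(scope="session")
def expression(sim_config, genome):
    return synth.make_expression(sim_config, genome.truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
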