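import pytest

from cnvpop import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_regions=300, n_chroms=5, n_differentiated=6, seed=7)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_dataset(small_config)
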