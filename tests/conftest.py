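import numpy as np
import pytest

from methylcontext.synthetic_data import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A compact genome for tests that need real sequence."""
    return SimulationConfig(
        genome_length=300_000,
        n_chroms=2,
        island_count=15,
        gene_count=20,
        planted_dmr_count=20,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_genome(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
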