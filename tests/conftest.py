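import numpy as np
import pytest

from mutmapkit import default_config, default_genome
from mutmapkit.simulate import simulate_dataset


@pytest.fixture(scope="session")
def genome():
    return default_genome()


@pytest.fixture(scope="session")
def morgans_per_bp(genome):
    return {c.name: c.genetic_length_morgans / c.length_bp for c in genome}


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down experiment for fast unit tests (full scale lives in the
    acceptance suite)."""
    return default_config(n_variants=400, n_f2=300, pool_size=60, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
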