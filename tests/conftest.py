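import numpy as np
import pytest

from polylife.kernels import compute_grm
from polylife.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One small complete study reused across read-only tests."""
    cfg = SimulationConfig(n_individuals=300, n_variants=200,
                           n_duplicate_pairs=2, missing_rate=0.02, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_grm(small_dataset):
    return compute_grm(small_dataset.genotypes)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
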