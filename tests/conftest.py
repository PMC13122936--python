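import numpy as np
import pytest

from scziva import CountMatrix, SimConfig, simulate_counts


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_counts(rng):
    """A 12 x 9 raw count matrix with a mix of zeros and positives."""
    values = rng.poisson(2.0, size=(12, 9)).astype(float)
    values[:, 4] = 0  # one all-zero gene
    return CountMatrix(values)


@pytest.fixture
def sim_small():
    """A small simulated dataset with group structure."""
    cfg = SimConfig(n_cells=80, n_genes=60, n_groups=3, block_size=10, seed=7)
    return simulate_counts(cfg)
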