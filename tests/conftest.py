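import numpy as np
import pytest

from coexqtl.config import SimConfig
from coexqtl import simulate


@pytest.fixture(scope="session")
def default_cfg() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def sim_default(default_cfg):
    """One default synthetic dataset shared across tests (seed 1)."""
    return simulate.simulate_all(default_cfg)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Small, fast dataset for io/round-trip and shape tests."""
    return SimConfig(
        n_individuals=40,
        n_snps=200,
        n_genes=120,
        module_sizes=(20, 15, 12),
        chrom_length_bp=2_000_000,
        n_cis_genes=5,
        n_structural_genes=10,
        n_tf_genes=6,
        seed=7,
    )


@pytest.fixture(scope="session")
def sim_small(small_cfg):
    return simulate.simulate_all(small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
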