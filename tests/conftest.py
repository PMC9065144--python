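import numpy as np
import pytest

from voxelgwas import SimConfig, simulate_genotypes, simulate_region_atlas


@pytest.fixture(scope="session")
def null_config():
    """Small global-null cohort config reused across tests."""
    return SimConfig(n_subjects=300, n_snps=80, ld_block_size=10,
                     within_block_r=0.5, missing_rate=0.01,
                     grid_dims=(6, 6, 2), n_latent=3, seed=11)


@pytest.fixture(scope="session")
def null_genotypes(null_config):
    return simulate_genotypes(null_config)


@pytest.fixture(scope="session")
def small_atlas():
    return simulate_region_atlas((6, 6, 2), n_regions=4, smoothness=1.0, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
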