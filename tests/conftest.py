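import numpy as np
import pytest

from xdosage.annotation import ParBoundaries
from xdosage.simulate import SimConfig, simulate_annotation


@pytest.fixture(scope="session")
def boundaries() -> ParBoundaries:
    return ParBoundaries()


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Reduced cohort used by most simulation-backed tests."""
    return SimConfig(seed=11, n_genes_autosome=60, n_genes_x_nonpar=100,
                     n_genes_par1=10, n_genes_par2=3)


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return simulate_annotation(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
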