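import numpy as np
import pytest

from action.metric import ACTIONKernel
from action.simulate import SimulationConfig, simulate_labeled_counts


@pytest.fixture(scope="session")
def fivetype():
    """Default five-type synthetic dataset (500 cells, 2000 genes)."""
    return simulate_labeled_counts(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def fivetype_kernel(fivetype):
    """Fitted similarity-kernel estimator for the five-type dataset."""
    return ACTIONKernel(random_state=0).fit(fivetype.X.values.T)


@pytest.fixture(scope="session")
def small_dataset():
    """Small three-type dataset for fast io/CLI tests."""
    config = SimulationConfig(
        n_types=3,
        cells_per_type=[40, 40, 40],
        m_genes=300,
        n_universal=30,
        markers_per_type=10,
        seed=7,
    )
    return simulate_labeled_counts(config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
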