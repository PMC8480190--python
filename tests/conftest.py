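import numpy as np
import pytest

from arcdating import make_benchmark_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """20-tip serially sampled dataset under the ARC clock (omega=2)."""
    ttree, stree = make_benchmark_dataset(2.0, seed=42, n_tips=20)
    return ttree, stree


@pytest.fixture(scope="session")
def strict_dataset():
    """20-tip dataset simulated with omega=0 (strict clock)."""
    ttree, stree = make_benchmark_dataset(0.0, seed=7, n_tips=20)
    return ttree, stree


@pytest.fixture
def rng():
    return np.random.default_rng(0)
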