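import numpy as np
import pytest

from alelm import default_mixture_spec, make_pool


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_split():
    """A small, well-separated 3-class mixture split shared across tests."""
    return make_pool(default_mixture_spec(n_total=300, seed=7))


@pytest.fixture
def two_class_data(rng):
    """Two well-separated 2-D Gaussian classes, 50 samples each."""
    X = np.vstack([
        rng.normal([-3.0, 0.0], 1.0, size=(50, 2)),
        rng.normal([3.0, 0.0], 1.0, size=(50, 2)),
    ])
    y = np.repeat([0, 1], 50)
    return X, y
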