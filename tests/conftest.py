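import numpy as np
import pytest

from deconfound.data import Dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """20 subjects, 5 features, one two-level confound, linear signal."""
    n, d = 20, 5
    c = (rng.random(n) < 0.5).astype(float)
    y = rng.normal(size=n)
    G = np.outer(y, rng.normal(size=d)) + np.outer(2 * c - 1, rng.normal(size=d)) \
        + rng.normal(size=(n, d))
    return Dataset(G=G, C=c[:, None], y=y)
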