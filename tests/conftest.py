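import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_onehot():
    def make(n, m, seed=0):
        r = np.random.default_rng(seed)
        x = np.zeros((n, m))
        x[np.arange(n), r.integers(m, size=n)] = 1.0
        return x

    return make
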