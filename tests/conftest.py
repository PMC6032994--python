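import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def two_blob_data():
    """Well-separated two-class Gaussian blobs (60 samples, 3 features)."""
    g = np.random.default_rng(42)
    X0 = g.normal(0.0, 0.5, size=(30, 3))
    X1 = g.normal(4.0, 0.5, size=(30, 3))
    X = np.vstack([X0, X1])
    y = np.array([0] * 30 + [1] * 30)
    perm = g.permutation(60)
    return X[perm], y[perm]
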