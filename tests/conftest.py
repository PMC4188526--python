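import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def standardized_regression(rng, n, p, k_signal=3, snr=1.0):
    """Small standardized (X, y) with k_signal true coefficients."""
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    beta = np.zeros(p)
    beta[:k_signal] = rng.standard_normal(k_signal) * snr
    y = X @ beta + rng.standard_normal(n)
    y = (y - y.mean()) / y.std(ddof=1)
    return X, y
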