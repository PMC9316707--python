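import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def standardized_design(rng, n, p, corr=None):
    """Random standardized design, optionally with a given correlation."""
    z = rng.standard_normal((n, p))
    if corr is not None:
        z = z @ np.linalg.cholesky(corr).T
    return (z - z.mean(axis=0)) / z.std(axis=0, ddof=1)


@pytest.fixture
def small_xy(rng):
    """A 40 x 3 standardized design with one strong predictor."""
    x = standardized_design(rng, 40, 3)
    beta = np.array([1.0, 0.4, 0.0])
    y = x @ beta + rng.standard_normal(40)
    return x, y - y.mean()
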