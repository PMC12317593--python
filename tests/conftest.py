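import numpy as np
import pytest
from scipy.special import expit

from casemix import Cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_cohort(rng, n=200, k=3, beta=None, intercept=-1.0, source_frac=0.5):
    """Small random cohort with a logistic outcome for unit tests."""
    X = rng.normal(size=(n, k))
    if beta is None:
        beta = np.linspace(0.5, -0.5, k)
    p = expit(intercept + X @ beta)
    Y = rng.binomial(1, p)
    R = (rng.random(n) < source_frac).astype(int)
    names = tuple(f"x{i}" for i in range(k))
    return Cohort(X, Y, R, names)


@pytest.fixture
def small_cohort(rng):
    return random_cohort(rng)
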