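import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_surv():
    """Six subjects, two groups, with ties and censoring — printed fixture."""
    time = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
    event = np.array([1, 1, 0, 1, 1, 0])
    group = np.array([0, 0, 0, 1, 1, 1])
    return time, event, group


def simulate_surv(rng, n, beta=0.0, x=None, censor_frac=0.3, scale=10.0, shape=1.2):
    """Weibull proportional-hazards draw used across survival tests."""
    if x is None:
        x = rng.standard_normal(n)
    lp = beta * x
    t = scale * (-np.log(rng.uniform(size=n)) / np.exp(lp)) ** (1.0 / shape)
    c = np.where(rng.uniform(size=n) < censor_frac,
                 rng.uniform(0, scale * 1.5, size=n), np.inf)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return x, time, event
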