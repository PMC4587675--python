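import numpy as np
import pytest

from betanova import BetaConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def config():
    return BetaConfig()


@pytest.fixture
def clean_record(rng):
    """A two-group gene record under the null (same mean, sigma2 = 0.05)."""
    sd = np.sqrt(0.05)
    return [rng.normal(3.0, sd, 5), rng.normal(3.0, sd, 5)]


def make_de_record(rng, means=(2.0, 4.0), n=3, sigma2=0.05):
    sd = np.sqrt(sigma2)
    return [rng.normal(mu, sd, n) for mu in means]


@pytest.fixture
def de_record(rng):
    return make_de_record(rng)
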