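import numpy as np
import pytest

from hgtlv.model import CommunityModel, CommunityState


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_hgt_model(rng, m=None, *, eta_max=0.25):
    """A random valid HGT community: rates in the standard protocol ranges."""
    if m is None:
        m = int(rng.integers(2, 11))
    mu = rng.uniform(0.4, 0.6, size=m)
    eta = float(rng.uniform(0.0, eta_max))
    return CommunityModel.from_growth_rates(
        mu, mu0=0.5, gamma=0.9, eta=eta, kappa=0.005, D=0.2
    )


def random_valid_state(rng, m):
    """A random state satisfying 0 <= p_ij <= s_i."""
    s = rng.uniform(0.05, 0.8, size=m)
    p = rng.uniform(0.0, 1.0, size=(m, m)) * s[:, None]
    return CommunityState(s=s, p=p)


@pytest.fixture
def model_factory():
    return random_hgt_model


@pytest.fixture
def state_factory():
    return random_valid_state
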