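import numpy as np
import pytest

from fedmil import SiteGenConfig, generate_federation, init_mil_params
from fedmil.synthetic import FeatureBag


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_params(rng):
    """A tiny MIL model: D=2, attention width 2, one hidden layer of 3."""
    return init_mil_params(2, attn_dim=2, rho_hidden=(3,), rng=rng, init_std=0.5)


@pytest.fixture
def random_bag(rng):
    X = rng.standard_normal((5, 2))
    return FeatureBag("slide0", "siteA", X, label=1)


@pytest.fixture
def tiny_federation():
    """Three small heterogeneous sites, split 60:15:25."""
    base = SiteGenConfig(n_bags=40, feature_dim=8, k_range=(5, 15), seed=1)
    return generate_federation(3, base, heterogeneity=1.5, seed=5)
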