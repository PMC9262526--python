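import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tcmcat.cat_engine import AbilityPrior, CATConfig, generate_item_bank

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_bank():
    """18 items, 3 per element, 4 categories: small enough for brute force."""
    return generate_item_bank(n_items=18, n_categories=4, seed=7)


@pytest.fixture(scope="session")
def default_bank():
    return generate_item_bank(seed=2)


@pytest.fixture(scope="session")
def prior():
    return AbilityPrior.standard()


@pytest.fixture(scope="session")
def cat_config():
    return CATConfig()
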