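import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from modcontrib import FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def additive_fixture():
    """Small three-modality dataset with an additive-linear oracle predictor."""
    return make_fixture(FixtureSpec(seed=11, n_samples=5))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
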