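import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from adhesim import validate_params

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
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    """The reference condition at full size (not run to completion in tests)."""
    return validate_params({"seed": 1})


@pytest.fixture
def short_params():
    """A short condition cheap enough for kernel runs inside unit tests."""
    return validate_params({"seed": 1, "t_total": 10.0, "t_burnin": 5.0})
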