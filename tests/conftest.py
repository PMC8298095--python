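import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from myeltrace.synthetic import scenario_suite

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scenarios():
    """The standard phantom scenarios at the default noise level, seed 0."""
    return scenario_suite(seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
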