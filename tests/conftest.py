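import pytest
from hypothesis import HealthCheck, settings

from forcarb.registry import ParameterRegistry
from forcarb.synthetic import zixi_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry() -> ParameterRegistry:
    return ParameterRegistry.default()


@pytest.fixture(scope="session")
def zixi():
    """Calibrated synthetic study-area inventory (deterministic)."""
    return zixi_fixture()
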