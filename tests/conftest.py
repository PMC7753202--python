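import pytest
from hypothesis import HealthCheck, settings

from flyscreen import SyntheticConfig

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def config() -> SyntheticConfig:
    """Default study conditions: 5 replicates, 15 flies (8 for CAFE)."""
    return SyntheticConfig(seed=7)
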