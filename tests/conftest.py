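import pytest
from hypothesis import HealthCheck, settings

import icicea

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    """Bundled base-case configuration (treat as read-only)."""
    return icicea.default_config()


@pytest.fixture()
def fresh_config():
    """A mutable copy of the default configuration."""
    return icicea.default_config()


@pytest.fixture(scope="session")
def base_traces(config):
    """Deterministic cohort traces of all three arms at baseline."""
    return {
        s.name: icicea.run_cohort(s.name, config) for s in config.strategies
    }
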