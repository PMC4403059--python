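import pytest
from hypothesis import HealthCheck, settings

from zcspec import default_grid, default_models, develop_method

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def models():
    return {m.compound_id: m for m in default_models()}


@pytest.fixture(scope="session")
def developed():
    """Noiseless method development on the default synthetic system."""
    return develop_method()
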