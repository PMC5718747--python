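import pytest
from hypothesis import HealthCheck, settings

from gpbuildup import builtin_registry
from gpbuildup.fixtures import (
    SyntheticSpec,
    synthetic_attenuation,
    synthetic_gp_library,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def synthetic_ds():
    """Deterministic synthetic elemental attenuation dataset, Z=1-30."""
    return synthetic_attenuation(SyntheticSpec())


@pytest.fixture(scope="session")
def synthetic_lib():
    """Deterministic GP library, exactly linear in ln Z per energy."""
    return synthetic_gp_library()


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()
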