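import pytest
from hypothesis import HealthCheck, settings

import visitcarbon as vc

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def profiles():
    return vc.load_city_profiles()


@pytest.fixture(scope="session")
def factors():
    """Default factor set (unrounded fleet-weighted drive factor)."""
    return vc.EmissionFactors()


@pytest.fixture(scope="session")
def factors259(factors):
    """Factor set with the drive factor pinned at the display value 259 g/km."""
    return factors.with_(drive_gco2e_per_km=259.0)


@pytest.fixture(scope="session")
def table6(profiles):
    return vc.fixture_table6(profiles)


@pytest.fixture(scope="session")
def populations():
    return vc.load_populations()
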