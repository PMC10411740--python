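import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from cryocarbon import build_scenario  # noqa: E402


@pytest.fixture(scope="session")
def cb1():
    return build_scenario("CB1")


@pytest.fixture(scope="session")
def cb4_table():
    return build_scenario("CB4", p0="table")


@pytest.fixture(scope="session")
def cb4_derived():
    return build_scenario("CB4", p0="derived")


@pytest.fixture(scope="session")
def cbiw():
    return build_scenario("CBIW")
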