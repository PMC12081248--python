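import pytest
from hypothesis import HealthCheck, settings

from hsctpbpk import build_individual
from hsctpbpk.library import load_library

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def individual():
    return build_individual()


@pytest.fixture(scope="session")
def library():
    return load_library()
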