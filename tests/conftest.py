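import pytest
from hypothesis import HealthCheck, settings

from pharmqueue import EVENING_SHIFT, MORNING_SHIFT, STUDY_POLICY

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def morning():
    return MORNING_SHIFT


@pytest.fixture(scope="session")
def evening():
    return EVENING_SHIFT


@pytest.fixture(scope="session")
def policy():
    return STUDY_POLICY
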