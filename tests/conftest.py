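import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pausekit import default_group_profiles

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def profiles():
    return default_group_profiles()


@pytest.fixture(scope="session")
def control_profile(profiles):
    return profiles["control"]
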