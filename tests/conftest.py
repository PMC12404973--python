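import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import psmcea

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

SCENARIO_IDS = (
    "china_overall",
    "china_ith_l",
    "china_a11_b62",
    "us_overall",
    "us_ith_l",
    "us_a11_b62",
)


@pytest.fixture(scope="session")
def scenarios():
    """All six packaged scenarios, loaded once."""
    return {sid: psmcea.load_scenario(sid) for sid in SCENARIO_IDS}


@pytest.fixture(scope="session")
def china_overall(scenarios):
    return scenarios["china_overall"]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
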