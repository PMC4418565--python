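import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from kegfr.gfr_equations import Subject


@pytest.fixture
def male_subject() -> Subject:
    return Subject("m50", age=50, sex="male", weight=80.0, height=180.0)


@pytest.fixture
def female_subject() -> Subject:
    return Subject("f60", age=60, sex="female", weight=65.0, height=162.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210412)
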