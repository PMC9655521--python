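import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bonedx import study

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_xt():
    """The study's 2×2×2 table reconstructed from printed percentages."""
    return study.study_crosstab()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
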