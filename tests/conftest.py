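import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pedri import default_config

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg():
    """Default six-analyte cohort model."""
    return default_config()


@pytest.fixture(scope="session")
def clean_cfg():
    """Default model with contamination switched off."""
    return default_config(contamination_fraction=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
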