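import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pwsfield.cohort import default_cohort_config, generate_cohort, patient_frame

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """The default 190-patient synthetic cohort, seed 0."""
    return generate_cohort(default_cohort_config(seed=0))


@pytest.fixture(scope="session")
def patient_table(default_cohort):
    return patient_frame(default_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
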