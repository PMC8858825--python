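import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from rdineq.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One medium cohort under the default study conditions."""
    return generate_cohort(SyntheticConfig(n=10_000, seed=42))


@pytest.fixture(scope="session")
def homogeneous_cohort():
    """Cohort with a homogeneous treatment effect of 1.0."""
    return generate_cohort(
        SyntheticConfig(n=10_000, late_by_tercile=(1.0, 1.0, 1.0), seed=7)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
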