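import pytest
from hypothesis import HealthCheck, settings

import alkdeep as ad

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def reference():
    return ad.default_reference()


@pytest.fixture(scope="session")
def profile():
    """Default-condition error profile shared across the suite."""
    return ad.draw_error_profile(seed=101)


@pytest.fixture(scope="session")
def controls(profile):
    """Eight germline controls at the assay's design depth."""
    return ad.simulate_control_cohort(profile, n_controls=8, depth=5000, seed=202)


@pytest.fixture(scope="session")
def model(controls):
    return ad.estimate_background(controls)


@pytest.fixture(scope="session")
def cohort_table():
    return ad.load_cohort()
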