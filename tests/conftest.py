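import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def reference_cohort():
    """One simulated reference cohort shared across read-only tests."""
    from ddxeval import reference_cohort_config, simulate_cohort

    return simulate_cohort(reference_cohort_config(seed=7))
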