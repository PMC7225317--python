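import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed cohort with artifacts enabled, shared across tests."""
    from pttsleep import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(n_children=24, seed=11, study_hours=6.0))


@pytest.fixture(scope="session")
def clean_cohort():
    """Artifact-free cohort for ground-truth recovery checks."""
    from pttsleep import CohortConfig, generate_cohort

    return generate_cohort(
        CohortConfig(n_children=24, seed=12, study_hours=6.0, artifact_spike_rate_per_hour=0.0,
                     spo2_dropout_rate_per_hour=0.0)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
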