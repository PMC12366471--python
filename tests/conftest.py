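import pytest
from hypothesis import HealthCheck, settings

from abcog import (
    BAYESIAN_NORM,
    ContextProfile,
    ParticipantSpec,
    generate_design,
    simulate_cohort,
)

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def minimal_design():
    """Smallest fully balanced cohort: 12 participants, every
    scenario-type x combination pair exactly once."""
    return generate_design(12, seed=11)


@pytest.fixture(scope="session")
def study_design():
    """Full 48-participant balanced battery."""
    return generate_design(48, seed=11)


@pytest.fixture(scope="session")
def bayesian_cohort(study_design):
    """Noiseless, unrounded judgments of ideal Bayesian responders."""
    profile = ContextProfile.uniform(BAYESIAN_NORM, sigma=0.0)
    specs = [ParticipantSpec(pid, profile) for pid in range(1, 49)]
    return simulate_cohort(study_design, specs, seed=11, round_percent=False)
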