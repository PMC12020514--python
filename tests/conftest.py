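import numpy as np
import pytest

from emostop.io import RunConfig, default_image_pool, simulate_cohort
from emostop.participants import ParticipantParams, sample_participant
from emostop.protocol import TaskSpec, build_schedule, run_session


@pytest.fixture(scope="session")
def spec():
    return TaskSpec()


@pytest.fixture(scope="session")
def image_pool():
    return default_image_pool()


def make_params(**overrides) -> ParticipantParams:
    """A deterministic, noiseless participant for constructed scenarios."""
    base = dict(
        go_mu=500.0,
        go_sigma=50.0,
        go_tau=150.0,
        image_appraisal_shift={"pleasant": 100.0, "unpleasant": 150.0},
        ssrt_mean=230.0,
        ssrt_sd=30.0,
        p_go_omission=0.0,
        p_choice_error=0.0,
        p_trigger_failure=0.0,
        p_image_wrong_action={"pleasant": 0.0, "unpleasant": 0.0},
        p_rating_agreement={"pleasant": 1.0, "unpleasant": 1.0},
        age_group="younger",
    )
    base.update(overrides)
    return ParticipantParams(**base)


@pytest.fixture(scope="session")
def session_records(spec, image_pool):
    """One full simulated session of a sampled younger participant."""
    participant = sample_participant("younger", seed=42)
    schedule = build_schedule(spec, image_pool, seed=7)
    return run_session(spec, schedule, participant, seed=11)


@pytest.fixture(scope="session")
def cohort():
    """Default-size cohort (39 younger / 40 older) with ratings."""
    sessions, ratings = simulate_cohort(RunConfig(seed=2024), with_ratings=True)
    return sessions, ratings
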