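import pytest

import sonoflow as sf
from sonoflow.distributions import deterministic
from sonoflow.profile import ExamType, HospitalProfile, PatientClassConfig, RoomConfig


def single_server_profile(arrival_spec, service_spec, setup_spec=deterministic(0.0),
                          arrival_model="renewal_process", interval=None, batch=1):
    """One room, one patient class, one exam type (queueing-oracle helper)."""
    exam = ExamType("scan", "fixed20", service_spec)
    cls = PatientClassConfig(
        name="outpatient",
        share=1.0,
        arrival_model=arrival_model,
        exam_mix=(("scan", 1.0),),
        interarrival_spec=arrival_spec,
        interval_minutes=interval,
        batch_size=batch,
    )
    return HospitalProfile(
        classes=(cls,), exams=(exam,), rooms=(RoomConfig(5, "female"),),
        setup_spec=setup_spec,
    )


@pytest.fixture(scope="session")
def profile():
    return sf.default_profile()


@pytest.fixture(scope="session")
def short_calendar():
    """A reduced calendar (one measured day, short warm-up) for fast tests."""
    return sf.CalendarConfig(days_per_replication=1, warmup_minutes=400.0)


@pytest.fixture(scope="session")
def full_calendar():
    return sf.CalendarConfig()


@pytest.fixture(scope="session")
def one_replication(profile, full_calendar):
    """One full-length seeded replication with its event log, shared by the
    invariant checks."""
    return sf.run_replication(profile, "points", full_calendar, seed=11, collect_events=True)
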