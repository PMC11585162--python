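import numpy as np
import pytest

from edewarn.io import Measurement, Outcome, RawVisit, TriageRecord, VitalChannel

HOUR = 3600


def make_triage(**overrides):
    features = {
        "age": 45, "sex": "F", "season": 2, "revisit": 0, "is_job_related": 0,
        "department": "medicine", "day_zone": 1, "arrival_by_ambulance": 0,
        "major_disease": 0, "judgement_code": "B", "triage": 3,
        "pain_index": 2, "gcs": 15, "acute_change": 0,
    }
    vitals = {
        VitalChannel.SBP: "120", VitalChannel.DBP: "75", VitalChannel.HR: "80",
        VitalChannel.SPO2: "98", VitalChannel.BT: "36.5", VitalChannel.RR: "16",
    }
    triage_time = overrides.pop("triage_time_s", 0)
    vitals.update(overrides.pop("vitals", {}))
    features.update(overrides)
    return TriageRecord(features, vitals, triage_time)


def make_visit(visit_id="V1", measurements=(), cpr=False, dead=False,
               cpr_time_s=None, **triage_overrides):
    ms = [Measurement(visit_id, t, ch, str(v)) for t, ch, v in measurements]
    return RawVisit(
        visit_id=visit_id,
        triage=make_triage(**triage_overrides),
        measurements=ms,
        outcome=Outcome(cpr=cpr, dead=dead, cpr_time_s=cpr_time_s),
    )


def hourly_visit(visit_id="V1", n_hours=5, channel=VitalChannel.HR, value=80,
                 **kwargs):
    """A no-event visit with one measurement of `channel` per hour."""
    meas = [(h * HOUR, channel, value) for h in range(1, n_hours)]
    return make_visit(visit_id, meas, **kwargs)


@pytest.fixture
def toy_cohort():
    """Three visits: CPR+dead, dead-only (DNR analog), and no-event."""
    cpr_visit = make_visit(
        "CPR1",
        [(1 * HOUR, VitalChannel.HR, 90), (2 * HOUR, VitalChannel.HR, 110)],
        cpr=True, dead=True, cpr_time_s=3 * HOUR)
    dnr_visit = make_visit(
        "DNR1",
        [(1 * HOUR, VitalChannel.HR, 85), (3 * HOUR, VitalChannel.RR, 24)],
        dead=True)
    ok_visit = make_visit(
        "OK1",
        [(1 * HOUR, VitalChannel.HR, 70), (4 * HOUR, VitalChannel.HR, 72)])
    return [cpr_visit, dnr_visit, ok_visit]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
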