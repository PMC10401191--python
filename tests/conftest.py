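from datetime import date

import pytest

from anctriage._config import load_raw_thresholds, load_recommendations, load_thresholds
from anctriage.cohort_sim import default_config, simulate_cohort
from anctriage.records import Arm, ParticipantRecord, VisitRecord, VisitType


@pytest.fixture(scope="session")
def raw_thresholds():
    return load_raw_thresholds()


@pytest.fixture(scope="session")
def thresholds():
    return load_thresholds()


@pytest.fixture(scope="session")
def catalogue():
    return load_recommendations()


@pytest.fixture(scope="session")
def default_cohort():
    """Default simulated cohort (seed 1): (participants, visits, flow)."""
    return simulate_cohort(default_config(), seed=1)


@pytest.fixture
def participant():
    return ParticipantRecord(
        participant_id="P1", cluster_id="PHC_HR_I", arm=Arm.intervention,
        date_of_birth=date(1996, 5, 2), registration_date=date(2020, 8, 1),
        height=1.55, weight=60.0, lmp_date=date(2020, 1, 1),
        delivery_date=date(2020, 10, 1), schooling_years=12, household_size=4,
        booking_hb=10.5)


def make_visit(**kwargs):
    defaults = dict(
        participant_id="P1", visit_type=VisitType.antenatal,
        visit_date=date(2020, 8, 1), sbp=110.0, dbp=70.0, heart_rate=78.0,
        hb=12.0, ogtt_2h_glucose=110.0, gdm_screened=True, ogtt_done=True,
        ifa_supplied=True, entry_complete=True, entry_on_time=True)
    defaults.update(kwargs)
    return VisitRecord(**defaults)


@pytest.fixture
def visit():
    return make_visit()
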