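import numpy as np
import pytest

from icusurv.data_model import AdmissionRecord, CohortIndex, Event


def make_admission(
    admission_id="A1",
    patient_id="P1",
    events=(),
    outcome_time_d=400.0,
    event_indicator=False,
    birth_day=15,
    age=70.0,
    los=2.0,
    sex="M",
):
    adm = AdmissionRecord(
        patient_id=patient_id,
        admission_id=admission_id,
        age_years=age,
        sex=sex,
        hospital_los_days=los,
        birth_day_of_month=birth_day,
        outcome_time_d=outcome_time_d,
        event_indicator=event_indicator,
        events=list(events),
    )
    adm.validate()
    return adm


@pytest.fixture
def tiny_cohort():
    """Two patients, three admissions, events across all domains."""
    ev1 = [
        Event("medical_history", -240.0, code="DJ189"),
        Event("surgical_history", -5000.0, code="KNGB40"),
        Event("examination", -100.0, code="UXRC001"),
        Event("medication", -10.0, code="J01DH01_IV", value=1.0),
        Event("lab", -2.0, variable_name="NPU03429", value=5.0, unit="au"),
        Event("chart", 2.5, text="patient stable and awake"),
        Event("high_frequency", 3.2, variable_name="InvSysBP", value=120.0, unit="au"),
        Event("high_frequency", 3.6, variable_name="InvSysBP", value=130.0, unit="au"),
    ]
    ev2 = [
        Event("medical_history", -480.0, code="DI509"),
        Event("lab", -1.0, variable_name="NPU03429", value=7.0, unit="au"),
    ]
    return CohortIndex(
        [
            make_admission("A1", "P1", ev1, outcome_time_d=30.0, event_indicator=True),
            make_admission("A2", "P1", ev2, outcome_time_d=400.0),
            make_admission("A3", "P2", [], outcome_time_d=10.0, event_indicator=True,
                           birth_day=3),
        ]
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
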