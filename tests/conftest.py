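"""Shared fixtures: hand-built record sets for the matching and feature
rules, plus small helpers for constructing patients and events."""

from datetime import date, timedelta

import pytest

from prodroma.records import CodedEvent, Patient, RecordSet
from prodroma.vocabulary import CATEGORY_GROUPS, CategoryGroup, EventCategory

_TYPE = {
    CategoryGroup.SPINAL: "clinical_code",
    CategoryGroup.MUSCULOSKELETAL: "clinical_code",
    CategoryGroup.RELATED_DISORDER: "clinical_code",
    CategoryGroup.DIAGNOSTIC_TEST: "test",
    CategoryGroup.TREATMENT: "prescription",
}


def mk_patient(pid, sex="M", birth="1970-01-01", practice="gp1",
               reg="1990-01-01", reg_end=None, dx=None, dmard=None):
    return Patient(
        patient_id=pid, sex=sex, birth_date=date.fromisoformat(birth),
        practice_id=practice, registration_start=date.fromisoformat(reg),
        registration_end=date.fromisoformat(reg_end) if reg_end else None,
        as_diagnosis_date=date.fromisoformat(dx) if dx else None,
        first_dmard_date=date.fromisoformat(dmard) if dmard else None,
    )


def mk_event(pid, when, category, event_type=None):
    if event_type is None:
        event_type = _TYPE[CATEGORY_GROUPS[EventCategory(category)]]
    return CodedEvent(patient_id=pid, date=date.fromisoformat(when),
                      category=category, event_type=event_type)


def mk_records(patients, events):
    return RecordSet.from_objects(patients, events)


@pytest.fixture
def tiny_records():
    """Two patients, three events."""
    patients = [
        mk_patient("a", dx="2005-06-01"),
        mk_patient("b", sex="F"),
    ]
    events = [
        mk_event("a", "2003-01-10", "axial_pain"),
        mk_event("a", "2003-01-25", "nsaid"),
        mk_event("b", "2004-07-01", "large_joint"),
    ]
    return mk_records(patients, events)


@pytest.fixture
def matching_records():
    """One valid case in a practice with seven interchangeable eligible
    population controls, for control-sampling tests."""
    patients = [mk_patient("case1", dx="2005-06-01", birth="1970-03-15")]
    for i in range(7):
        patients.append(mk_patient(f"ctl{i}", birth="1970-06-01"))
    # wrong practice / wrong sex / prevalent AS: never eligible
    patients.append(mk_patient("other_practice", practice="gp2", birth="1970-06-01"))
    patients.append(mk_patient("wrong_sex", sex="F", birth="1970-06-01"))
    patients.append(mk_patient("prior_as", birth="1970-06-01", dx="2005-05-31"))
    events = [mk_event("case1", "2005-06-01", "as_diagnosis")]
    return mk_records(patients, events)
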