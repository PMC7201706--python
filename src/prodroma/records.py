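"""Patient and event tables: domain types, validation, CSV readers/writers.

The record model is deliberately minimal — the atoms of a coded primary-care
record are a patient (demographics, practice, one registration spell, optional
diagnosis and first-DMARD dates) and a dated coded event in one of the
controlled categories.  Dates are calendar dates, ISO-8601 in files; all
arithmetic elsewhere in the package is in whole days, except the analysis
window offsets which use calendar months.

Same-day duplicate codes are retained (presence/absence feature coding
absorbs them); an event dated outside its patient's registration spell
raises a warning but is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import pandas as pd

from .errors import DateParseError, ReferentialError, SchemaError, VocabularyError
from .vocabulary import CATEGORY_NAMES, EVENT_TYPES

PATIENT_COLUMNS = [
    "patient_id",
    "sex",
    "birth_date",
    "practice_id",
    "registration_start",
    "registration_end",
    "as_diagnosis_date",
    "first_dmard_date",
]
EVENT_COLUMNS = ["patient_id", "date", "category", "event_type"]

_PATIENT_DATE_COLS = ["birth_date", "registration_start", "registration_end",
                      "as_diagnosis_date", "first_dmard_date"]
_OPTIONAL_PATIENT_DATES = {"registration_end", "as_diagnosis_date", "first_dmard_date"}


@dataclass(frozen=True)
class Patient:
    """One patient with a single continuous registration spell."""

    patient_id: str
    sex: str
    birth_date: date
    practice_id: str
    registration_start: date
    registration_end: date | None = None
    as_diagnosis_date: date | None = None
    first_dmard_date: date | None = None


@dataclass(frozen=True)
class CodedEvent:
    """One dated coded entry in a patient's record."""

    patient_id: str
    date: date
    category: str
    event_type: str


class RecordSet:
    """Validated pair of patient and event tables.

    Parameters
    ----------
    patients, events:
        DataFrames with the documented columns; date columns either
        datetime64 or ISO-8601 strings.
    validate:
        Run schema/vocabulary/referential checks (default True).
    """

    def __init__(self, patients: pd.DataFrame, events: pd.DataFrame,
                 validate: bool = True):
        self.patients = _normalise_patients(patients)
        self.events = _normalise_events(events)
        if validate:
            self._validate()

    @classmethod
    def from_objects(cls, patients: list[Patient], events: list[CodedEvent]) -> "RecordSet":
        pdf = pd.DataFrame(
            [
                {
                    "patient_id": p.patient_id,
                    "sex": p.sex,
                    "birth_date": pd.Timestamp(p.birth_date),
                    "practice_id": p.practice_id,
                    "registration_start": pd.Timestamp(p.registration_start),
                    "registration_end": pd.Timestamp(p.registration_end) if p.registration_end else pd.NaT,
                    "as_diagnosis_date": pd.Timestamp(p.as_diagnosis_date) if p.as_diagnosis_date else pd.NaT,
                    "first_dmard_date": pd.Timestamp(p.first_dmard_date) if p.first_dmard_date else pd.NaT,
                }
                for p in patients
            ],
            columns=PATIENT_COLUMNS,
        )
        edf = pd.DataFrame(
            [
                {"patient_id": e.patient_id, "date": pd.Timestamp(e.date),
                 "category": e.category, "event_type": e.event_type}
                for e in events
            ],
            columns=EVENT_COLUMNS,
        )
        if edf.empty:
            edf["date"] = pd.to_datetime(edf["date"])
        return cls(pdf, edf)

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        pats, evs = self.patients, self.events
        bad_cat = ~evs["category"].isin(CATEGORY_NAMES)
        if bad_cat.any():
            rows = evs.index[bad_cat].tolist()[:20]
            labels = sorted(evs.loc[bad_cat, "category"].unique())
            raise VocabularyError(
                f"unknown event categories {labels} at rows {rows}"
            )
        bad_type = ~evs["event_type"].isin(EVENT_TYPES)
        if bad_type.any():
            rows = evs.index[bad_type].tolist()[:20]
            raise VocabularyError(f"unknown event_type at rows {rows}")
        known = set(pats["patient_id"])
        orphan = ~evs["patient_id"].isin(known)
        if orphan.any():
            rows = evs.index[orphan].tolist()[:20]
            raise ReferentialError(
                f"events reference unknown patient_ids at rows {rows}"
            )
        both = pats["registration_end"].notna()
        bad_spell = both & (pats["registration_start"] >= pats["registration_end"])
        if bad_spell.any():
            raise SchemaError(
                f"registration_start >= registration_end for patients "
                f"{pats.loc[bad_spell, 'patient_id'].tolist()}"
            )
        bad_birth = pats["birth_date"] >= pats["registration_start"]
        if bad_birth.any():
            raise SchemaError(
                f"birth_date on/after registration_start for patients "
                f"{pats.loc[bad_birth, 'patient_id'].tolist()}"
            )
        # events outside the registration spell: warn, keep
        spells = pats.set_index("patient_id")[["registration_start", "registration_end"]]
        ev = evs.join(spells, on="patient_id")
        early = ev["date"] < ev["registration_start"]
        late = ev["registration_end"].notna() & (ev["date"] > ev["registration_end"])
        outside = early | late
        if outside.any():
            warnings.warn(
                f"{int(outside.sum())} event(s) dated outside the patient's "
                f"registration spell (rows {evs.index[outside].tolist()[:20]}); retained",
                UserWarning,
                stacklevel=3,
            )

    # -- conveniences -------------------------------------------------------

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_events(self) -> int:
        return len(self.events)

    def events_for(self, patient_id: str) -> pd.DataFrame:
        return self.events[self.events["patient_id"] == patient_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RecordSet):
            return NotImplemented
        return (
            _sorted_patients(self.patients).equals(_sorted_patients(other.patients))
            and _sorted_events(self.events).equals(_sorted_events(other.events))
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"RecordSet({self.n_patients} patients, {self.n_events} events)"


def _parse_dates(df: pd.DataFrame, cols: list[str], optional: set[str],
                 table: str) -> pd.DataFrame:
    df = df.copy()
    for col in cols:
        if col not in df.columns:
            continue
        raw = df[col]
        if pd.api.types.is_datetime64_any_dtype(raw):
            continue
        parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
        blank = raw.isna() | (raw.astype(str).str.strip() == "")
        bad = parsed.isna() & ~blank
        if bad.any():
            rows = df.index[bad].tolist()[:20]
            raise DateParseError(
                f"{table}.{col}: unparseable ISO-8601 dates at rows {rows}"
            )
        if col not in optional and blank.any():
            rows = df.index[blank].tolist()[:20]
            raise DateParseError(
                f"{table}.{col}: missing required dates at rows {rows}"
            )
        df[col] = parsed
    return df


def _normalise_patients(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"patient table missing columns {missing}")
    df = _parse_dates(df[PATIENT_COLUMNS], _PATIENT_DATE_COLS,
                      _OPTIONAL_PATIENT_DATES, "patients")
    df["patient_id"] = df["patient_id"].astype(str)
    df["practice_id"] = df["practice_id"].astype(str)
    df["sex"] = df["sex"].astype(str)
    bad_sex = ~df["sex"].isin(["M", "F"])
    if bad_sex.any():
        raise SchemaError(
            f"sex must be M or F; bad rows {df.index[bad_sex].tolist()[:20]}"
        )
    return df.reset_index(drop=True)


def _normalise_events(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"event table missing columns {missing}")
    df = _parse_dates(df[EVENT_COLUMNS], ["date"], set(), "events")
    df["patient_id"] = df["patient_id"].astype(str)
    df["category"] = df["category"].astype(str)
    df["event_type"] = df["event_type"].astype(str)
    return df.reset_index(drop=True)


def _sorted_patients(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values("patient_id", kind="mergesort").reset_index(drop=True)


def _sorted_events(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(
        ["patient_id", "date", "category", "event_type"], kind="mergesort"
    ).reset_index(drop=True)


def read_records(patient_path: str | Path, event_path: str | Path) -> RecordSet:
    """Read and validate patient and event CSV tables.

    Raises :class:`SchemaError`, :class:`DateParseError`,
    :class:`VocabularyError` or :class:`ReferentialError` with offending row
    numbers on malformed input.
    """
    patients = pd.read_csv(patient_path, dtype=str, keep_default_na=False)
    patients = patients.replace({"": None})
    events = pd.read_csv(event_path, dtype=str, keep_default_na=False)
    return RecordSet(patients, events)


def write_records(rs: RecordSet, patient_path: str | Path,
                  event_path: str | Path) -> None:
    """Write a RecordSet to CSV, ordered by patient then date.

    The written files round-trip exactly: ``read_records`` on the output
    reproduces the RecordSet, and a second write is byte-identical.
    """
    pats = _sorted_patients(rs.patients).copy()
    for col in _PATIENT_DATE_COLS:
        pats[col] = pats[col].dt.strftime("%Y-%m-%d").fillna("")
    pats.to_csv(patient_path, index=False)
    evs = _sorted_events(rs.events).copy()
    evs["date"] = evs["date"].dt.strftime("%Y-%m-%d")
    evs.to_csv(event_path, index=False)
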