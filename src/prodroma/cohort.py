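"""Incident-case identification and incidence-density matched control sampling.

Cases are patients with a first coded AS diagnosis inside the study window,
aged 18-50 (completed years, bounds inclusive) at diagnosis, registered for
at least one year before diagnosis, and with no DMARD prescription more than
30 days before the coded diagnosis (such prescriptions mark prevalent
disease coded late).

Two control groups are drawn per case, both individually matched on sex and
GP practice with age within a caliper, registered and AS-free at the case's
index date (the case's diagnosis date, assigned identically to its
controls):

* population controls — any eligible patient;
* symptomatic controls — additionally require a coded spinal symptom or
  non-AS spinal diagnosis (axial pain / other spine diagnosis) on or before
  the index date.

When more than ``k`` matches are available, ``k`` are drawn uniformly
without replacement from a seeded stream; the draw is a deterministic
function of the record set, seed and case, independent of iteration order.
A patient may serve as a control for more than one case (logged); within
one case's set each control appears once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .records import RecordSet
from .vocabulary import SYMPTOMATIC_QUALIFYING

logger = logging.getLogger(__name__)

COMPARISONS = ("population", "symptomatic")


@dataclass(frozen=True)
class CaseDefinition:
    """Eligibility rules for incident cases."""

    diagnosis_window: tuple[date, date] = (date(2000, 1, 1), date(2010, 12, 31))
    age_range: tuple[int, int] = (18, 50)
    min_registration_lead_days: int = 365
    dmard_exclusion_lead_days: int = 30

    def __post_init__(self) -> None:
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range low must be < high")
        if self.min_registration_lead_days <= 0 or self.dmard_exclusion_lead_days <= 0:
            raise ValueError("leads must be positive")


@dataclass(frozen=True)
class MatchedSet:
    """One case plus its matched controls, sharing the case's index date."""

    comparison: str
    case_id: str
    control_ids: tuple[str, ...]
    index_date: pd.Timestamp

    @property
    def set_id(self) -> str:
        return f"{self.comparison}:{self.case_id}"


def completed_years(birth: pd.Series, at: pd.Timestamp) -> pd.Series:
    """Age in completed years at a date (vectorised)."""
    years = at.year - birth.dt.year
    had_birthday = (birth.dt.month < at.month) | (
        (birth.dt.month == at.month) & (birth.dt.day <= at.day))
    return years - (~had_birthday).astype(int)


def _effective_dates(rs: RecordSet) -> pd.DataFrame:
    """Per-patient effective AS-diagnosis / first-DMARD / first-spinal dates.

    The patient-table columns take precedence; where empty, the earliest
    matching coded event stands in.
    """
    pats = rs.patients.set_index("patient_id")
    ev = rs.events
    first_as = ev[ev["category"] == "as_diagnosis"].groupby("patient_id")["date"].min()
    first_dmard = ev[ev["category"] == "dmard"].groupby("patient_id")["date"].min()
    first_spinal = ev[ev["category"].isin(SYMPTOMATIC_QUALIFYING)] \
        .groupby("patient_id")["date"].min()
    out = pats[["sex", "practice_id", "birth_date",
                "registration_start", "registration_end"]].copy()
    out["as_date"] = pats["as_diagnosis_date"].fillna(
        first_as.reindex(pats.index))
    out["dmard_date"] = pats["first_dmard_date"].fillna(
        first_dmard.reindex(pats.index))
    out["first_spinal"] = first_spinal.reindex(pats.index)
    return out


def find_incident_cases(rs: RecordSet,
                        cd: CaseDefinition | None = None) -> pd.DataFrame:
    """Patients meeting the incident-case definition.

    Returns a frame with columns ``patient_id`` and ``index_date`` (the
    diagnosis date), sorted by patient_id.  An empty result is valid.
    """
    cd = cd or CaseDefinition()
    eff = _effective_dates(rs)
    dx = eff["as_date"]
    lo, hi = (pd.Timestamp(cd.diagnosis_window[0]),
              pd.Timestamp(cd.diagnosis_window[1]))
    ok = dx.notna() & (dx >= lo) & (dx <= hi)

    # age bounds inclusive, completed years at diagnosis
    age = pd.Series(index=eff.index, dtype=float)
    sub = eff[ok]
    years = sub["as_date"].dt.year - sub["birth_date"].dt.year
    had = (sub["birth_date"].dt.month < sub["as_date"].dt.month) | (
        (sub["birth_date"].dt.month == sub["as_date"].dt.month)
        & (sub["birth_date"].dt.day <= sub["as_date"].dt.day))
    age_completed = years - (~had).astype(int)
    ok.loc[sub.index] &= (age_completed >= cd.age_range[0]) & \
        (age_completed <= cd.age_range[1])

    lead = (dx - eff["registration_start"]).dt.days
    ok &= lead >= cd.min_registration_lead_days

    dmard_gap = (dx - eff["dmard_date"]).dt.days
    ok &= ~(dmard_gap > cd.dmard_exclusion_lead_days).fillna(False)

    out = pd.DataFrame({
        "patient_id": eff.index[ok],
        "index_date": dx[ok].values,
    }).sort_values("patient_id").reset_index(drop=True)
    return out


def _age_at(eff: pd.DataFrame, at: pd.Timestamp) -> pd.Series:
    years = at.year - eff["birth_date"].dt.year
    had = (eff["birth_date"].dt.month < at.month) | (
        (eff["birth_date"].dt.month == at.month)
        & (eff["birth_date"].dt.day <= at.day))
    return years - (~had).astype(int)


def _eligible_pool(eff: pd.DataFrame, case_id: str, index_date: pd.Timestamp,
                   caliper_years: float, symptomatic: bool) -> list[str]:
    case = eff.loc[case_id]
    at = pd.Timestamp(index_date)
    pool = eff[(eff.index != case_id)
               & (eff["sex"] == case["sex"])
               & (eff["practice_id"] == case["practice_id"])]
    # under observation at the index date
    pool = pool[(pool["registration_start"] <= at)
                & (pool["registration_end"].isna() | (pool["registration_end"] >= at))]
    # AS-free on/at the index date
    pool = pool[pool["as_date"].isna() | (pool["as_date"] > at)]
    case_age = _age_at(eff.loc[[case_id]], at).iloc[0]
    ages = _age_at(pool, at)
    pool = pool[(ages - case_age).abs() <= caliper_years]
    if symptomatic:
        pool = pool[pool["first_spinal"].notna() & (pool["first_spinal"] <= at)]
    return sorted(pool.index)


def _draw(pool: list[str], k: int, rng: np.random.Generator) -> tuple[str, ...]:
    if len(pool) <= k:
        return tuple(pool)
    picks = rng.choice(len(pool), size=k, replace=False)
    return tuple(pool[j] for j in sorted(picks))


def select_population_controls(rs: RecordSet, case_id: str,
                               index_date: pd.Timestamp, k: int = 4,
                               caliper_years: float = 2.0,
                               seed: int = 0) -> MatchedSet | None:
    """Matched population controls for one case; None if the pool is empty."""
    eff = _effective_dates(rs)
    pool = _eligible_pool(eff, case_id, index_date, caliper_years, False)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    ids = _draw(pool, k, rng)
    if not ids:
        return None
    return MatchedSet("population", case_id, ids, pd.Timestamp(index_date))


def select_symptomatic_controls(rs: RecordSet, case_id: str,
                                index_date: pd.Timestamp, k: int = 4,
                                caliper_years: float = 2.0,
                                seed: int = 0) -> MatchedSet | None:
    """Matched symptomatic (spinal-code) controls for one case."""
    eff = _effective_dates(rs)
    pool = _eligible_pool(eff, case_id, index_date, caliper_years, True)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    ids = _draw(pool, k, rng)
    if not ids:
        return None
    return MatchedSet("symptomatic", case_id, ids, pd.Timestamp(index_date))


def build_cohort(rs: RecordSet, cd: CaseDefinition | None = None,
                 k: int = 4, population_caliper_years: float = 2.0,
                 symptomatic_caliper_years: float = 2.0, seed: int = 0,
                 comparisons: tuple[str, ...] = COMPARISONS) -> pd.DataFrame:
    """Full matched cohort for both comparisons.

    Returns one row per member: ``comparison, set_id, role, patient_id,
    index_date``.  Cases without any eligible control in a comparison are
    dropped from that comparison only (logged).  Deterministic under
    (records, seed).
    """
    cd = cd or CaseDefinition()
    eff = _effective_dates(rs)
    cases = find_incident_cases(rs, cd)
    rows: list[dict] = []
    for ci, comparison in enumerate(comparisons):
        caliper = (population_caliper_years if comparison == "population"
                   else symptomatic_caliper_years)
        used: dict[str, int] = {}
        for j, case in cases.iterrows():
            pool = _eligible_pool(eff, case["patient_id"], case["index_date"],
                                  caliper, comparison == "symptomatic")
            rng = np.random.default_rng(np.random.SeedSequence(
                entropy=seed, spawn_key=(ci, int(j))))
            ids = _draw(pool, k, rng)
            if not ids:
                logger.info("case %s: no eligible %s controls; set dropped",
                            case["patient_id"], comparison)
                continue
            set_id = f"{comparison}:{case['patient_id']}"
            rows.append({"comparison": comparison, "set_id": set_id,
                         "role": "case", "patient_id": case["patient_id"],
                         "index_date": case["index_date"]})
            for cid in ids:
                if cid in used:
                    logger.info("control %s reused across cases (%s)",
                                cid, comparison)
                used[cid] = used.get(cid, 0) + 1
                rows.append({"comparison": comparison, "set_id": set_id,
                             "role": "control", "patient_id": cid,
                             "index_date": case["index_date"]})
    cohort = pd.DataFrame(rows, columns=["comparison", "set_id", "role",
                                         "patient_id", "index_date"])
    if not cohort.empty:
        cohort["index_date"] = pd.to_datetime(cohort["index_date"])
    return cohort


def write_cohort(cohort: pd.DataFrame, path) -> None:
    out = cohort.copy()
    out["index_date"] = out["index_date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    cohort = pd.read_csv(path, dtype={"patient_id": str, "set_id": str})
    cohort["index_date"] = pd.to_datetime(cohort["index_date"],
                                          format="%Y-%m-%d")
    return cohort
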