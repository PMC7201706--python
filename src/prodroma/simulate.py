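"""Synthetic coded primary-care records with known ground truth.

No public extract of a UK primary-care database exists for this analysis, so
every downstream stage is exercised on simulated records that reproduce the
statistical structure the method assumes:

* per-category homogeneous Poisson event processes over each patient's
  registration spell, with case-status rate multipliers (rate-ratio
  analogues of the reported effect sizes);
* a linear intensity *ramp* on one category (axial pain by default) for
  cases over the final months before diagnosis, emulating the rising
  pre-diagnosis signal;
* NSAID prescriptions lag-coupled to axial-pain events, so that
  "A within N days of B" proximity composites have something to find;
* an optional under-coding thinning probability, since real symptom coding
  is sparse.

Default rates are calibrated once against the published control-group
3-year prevalences (rate = -ln(1-p)/3 per person-year) and the case
multipliers against the published effect sizes; see docs/methods.md.

The generator draws one pseudo-random substream per patient (spawned by
patient counter from the global seed), so output is reproducible and
independent of patient iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .records import RecordSet
from .vocabulary import CATEGORY_GROUPS, CategoryGroup, EventCategory

_EPOCH = pd.Timestamp("1970-01-01")
DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0

#: control-group baseline event rates, events per person-year
DEFAULT_BASE_RATES: dict[str, float] = {
    "axial_pain": 0.037,
    "other_spine_diagnosis": 0.020,
    "sciatica": 0.009,
    "enthesopathy_tendon": 0.014,
    "large_joint": 0.030,
    "other_joint": 0.005,
    "iritis": 0.001,
    "urethral": 0.001,
    "fatigue": 0.028,
    "ibd": 0.005,
    "other_inflammatory_arthritis": 0.002,
    "fbc": 0.022,
    "esr": 0.006,
    "thyroid_function": 0.015,
    "xray_spine": 0.001,
    "xray_pelvis": 0.0005,
    "ct": 0.001,
    "mri": 0.002,
    "nsaid": 0.076,
    "analgesic": 0.052,
    "opioid": 0.006,
    "tricyclic": 0.017,
    "ssri": 0.040,
}

#: case/control rate ratios (true-effect analogues of the reported ORs)
DEFAULT_CASE_MULTIPLIERS: dict[str, float] = {
    "axial_pain": 3.0,
    "other_spine_diagnosis": 5.0,
    "sciatica": 2.8,
    "enthesopathy_tendon": 3.4,
    "large_joint": 2.7,
    "other_joint": 6.0,
    "iritis": 32.0,
    "urethral": 2.0,
    "fatigue": 1.9,
    "ibd": 7.0,
    "other_inflammatory_arthritis": 4.0,
    "fbc": 5.5,
    "esr": 14.9,
    "thyroid_function": 1.5,
    "xray_spine": 8.0,
    "xray_pelvis": 8.0,
    "ct": 2.0,
    "mri": 1.0,
    "nsaid": 3.5,
    "analgesic": 4.0,
    "opioid": 7.5,
    "tricyclic": 2.9,
    "ssri": 0.6,
}

_TYPE_BY_GROUP = {
    CategoryGroup.SPINAL: "clinical_code",
    CategoryGroup.MUSCULOSKELETAL: "clinical_code",
    CategoryGroup.RELATED_DISORDER: "clinical_code",
    CategoryGroup.DIAGNOSTIC_TEST: "test",
    CategoryGroup.TREATMENT: "prescription",
}


@dataclass(frozen=True)
class RampConfig:
    """Linear pre-diagnosis intensity rise for cases on one category.

    The case rate for ``category`` is multiplied by 1 at
    ``gap_horizon_months`` before diagnosis, rising linearly to
    ``peak_multiplier`` on the diagnosis day (on top of the category's
    constant case multiplier).
    """

    category: str = "axial_pain"
    gap_horizon_months: float = 36.0
    peak_multiplier: float = 4.0


@dataclass(frozen=True)
class CouplingConfig:
    """Chance that an axial-pain event spawns an NSAID prescription
    within a uniform lag of ``lag_days_max`` days."""

    probability: float = 0.5
    lag_days_max: int = 30


@dataclass
class SimulationConfig:
    n_practices: int = 12
    n_patients: int = 4000
    study_start: date = date(2000, 1, 1)
    study_end: date = date(2010, 12, 31)
    case_fraction: float = 0.02
    base_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_RATES))
    case_multipliers: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CASE_MULTIPLIERS))
    ramp: RampConfig | None = field(default_factory=RampConfig)
    nsaid_coupling: CouplingConfig | None = field(default_factory=CouplingConfig)
    male_fraction_cases: float = 0.72
    male_fraction_others: float = 0.49
    #: probability each generated event is dropped (under-coding); default off
    under_coding_prob: float = 0.0
    #: registration opens uniformly this many days before study_start
    registration_lookback_days: tuple[int, int] = (365, 6 * 365)
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.case_fraction < 1:
            raise ConfigError("case_fraction must be in (0, 1)")
        if round(self.case_fraction * self.n_patients) < 1:
            raise ConfigError("case_fraction x n_patients < 1: no cases to simulate")
        if self.n_practices < 1 or self.n_patients < 2:
            raise ConfigError("need >= 1 practice and >= 2 patients")
        for cat, r in self.base_rates.items():
            if cat not in EventCategory._value2member_map_:
                raise ConfigError(f"unknown category in base_rates: {cat!r}")
            if r < 0:
                raise ConfigError(f"negative base rate for {cat}")
        for cat, m in self.case_multipliers.items():
            if cat not in EventCategory._value2member_map_:
                raise ConfigError(f"unknown category in case_multipliers: {cat!r}")
            if m <= 0:
                raise ConfigError(f"non-positive case multiplier for {cat}")
        if self.ramp is not None:
            if self.ramp.category not in EventCategory._value2member_map_:
                raise ConfigError(f"unknown ramp category {self.ramp.category!r}")
            if self.ramp.gap_horizon_months <= 0 or self.ramp.peak_multiplier <= 0:
                raise ConfigError("ramp horizon and peak multiplier must be > 0")
        if self.nsaid_coupling is not None:
            c = self.nsaid_coupling
            if not 0 <= c.probability <= 1 or c.lag_days_max < 0:
                raise ConfigError("invalid nsaid_coupling")
        if not 0 <= self.under_coding_prob < 1:
            raise ConfigError("under_coding_prob must be in [0, 1)")
        if self.study_start >= self.study_end:
            raise ConfigError("study_start must precede study_end")

    @property
    def n_cases(self) -> int:
        return int(round(self.case_fraction * self.n_patients))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "ramp" in raw and raw["ramp"] is not None:
            raw["ramp"] = RampConfig(**raw["ramp"])
        if "nsaid_coupling" in raw and raw["nsaid_coupling"] is not None:
            raw["nsaid_coupling"] = CouplingConfig(**raw["nsaid_coupling"])
        for key in ("study_start", "study_end"):
            if key in raw and isinstance(raw[key], str):
                raw[key] = date.fromisoformat(raw[key])
        if "registration_lookback_days" in raw:
            raw["registration_lookback_days"] = tuple(raw["registration_lookback_days"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["study_start"] = self.study_start.isoformat()
        raw["study_end"] = self.study_end.isoformat()
        raw["registration_lookback_days"] = list(self.registration_lookback_days)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def intensity_at(t_days_before_diagnosis: float, ramp: RampConfig | None,
                 is_case: bool = True) -> float:
    """Rate multiplier applied by the pre-diagnosis ramp at a given lead time.

    Returns 1 for controls, for no ramp, and at/beyond the horizon; rises
    linearly to ``peak_multiplier`` on the diagnosis day.
    """
    if t_days_before_diagnosis < 0:
        raise ValueError("lead time before diagnosis must be >= 0")
    if not is_case or ramp is None:
        return 1.0
    horizon_days = ramp.gap_horizon_months * DAYS_PER_MONTH
    if t_days_before_diagnosis >= horizon_days:
        return 1.0
    frac = 1.0 - t_days_before_diagnosis / horizon_days
    return 1.0 + (ramp.peak_multiplier - 1.0) * frac


def _day(d: date) -> int:
    return (pd.Timestamp(d) - _EPOCH).days


def _homogeneous(rng: np.random.Generator, rate_per_year: float,
                 lo: int, hi: int) -> np.ndarray:
    """Event days of a homogeneous Poisson process on [lo, hi)."""
    span = hi - lo
    if span <= 0 or rate_per_year <= 0:
        return np.empty(0, dtype=np.int64)
    n = rng.poisson(rate_per_year * span / DAYS_PER_YEAR)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    return lo + rng.integers(0, span, size=n).astype(np.int64)


def _ramped(rng: np.random.Generator, rate_per_year: float, lo: int, hi: int,
            dx_day: int, ramp: RampConfig) -> np.ndarray:
    """Inhomogeneous (thinned) Poisson days on [lo, hi) under the ramp."""
    if hi <= lo or rate_per_year <= 0:
        return np.empty(0, dtype=np.int64)
    peak = ramp.peak_multiplier
    span = hi - lo
    n = rng.poisson(rate_per_year * peak * span / DAYS_PER_YEAR)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    days = lo + rng.integers(0, span, size=n).astype(np.int64)
    lead = (dx_day - days).astype(float)
    mult = np.array([intensity_at(t, ramp) for t in lead])
    keep = rng.uniform(size=n) < mult / peak
    return days[keep]


def simulate(cfg: SimulationConfig) -> tuple[RecordSet, pd.DataFrame]:
    """Draw a synthetic RecordSet and its ground truth.

    Returns the records plus a ground-truth frame with one row per patient:
    case status, diagnosis date and realized per-category event counts.
    Identical config (including seed) gives identical output.
    """
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    n_cases = cfg.n_cases
    study_lo, study_hi = _day(cfg.study_start), _day(cfg.study_end)
    lb_lo, lb_hi = cfg.registration_lookback_days
    ramp_cat = cfg.ramp.category if cfg.ramp is not None else None
    ramp_days = (int(round(cfg.ramp.gap_horizon_months * DAYS_PER_MONTH))
                 if cfg.ramp is not None else 0)

    pat_rows: list[dict] = []
    ev_pid: list[str] = []
    ev_day: list[int] = []
    ev_cat: list[str] = []
    ev_typ: list[str] = []
    gt_rows: list[dict] = []

    rated = [(cat, rate) for cat, rate in sorted(cfg.base_rates.items()) if rate > 0]

    for i in range(cfg.n_patients):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=cfg.seed, spawn_key=(i,)))
        pid = f"p{i:06d}"
        is_case = i < n_cases
        practice = f"gp{int(rng.integers(0, cfg.n_practices)):03d}"
        reg_start = study_lo - int(rng.integers(lb_lo, lb_hi + 1))
        obs_end = study_hi

        if is_case:
            sex = "M" if rng.uniform() < cfg.male_fraction_cases else "F"
            dx_day = int(rng.integers(study_lo, study_hi + 1))
            dx_day = max(dx_day, reg_start + 366)  # incident by construction
            age_at_dx = 18.0 + rng.uniform() * 32.0
            birth_day = dx_day - int(round(age_at_dx * DAYS_PER_YEAR))
        else:
            sex = "M" if rng.uniform() < cfg.male_fraction_others else "F"
            dx_day = None
            mid = (study_lo + study_hi) // 2
            age_mid = 18.0 + rng.uniform() * 37.0
            birth_day = mid - int(round(age_mid * DAYS_PER_YEAR))

        days_by_cat: dict[str, np.ndarray] = {}
        for cat, rate in rated:
            mult = cfg.case_multipliers.get(cat, 1.0) if is_case else 1.0
            eff = rate * mult
            if is_case and cat == ramp_cat:
                ramp_lo = max(reg_start, dx_day - ramp_days)
                pre = _homogeneous(rng, eff, reg_start, ramp_lo)
                ramped = _ramped(rng, eff, ramp_lo, dx_day, dx_day, cfg.ramp)
                post = _homogeneous(rng, eff, dx_day, obs_end + 1)
                days = np.concatenate([pre, ramped, post])
            else:
                days = _homogeneous(rng, eff, reg_start, obs_end + 1)
            days_by_cat[cat] = days

        # NSAID prescriptions lag-coupled to axial-pain consultations
        if cfg.nsaid_coupling is not None and cfg.nsaid_coupling.probability > 0:
            pain = days_by_cat.get("axial_pain", np.empty(0, dtype=np.int64))
            if pain.size:
                fire = rng.uniform(size=pain.size) < cfg.nsaid_coupling.probability
                lags = rng.integers(0, cfg.nsaid_coupling.lag_days_max + 1,
                                    size=pain.size)
                coupled = (pain + lags)[fire]
                coupled = coupled[coupled <= obs_end]
                base_nsaid = days_by_cat.get("nsaid", np.empty(0, dtype=np.int64))
                days_by_cat["nsaid"] = np.concatenate([base_nsaid, coupled])

        if cfg.under_coding_prob > 0:
            for cat, days in days_by_cat.items():
                if days.size:
                    keep = rng.uniform(size=days.size) >= cfg.under_coding_prob
                    days_by_cat[cat] = days[keep]

        counts = {f"n_{cat}": 0 for cat in cfg.base_rates}
        for cat, days in days_by_cat.items():
            days = np.sort(days)
            counts[f"n_{cat}"] = int(days.size)
            typ = _TYPE_BY_GROUP[CATEGORY_GROUPS[EventCategory(cat)]]
            ev_pid.extend([pid] * days.size)
            ev_day.extend(days.tolist())
            ev_cat.extend([cat] * days.size)
            ev_typ.extend([typ] * days.size)

        if is_case:
            ev_pid.append(pid)
            ev_day.append(dx_day)
            ev_cat.append("as_diagnosis")
            ev_typ.append("clinical_code")

        pat_rows.append({
            "patient_id": pid,
            "sex": sex,
            "birth_date": birth_day,
            "practice_id": practice,
            "registration_start": reg_start,
            "registration_end": None,
            "as_diagnosis_date": dx_day,
            "first_dmard_date": None,
        })
        gt_rows.append({"patient_id": pid, "is_case": is_case,
                        "diagnosis_day": dx_day, **counts})

    patients = pd.DataFrame(pat_rows)
    for col in ("birth_date", "registration_start", "registration_end",
                "as_diagnosis_date", "first_dmard_date"):
        patients[col] = _EPOCH + pd.to_timedelta(
            pd.array(patients[col], dtype="Int64"), unit="D")
    events = pd.DataFrame({
        "patient_id": ev_pid,
        "date": _EPOCH + pd.to_timedelta(np.asarray(ev_day, dtype=np.int64), unit="D"),
        "category": ev_cat,
        "event_type": ev_typ,
    })
    ground_truth = pd.DataFrame(gt_rows)
    ground_truth["diagnosis_date"] = _EPOCH + pd.to_timedelta(
        pd.array(ground_truth.pop("diagnosis_day"), dtype="Int64"), unit="D")
    front = ["patient_id", "is_case", "diagnosis_date"]
    ground_truth = ground_truth[front + [c for c in ground_truth.columns if c not in front]]
    return RecordSet(patients, events), ground_truth


def write_ground_truth(gt: pd.DataFrame, path: str | Path) -> None:
    out = gt.copy()
    out["diagnosis_date"] = out["diagnosis_date"].dt.strftime("%Y-%m-%d").fillna("")
    out["is_case"] = out["is_case"].astype(int)
    out.to_csv(path, index=False)
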