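"""Temporal feature engineering on coded event streams.

Each feature is a binary presence/absence indicator evaluated over a
horizon: either the whole pre-index record ("any_time") or a 3-year sliding
window whose end sits a configurable gap (0, 3, 6, 12, 18, 24 or 36 calendar
months) before the index date.  Features are either a single category or a
composite built from one of three temporal relations:

* ``proximity`` — any occurrence of X within N days of any occurrence of Y,
  in either order (|date(x) - date(y)| <= N, both in the horizon);
* ``separate`` — two *consecutive* occurrences of X separated by more than
  N days (distinct episodes rather than one multi-code episode);
* ``exclusive`` — at least one X in the horizon and no Y anywhere in the
  patient's available record ("without ever").

Window offsets use calendar months with month-end clamping (Mar 31 minus
1 month is Feb 28/29); windows are half-open ``[start, end)`` so a day never
counts in two adjacent horizons and an index-day event is in no window.

For windowed horizons, patients must have been registered for at least one
year before the window end (the date the gap begins); ineligible members
are flagged so the fitting stage can drop controls individually and whole
sets when the case is ineligible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .records import RecordSet
from .vocabulary import EventCategory

_EPOCH = pd.Timestamp("1970-01-01")

RELATIONS = ("single", "proximity", "separate", "exclusive")
DEFAULT_GAPS = (0, 3, 6, 12, 18, 24, 36)
ANY_TIME = "any_time"


@dataclass(frozen=True)
class FeatureSpec:
    """Declarative description of one single or composite feature."""

    name: str
    relation: str
    primary_category: str
    secondary_category: str | None = None
    threshold_days: int | None = None

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ConfigError(f"unknown relation {self.relation!r}")
        for cat in (self.primary_category, self.secondary_category):
            if cat is not None and cat not in EventCategory._value2member_map_:
                raise ConfigError(f"unknown category {cat!r} in feature {self.name!r}")
        needs_secondary = self.relation in ("proximity", "exclusive")
        if needs_secondary and self.secondary_category is None:
            raise ConfigError(f"{self.relation} feature {self.name!r} needs secondary_category")
        if not needs_secondary and self.secondary_category is not None:
            raise ConfigError(f"{self.relation} feature {self.name!r} takes no secondary_category")
        needs_threshold = self.relation in ("proximity", "separate")
        if needs_threshold and (self.threshold_days is None or self.threshold_days < 0):
            raise ConfigError(f"{self.relation} feature {self.name!r} needs threshold_days >= 0")
        if not needs_threshold and self.threshold_days is not None:
            raise ConfigError(f"{self.relation} feature {self.name!r} takes no threshold_days")


def default_roster() -> list[FeatureSpec]:
    """The standard 19-feature roster: 9 single + 10 composite features."""
    s = FeatureSpec
    return [
        s("axial_pain", "single", "axial_pain"),
        s("other_spine_diagnosis", "single", "other_spine_diagnosis"),
        s("sciatica", "single", "sciatica"),
        s("large_joint", "single", "large_joint"),
        s("other_joint", "single", "other_joint"),
        s("tendon_disorders", "single", "enthesopathy_tendon"),
        s("iritis", "single", "iritis"),
        s("fatigue", "single", "fatigue"),
        s("nsaid", "single", "nsaid"),
        s("axial_pain_within_30d_nsaid", "proximity", "axial_pain", "nsaid", 30),
        s("axial_pain_within_360d_large_joint", "proximity", "axial_pain", "large_joint", 360),
        s("axial_pain_separated_180d", "separate", "axial_pain", None, 180),
        s("axial_pain_separated_360d", "separate", "axial_pain", None, 360),
        s("axial_pain_without_ever_sciatica", "exclusive", "axial_pain", "sciatica"),
        s("tendon_separated_180d", "separate", "enthesopathy_tendon", None, 180),
        s("tendon_within_360d_axial_pain", "proximity", "enthesopathy_tendon", "axial_pain", 360),
        s("fbc_within_90d_axial_pain", "proximity", "fbc", "axial_pain", 90),
        s("esr_within_180d_axial_pain", "proximity", "esr", "axial_pain", 180),
        s("iritis_within_360d_axial_pain", "proximity", "iritis", "axial_pain", 360),
    ]


def roster_from_yaml(path: str | Path) -> list[FeatureSpec]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or []
    return [FeatureSpec(**item) for item in raw]


def roster_to_yaml(specs: list[FeatureSpec], path: str | Path) -> None:
    raw = [
        {k: v for k, v in {
            "name": sp.name, "relation": sp.relation,
            "primary_category": sp.primary_category,
            "secondary_category": sp.secondary_category,
            "threshold_days": sp.threshold_days,
        }.items() if v is not None}
        for sp in specs
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


# -- windows ----------------------------------------------------------------

def window_bounds(index_date, gap_months: int,
                  length_months: int = 36) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Half-open window ``[start, end)`` ending ``gap_months`` calendar
    months before the index date, of ``length_months`` months.

    Month arithmetic clamps at month end (2005-03-31 minus 1 month is
    2005-02-28).
    """
    if gap_months < 0 or length_months <= 0:
        raise ConfigError("gap_months must be >= 0 and length_months > 0")
    idx = pd.Timestamp(index_date)
    end = idx - pd.DateOffset(months=gap_months)
    start = end - pd.DateOffset(months=length_months)
    return start, end


# -- relation primitives (event days as sorted int64 arrays) ----------------

def _in_interval(days: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Days d with lo <= d < hi (input sorted)."""
    i = np.searchsorted(days, lo, side="left")
    j = np.searchsorted(days, hi, side="left")
    return days[i:j]


def single_present(x_days: np.ndarray, lo: int, hi: int) -> bool:
    """At least one event in the half-open interval."""
    return _in_interval(x_days, lo, hi).size > 0


def proximity_present(x_days: np.ndarray, y_days: np.ndarray,
                      threshold_days: int, lo: int, hi: int) -> bool:
    """Some X and some Y, both in the interval, within the threshold of each
    other (inclusive, either order)."""
    xs = _in_interval(x_days, lo, hi)
    ys = _in_interval(y_days, lo, hi)
    if xs.size == 0 or ys.size == 0:
        return False
    pos = np.searchsorted(ys, xs)
    left = np.where(pos > 0, xs - ys[np.maximum(pos - 1, 0)], np.iinfo(np.int64).max)
    right = np.where(pos < ys.size, ys[np.minimum(pos, ys.size - 1)] - xs,
                     np.iinfo(np.int64).max)
    return bool(np.minimum(left, right).min() <= threshold_days)


def separate_present(x_days: np.ndarray, threshold_days: int,
                     lo: int, hi: int) -> bool:
    """Two consecutive in-interval occurrences strictly more than the
    threshold apart (the total span does not count)."""
    xs = np.sort(_in_interval(x_days, lo, hi))
    if xs.size < 2:
        return False
    return bool(np.diff(xs).max() > threshold_days)


def exclusive_present(x_days: np.ndarray, y_days_full_record: np.ndarray,
                      lo: int, hi: int) -> bool:
    """At least one in-interval X and no Y *anywhere* in the record
    ("without ever")."""
    if y_days_full_record.size > 0:
        return False
    return single_present(x_days, lo, hi)


def feature_present(spec: FeatureSpec, days_by_cat: dict[str, np.ndarray],
                    lo: int, hi: int) -> bool:
    empty = np.empty(0, dtype=np.int64)
    x = days_by_cat.get(spec.primary_category, empty)
    if spec.relation == "single":
        return single_present(x, lo, hi)
    if spec.relation == "proximity":
        y = days_by_cat.get(spec.secondary_category, empty)
        return proximity_present(x, y, spec.threshold_days, lo, hi)
    if spec.relation == "separate":
        return separate_present(x, spec.threshold_days, lo, hi)
    y_full = days_by_cat.get(spec.secondary_category, empty)
    return exclusive_present(x, y_full, lo, hi)


# -- matrix -----------------------------------------------------------------

def _event_index(rs: RecordSet, patient_ids: set[str]) -> dict[str, dict[str, np.ndarray]]:
    ev = rs.events[rs.events["patient_id"].isin(patient_ids)]
    days = (ev["date"] - _EPOCH).dt.days.to_numpy(dtype=np.int64)
    index: dict[str, dict[str, np.ndarray]] = {pid: {} for pid in patient_ids}
    frame = pd.DataFrame({"pid": ev["patient_id"].to_numpy(),
                          "cat": ev["category"].to_numpy(), "day": days})
    for (pid, cat), grp in frame.groupby(["pid", "cat"], sort=False):
        index[pid][cat] = np.sort(grp["day"].to_numpy())
    return index


def build_feature_matrix(rs: RecordSet, cohort: pd.DataFrame,
                         specs: list[FeatureSpec] | None = None,
                         gaps: tuple[int, ...] = DEFAULT_GAPS,
                         length_months: int = 36,
                         registration_lead_days: int = 365,
                         eligibility_anchor: str = "end") -> pd.DataFrame:
    """Boolean presence matrix over cohort members and horizons.

    One row per (cohort member, horizon); horizons are ``any_time`` (from
    registration start to the index date) plus ``gap_<g>`` for each gap.
    Columns: the cohort keys, ``horizon``, ``eligible`` (the one-year
    registration rule, anchored at the window end by default, or at the
    window start with ``eligibility_anchor="start"``), then one boolean
    column per feature.
    """
    specs = specs if specs is not None else default_roster()
    names = [sp.name for sp in specs]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate feature names in roster")
    if eligibility_anchor not in ("end", "start"):
        raise ConfigError("eligibility_anchor must be 'end' or 'start'")
    pids = set(cohort["patient_id"])
    ev_index = _event_index(rs, pids)
    reg = rs.patients.set_index("patient_id")["registration_start"]
    reg_days = ((reg - _EPOCH).dt.days).to_dict()

    horizons: list[tuple[str, int | None]] = [(ANY_TIME, None)]
    horizons += [(f"gap_{g}", g) for g in gaps]

    out_rows: list[list] = []
    for row in cohort.itertuples(index=False):
        idx = pd.Timestamp(row.index_date)
        idx_day = (idx - _EPOCH).days
        days_by_cat = ev_index.get(row.patient_id, {})
        rstart = reg_days[row.patient_id]
        for horizon, gap in horizons:
            if gap is None:
                lo, hi = rstart, idx_day
                eligible = True
            else:
                start, end = window_bounds(idx, gap, length_months)
                lo, hi = (start - _EPOCH).days, (end - _EPOCH).days
                anchor = hi if eligibility_anchor == "end" else lo
                eligible = rstart <= anchor - registration_lead_days
            vals = [feature_present(sp, days_by_cat, lo, hi) for sp in specs]
            out_rows.append([row.comparison, row.set_id, row.patient_id,
                             row.role, horizon, eligible, *vals])
    cols = ["comparison", "set_id", "patient_id", "role", "horizon",
            "eligible", *names]
    return pd.DataFrame(out_rows, columns=cols)
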