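"""Window arithmetic and temporal relation semantics, with brute-force
oracles and property tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from prodroma.errors import ConfigError
from prodroma.features import (FeatureSpec, build_feature_matrix,
                               default_roster, exclusive_present,
                               proximity_present, separate_present,
                               single_present, window_bounds)
from prodroma.cohort import build_cohort

from conftest import mk_event, mk_patient, mk_records

A = lambda *xs: np.asarray(sorted(xs), dtype=np.int64)
EMPTY = np.empty(0, dtype=np.int64)
BIG = 10**6


# -- windows ----------------------------------------------------------------

class TestWindowBounds:
    def test_six_month_gap(self):
        start, end = window_bounds(pd.Timestamp("2005-06-01"), 6)
        assert (start, end) == (pd.Timestamp("2001-12-01"), pd.Timestamp("2004-12-01"))

    def test_gap_zero_window_ends_on_index_day_half_open(self):
        start, end = window_bounds(pd.Timestamp("2005-06-01"), 0)
        assert end == pd.Timestamp("2005-06-01")
        day = (end - pd.Timestamp("1970-01-01")).days
        lo = (start - pd.Timestamp("1970-01-01")).days
        assert not single_present(A(day), lo, day)  # index-day event excluded
        assert single_present(A(day - 1), lo, day)

    def test_month_end_clamping(self):
        _, end = window_bounds(pd.Timestamp("2005-03-31"), 1)
        assert end == pd.Timestamp("2005-02-28")

    def test_invalid_months_rejected(self):
        with pytest.raises(ConfigError):
            window_bounds(pd.Timestamp("2005-06-01"), -1)
        with pytest.raises(ConfigError):
            window_bounds(pd.Timestamp("2005-06-01"), 0, length_months=0)

    def test_adjacent_gaps_overlap_iff_less_than_window_length(self):
        idx = pd.Timestamp("2008-01-15")
        gaps = (0, 3, 6, 12, 18, 24, 36)
        for g1 in gaps:
            for g2 in gaps:
                if g1 >= g2:
                    continue
                s1, e1 = window_bounds(idx, g1)
                s2, e2 = window_bounds(idx, g2)
                overlaps = max(s1, s2) < min(e1, e2)
                assert overlaps == (g2 - g1 < 36)


# -- relation semantics -----------------------------------------------------

class TestRelations:
    def test_single_presence(self):
        assert single_present(A(100), 0, BIG)
        assert not single_present(A(100), 200, BIG)
        assert single_present(A(100, 100), 0, BIG)  # duplicates: presence only

    def test_proximity_inclusive_threshold(self):
        assert proximity_present(A(100), A(120), 30, 0, BIG)      # 20 <= 30
        assert proximity_present(A(100), A(130), 30, 0, BIG)      # 30 <= 30
        assert not proximity_present(A(100), A(131), 30, 0, BIG)  # 31 > 30

    def test_proximity_either_order(self):
        assert proximity_present(A(120), A(100), 30, 0, BIG)

    def test_proximity_requires_both_in_window(self):
        assert not proximity_present(A(100), A(120), 30, 110, BIG)
        assert not proximity_present(A(100), EMPTY, 30, 0, BIG)

    def test_separate_strict_consecutive_gaps(self):
        assert separate_present(A(0, 190), 180, 0, BIG)         # 190 > 180
        assert not separate_present(A(0, 90, 180), 180, 0, BIG)  # gaps 90, 90
        assert not separate_present(A(0, 180), 180, 0, BIG)      # 180 not > 180
        assert not separate_present(A(100), 180, 0, BIG)         # one event

    def test_exclusive_scans_entire_record_for_veto(self):
        # sciatica five years before the window still vetoes
        assert not exclusive_present(A(1000), A(-1000), 900, 1100)
        assert exclusive_present(A(1000), EMPTY, 900, 1100)
        assert not exclusive_present(A(100), EMPTY, 900, 1100)  # no X in window

    def test_oracle_agreement_on_random_streams(self):
        """Each relation matches an exhaustive check over event pairs."""
        rng = np.random.default_rng(2024)
        for _ in range(25):
            x = np.sort(rng.integers(0, 400, size=rng.integers(0, 20)))
            y = np.sort(rng.integers(0, 400, size=rng.integers(0, 20)))
            lo, hi = 50, 350
            n = int(rng.integers(0, 120))
            xs = [d for d in x if lo <= d < hi]
            ys = [d for d in y if lo <= d < hi]
            brute_prox = any(abs(a - b) <= n for a in xs for b in ys)
            brute_sep = any(b - a > n for a, b in zip(sorted(xs), sorted(xs)[1:]))
            brute_excl = bool(xs) and y.size == 0
            assert proximity_present(x, y, n, lo, hi) == brute_prox
            assert separate_present(x, n, lo, hi) == brute_sep
            assert exclusive_present(x, y, lo, hi) == brute_excl


day_lists = st.lists(st.integers(0, 500), min_size=0, max_size=15)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(x=day_lists, y=day_lists, n=st.integers(0, 200))
def test_proximity_is_symmetric(x, y, n):
    xa, ya = A(*x), A(*y)
    assert proximity_present(xa, ya, n, 0, 501) == proximity_present(ya, xa, n, 0, 501)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(x=day_lists, y=day_lists, n=st.integers(0, 200),
       lo1=st.integers(0, 250), hi1=st.integers(251, 501),
       grow=st.integers(0, 250))
def test_enlarging_window_never_turns_features_off(x, y, n, lo1, hi1, grow):
    xa, ya = A(*x), A(*y)
    lo2, hi2 = lo1 - grow, hi1 + grow
    if single_present(xa, lo1, hi1):
        assert single_present(xa, lo2, hi2)
    if proximity_present(xa, ya, n, lo1, hi1):
        assert proximity_present(xa, ya, n, lo2, hi2)
    if separate_present(xa, n, lo1, hi1):
        assert separate_present(xa, n, lo2, hi2)


# -- specs and matrix -------------------------------------------------------

class TestFeatureSpec:
    def test_default_roster_shape(self):
        roster = default_roster()
        assert len(roster) == 19
        assert sum(sp.relation == "single" for sp in roster) == 9
        names = [sp.name for sp in roster]
        assert len(set(names)) == 19
        assert "axial_pain_within_30d_nsaid" in names

    @pytest.mark.parametrize("kwargs,msg", [
        (dict(name="f", relation="proximity", primary_category="axial_pain"),
         "needs secondary"),
        (dict(name="f", relation="single", primary_category="axial_pain",
              threshold_days=3), "takes no threshold"),
        (dict(name="f", relation="separate", primary_category="axial_pain"),
         "needs threshold"),
        (dict(name="f", relation="single", primary_category="axial_pani"),
         "unknown category"),
        (dict(name="f", relation="near", primary_category="axial_pain"),
         "unknown relation"),
    ])
    def test_invalid_specs_rejected(self, kwargs, msg):
        with pytest.raises(ConfigError, match=msg):
            FeatureSpec(**kwargs)


def _small_cohort_records():
    patients = [
        mk_patient("case1", dx="2005-06-01", reg="1995-01-01"),
        mk_patient("ctl_long", reg="1995-01-01"),
        # registered six months before the gap-0 window end: ineligible there
        mk_patient("ctl_short", reg="2004-12-01"),
    ]
    events = [
        mk_event("case1", "2005-06-01", "as_diagnosis"),
        mk_event("case1", "2004-08-10", "axial_pain"),
        mk_event("ctl_long", "2004-08-10", "axial_pain"),
    ]
    return mk_records(patients, events)


class TestFeatureMatrix:
    def test_matrix_has_19_feature_columns_per_horizon(self):
        rs = _small_cohort_records()
        cohort = build_cohort(rs, comparisons=("population",))
        m = build_feature_matrix(rs, cohort, gaps=(0, 36))
        meta = {"comparison", "set_id", "patient_id", "role", "horizon", "eligible"}
        assert len(set(m.columns) - meta) == 19
        assert set(m["horizon"]) == {"any_time", "gap_0", "gap_36"}
        # every member appears once per horizon
        assert m.groupby("horizon").size().nunique() == 1

    def test_short_registration_is_ineligible_for_window(self):
        rs = _small_cohort_records()
        cohort = build_cohort(rs, comparisons=("population",))
        m = build_feature_matrix(rs, cohort, gaps=(0,))
        short = m[(m["patient_id"] == "ctl_short") & (m["horizon"] == "gap_0")]
        long = m[(m["patient_id"] == "ctl_long") & (m["horizon"] == "gap_0")]
        assert not short["eligible"].iloc[0]
        assert long["eligible"].iloc[0]
        any_time = m[(m["patient_id"] == "ctl_short") & (m["horizon"] == "any_time")]
        assert any_time["eligible"].iloc[0]

    def test_anchor_switch_changes_eligibility(self):
        rs = _small_cohort_records()
        cohort = build_cohort(rs, comparisons=("population",))
        # anchored at the window *start*, even ctl_long (reg 1995) passes for
        # gap 0; ctl_short (reg 2004-12) fails both anchors
        m = build_feature_matrix(rs, cohort, gaps=(0,), eligibility_anchor="start")
        short = m[(m["patient_id"] == "ctl_short") & (m["horizon"] == "gap_0")]
        assert not short["eligible"].iloc[0]

    def test_empty_event_stream_gives_all_false_row(self):
        rs = mk_records([
            mk_patient("case1", dx="2005-06-01"),
            mk_patient("quiet"),
        ], [mk_event("case1", "2005-06-01", "as_diagnosis")])
        cohort = build_cohort(rs, comparisons=("population",))
        m = build_feature_matrix(rs, cohort, gaps=(0,))
        row = m[(m["patient_id"] == "quiet") & (m["horizon"] == "gap_0")]
        feats = [sp.name for sp in default_roster()]
        assert not row[feats].to_numpy().any()

    def test_unknown_category_in_spec_rejected(self):
        with pytest.raises(ConfigError):
            FeatureSpec("bad", "single", "not_a_category")
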