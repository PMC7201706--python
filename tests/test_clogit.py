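"""Conditional logistic regression: closed forms, likelihood shape,
invariances, oracle agreement and the cross-check against an established
implementation."""

import numpy as np
import pandas as pd
import pytest

from prodroma.clogit import (ConditionalLogit, ExposureSet, fit_all,
                             fit_feature)


def pair(case_exposed, control_exposed, sid="s"):
    return ExposureSet(sid, case_exposed, (control_exposed,))


def random_sets(rng, n_sets=20, max_controls=4):
    sets = []
    for i in range(n_sets):
        m = int(rng.integers(1, max_controls + 1))
        sets.append(ExposureSet(
            f"s{i}", bool(rng.uniform() < 0.5),
            tuple(bool(v) for v in rng.uniform(size=m) < 0.3)))
    return sets


def is_separated(sets):
    return ConditionalLogit(sets).separated


class TestLoglik:
    def test_uniform_at_null_for_one_to_four_set(self):
        model = ConditionalLogit([ExposureSet("s", True, (False,) * 4)])
        assert model.loglike(0.0) == pytest.approx(np.log(1 / 5))
        model2 = ConditionalLogit([ExposureSet("s", False, (True, False, True, False))])
        assert model2.loglike(0.0) == pytest.approx(np.log(1 / 5))

    def test_concordant_data_constant_in_beta(self):
        model = ConditionalLogit([
            ExposureSet("a", True, (True, True)),
            ExposureSet("b", False, (False, False, False)),
        ])
        lls = model.loglike(np.array([-3.0, 0.0, 2.0, 7.0]))
        assert np.allclose(lls, lls[0])
        # exact constants: log(1/3) + log(1/4)
        assert lls[0] == pytest.approx(np.log(1 / 3) + np.log(1 / 4))

    def test_single_discordant_pair_closed_form(self):
        model = ConditionalLogit([pair(True, False)])
        b = np.log(3)
        assert model.loglike(b) == pytest.approx(b - np.log(1 + np.exp(b)))
        assert model.loglike(b) == pytest.approx(np.log(3 / 4))


class TestFit:
    def test_matched_pairs_discordant_ratio(self):
        sets = [pair(True, False, f"a{i}") for i in range(3)] + \
               [pair(False, True, "b0")]
        res = ConditionalLogit(sets).fit()
        assert res.or_point == pytest.approx(3.0, abs=1e-8)
        assert res.n_informative_sets == 4

    def test_equal_discordant_counts_give_or_one(self):
        sets = [pair(True, False, "a"), pair(False, True, "b")]
        res = ConditionalLogit(sets).fit()
        assert res.or_point == pytest.approx(1.0, abs=1e-10)

    def test_case_only_exposure_is_non_estimable(self):
        # mirrors a "-" table cell: every exposed member is a case
        sets = [ExposureSet(f"s{i}", True, (False,) * 4) for i in range(8)]
        res = ConditionalLogit(sets).fit()
        assert not res.estimable
        assert np.isnan(res.or_point)
        assert res.suppressed

    def test_all_concordant_is_non_estimable(self):
        sets = [ExposureSet("s", True, (True,)), ExposureSet("t", False, (False,))]
        assert not ConditionalLogit(sets).fit().estimable

    def test_newton_matches_grid_search(self):
        rng = np.random.default_rng(7)
        grid = np.arange(-10, 10 + 1e-9, 1e-3)
        for _ in range(5):
            sets = random_sets(rng)
            if is_separated(sets):
                continue
            model = ConditionalLogit(sets)
            res = model.fit()
            best = grid[np.argmax(model.loglike(grid))]
            assert abs(res.beta - best) < 1e-3

    def test_counts_match_input(self):
        sets = [ExposureSet("a", True, (True, False, False)),
                ExposureSet("b", False, (True, True))]
        res = ConditionalLogit(sets).fit()
        assert res.n_cases == 2 and res.n_controls == 5
        assert res.n_exposed_cases == 1 and res.n_exposed_controls == 3

    def test_no_sets_rejected(self):
        with pytest.raises(ValueError):
            ConditionalLogit([])

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(11)
        sets = random_sets(rng, 40)
        res = ConditionalLogit(sets).fit()
        lo, hi = res.ci95
        assert lo < res.or_point < hi
        lo99, hi99 = res.conf_int(0.01)
        assert lo99 < lo and hi99 > hi


class TestInvariances:
    def test_concordant_sets_leave_estimate_unchanged(self):
        rng = np.random.default_rng(3)
        sets = random_sets(rng, 15)
        while is_separated(sets):
            sets = random_sets(rng, 15)
        base = ConditionalLogit(sets).fit()
        padded = sets + \
            [ExposureSet(f"c{i}", True, (True, True)) for i in range(50)] + \
            [ExposureSet(f"d{i}", False, (False,)) for i in range(50)]
        res = ConditionalLogit(padded).fit()
        assert abs(res.beta - base.beta) < 1e-10
        assert abs(res.se - base.se) < 1e-10

    def test_flipping_exposures_negates_beta_exactly(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            sets = random_sets(rng, 12)
            if is_separated(sets):
                continue
            res = ConditionalLogit(sets).fit()
            flipped = [ExposureSet(s.set_id, not s.case_exposed,
                                   tuple(not c for c in s.controls_exposed))
                       for s in sets]
            res_f = ConditionalLogit(flipped).fit()
            assert res_f.beta == -res.beta

    def test_summary_renders(self):
        res = ConditionalLogit([pair(True, False, f"x{i}") for i in range(5)]
                               + [pair(False, True, "y")]).fit()
        text = res.summary()
        assert "OR" in text and "95% CI" in text


class TestCrossCheck:
    def test_agrees_with_statsmodels_conditional_logit(self):
        """Independent implementation check on shared fixtures: solve the
        statsmodels conditional-likelihood score equation to high precision
        (its default optimisers stop around 1e-6) and compare estimate and
        observed-information SE."""
        from scipy.optimize import brentq
        from statsmodels.discrete.conditional_models import (
            ConditionalLogit as SMConditionalLogit)

        rng = np.random.default_rng(17)
        for _ in range(5):
            sets = random_sets(rng, 25)
            if is_separated(sets):
                continue
            res = ConditionalLogit(sets).fit()
            y, x, g = [], [], []
            for i, s in enumerate(sets):
                y += [1] + [0] * len(s.controls_exposed)
                x += [int(s.case_exposed)] + [int(c) for c in s.controls_exposed]
                g += [i] * (1 + len(s.controls_exposed))
            sm = SMConditionalLogit(np.array(y), np.array(x)[:, None],
                                    groups=np.array(g))
            beta_sm = brentq(lambda b: sm.score(np.array([b]))[0],
                             -10, 10, xtol=1e-12)
            se_sm = 1.0 / np.sqrt(-sm.hessian(np.array([beta_sm]))[0, 0])
            assert abs(res.beta - beta_sm) < 1e-6
            assert abs(res.se - se_sm) < 1e-6


class TestFitAll:
    def _matrix(self):
        rows = []
        # set A: case exposed+eligible, 2 eligible controls (one exposed)
        rows += [
            dict(comparison="population", set_id="A", patient_id="a0",
                 role="case", horizon="gap_0", eligible=True, f=True),
            dict(comparison="population", set_id="A", patient_id="a1",
                 role="control", horizon="gap_0", eligible=True, f=False),
            dict(comparison="population", set_id="A", patient_id="a2",
                 role="control", horizon="gap_0", eligible=True, f=True),
            dict(comparison="population", set_id="A", patient_id="a3",
                 role="control", horizon="gap_0", eligible=False, f=True),
        ]
        # set B: case ineligible -> whole set dropped
        rows += [
            dict(comparison="population", set_id="B", patient_id="b0",
                 role="case", horizon="gap_0", eligible=False, f=True),
            dict(comparison="population", set_id="B", patient_id="b1",
                 role="control", horizon="gap_0", eligible=True, f=False),
        ]
        # set C: all controls ineligible -> dropped
        rows += [
            dict(comparison="population", set_id="C", patient_id="c0",
                 role="case", horizon="gap_0", eligible=True, f=False),
            dict(comparison="population", set_id="C", patient_id="c1",
                 role="control", horizon="gap_0", eligible=False, f=True),
        ]
        # set D: informative the other way
        rows += [
            dict(comparison="population", set_id="D", patient_id="d0",
                 role="case", horizon="gap_0", eligible=True, f=False),
            dict(comparison="population", set_id="D", patient_id="d1",
                 role="control", horizon="gap_0", eligible=True, f=True),
        ]
        return pd.DataFrame(rows)

    def test_eligibility_drops_sets_and_members(self):
        res = fit_feature(self._matrix(), "f", "population", "gap_0")
        # sets A and D survive; A has 2 controls (ineligible third dropped)
        assert res.n_sets == 2
        assert res.n_controls == 3
        assert res.estimable

    def test_fit_all_table_shape(self):
        table = fit_all(self._matrix(), "population", "gap_0")
        assert list(table["feature"]) == ["f"]
        assert {"or", "ci_low", "ci_high", "pct_cases", "estimable",
                "suppressed"} <= set(table.columns)

    def test_feature_present_everywhere_is_non_estimable(self):
        m = self._matrix().assign(f=True)
        table = fit_all(m, "population", "gap_0")
        assert not table["estimable"].iloc[0]

    def test_sparse_exposure_suppressed_but_estimable(self):
        res = fit_feature(self._matrix(), "f", "population", "gap_0",
                          min_exposed_for_report=5)
        assert res.estimable and res.suppressed
        res2 = fit_feature(self._matrix(), "f", "population", "gap_0",
                           min_exposed_for_report=2)
        assert not res2.suppressed
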