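"""Statistics-module tests, each core routine checked against an
independent oracle (enumeration, closed form, or hand-solved algebra)."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from actdose import (
    TwoByTwo,
    ValidationError,
    chi_square,
    fisher_exact,
    linear_fit,
    logistic_fit,
    odds_ratio,
    summarize_trial,
    sus_score,
    synthetic_bolus_dataset,
    t_test,
    univariate_then_multivariate,
    vif,
)
from actdose.stats import SeparationError


class TestOddsRatio:
    def test_study_below_goal_table(self):
        res = odds_ratio(TwoByTwo(26, 139, 27, 50))
        assert round(res.odds_ratio, 2) == 0.20
        assert round(res.ci_low, 2) == 0.10
        assert round(res.ci_high, 2) == 0.39

    def test_study_above_400_table(self):
        res = odds_ratio(TwoByTwo(7, 139, 10, 50))
        assert round(res.odds_ratio, 2) == 0.21

    def test_equal_proportions_give_unity(self):
        res = odds_ratio(TwoByTwo(10, 50, 20, 100))
        assert res.odds_ratio == pytest.approx(1.0)

    def test_woolf_ci_matches_hand_formula(self):
        a, b, c, d = 26.0, 113.0, 27.0, 23.0
        or_hand = (a / b) / (c / d)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        res = odds_ratio(TwoByTwo(26, 139, 27, 50))
        assert res.odds_ratio == pytest.approx(or_hand, rel=1e-12)
        assert res.ci_low == pytest.approx(
            math.exp(math.log(or_hand) - 1.959963984540054 * se), rel=1e-9
        )

    def test_zero_cell_triggers_haldane(self):
        res = odds_ratio(TwoByTwo(0, 20, 5, 20))
        assert res.corrected
        assert res.odds_ratio > 0.0

    def test_swapping_arms_inverts(self):
        t = TwoByTwo(26, 139, 27, 50)
        s = TwoByTwo(27, 50, 26, 139)
        r, ri = odds_ratio(t), odds_ratio(s)
        assert ri.odds_ratio == pytest.approx(1.0 / r.odds_ratio)
        assert ri.ci_low == pytest.approx(1.0 / r.ci_high)
        assert ri.ci_high == pytest.approx(1.0 / r.ci_low)


class TestChiSquare:
    def test_proportional_table_is_null(self):
        stat, df, p = chi_square([[10, 20], [20, 40]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_statistic(self):
        # margins 30/30, 30/30 -> every expected cell is 15
        obs = np.array([[10.0, 20.0], [20.0, 10.0]])
        expected_stat = ((obs - 15.0) ** 2 / 15.0).sum()
        stat, df, p = chi_square(obs)
        assert stat == pytest.approx(expected_stat, rel=1e-12)
        assert df == 1

    def test_df_for_2x3(self):
        _, df, _ = chi_square([[5, 10, 15], [10, 10, 10]])
        assert df == 2

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            chi_square([[0, 0], [5, 10]])


def enumerate_fisher_p(a, b, c, d):
    """Independent oracle: sum hypergeometric pmf over all tables with the
    observed margins whose probability does not exceed the observed one."""
    r1, n, c1 = a + b, a + b + c + d, a + c
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    pmf = {k: sps.hypergeom.pmf(k, n, r1, c1) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9)))


class TestFisherExact:
    def test_zero_margin_is_one(self):
        assert fisher_exact(TwoByTwo(0, 4, 0, 4)) == pytest.approx(1.0)

    def test_small_table_matches_enumeration(self):
        t = TwoByTwo(3, 4, 1, 4)  # cells {{3,1},{1,3}}
        assert fisher_exact(t) == pytest.approx(enumerate_fisher_p(3, 1, 1, 3),
                                                rel=1e-9)

    def test_transpose_invariance(self):
        # transposing the 2x2 leaves the exact p unchanged
        p1 = fisher_exact(TwoByTwo(3, 10, 2, 8))
        p2 = fisher_exact(TwoByTwo(3, 5, 7, 13))  # transposed cells
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_enumeration_over_moderate_margins(self):
        """Exhaustive agreement on a lattice of tables with margins <= 12."""
        for a, b, c, d in itertools.product(range(0, 13, 3), repeat=4):
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            if a + b > 12 or c + d > 12 or a + c > 12 or b + d > 12:
                continue
            p = fisher_exact(TwoByTwo(a, a + b, c, c + d))
            assert p == pytest.approx(enumerate_fisher_p(a, b, c, d),
                                      rel=1e-9), (a, b, c, d)

    def test_agrees_with_chi_square_when_cells_large(self):
        t = TwoByTwo(40, 100, 60, 100)
        _, _, p_chi = chi_square(t.as_table())
        assert abs(fisher_exact(t) - p_chi) < 0.02


class TestTTest:
    def test_identical_samples_null(self):
        t, df, p = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        # pooled sd = 1, se = sqrt(1*(1/3+1/3)), t = -3/se
        se = math.sqrt(2.0 / 3.0)
        t, df, p = t_test(x, y, pooled=True)
        assert t == pytest.approx(-3.0 / se, rel=1e-12)
        assert df == 4

    def test_scale_invariance(self):
        x = [3.0, 5.0, 9.0, 11.0]
        y = [4.0, 6.0, 7.0, 13.0]
        t1 = t_test(x, y)[0]
        t2 = t_test([7.0 * v for v in x], [7.0 * v for v in y])[0]
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_welch_available(self):
        t_w = t_test([1.0, 2.0, 3.0], [4.0, 9.0, 20.0, 2.0], pooled=False)
        t_s = t_test([1.0, 2.0, 3.0], [4.0, 9.0, 20.0, 2.0], pooled=True)
        assert t_w[1] != t_s[1]  # different degrees of freedom


class TestRegression:
    def test_intercept_only_is_sample_mean(self):
        y = [3.0, 5.0, 7.0, 9.0, 11.0]
        res = linear_fit(y, pd.DataFrame(index=range(5)))
        assert res.table.loc["const", "beta"] == pytest.approx(np.mean(y))

    def test_group_indicator_beta_is_mean_difference(self):
        y = [1.0, 2.0, 3.0, 7.0, 8.0, 9.0]
        g = pd.DataFrame({"g": [0, 0, 0, 1, 1, 1]})
        res = linear_fit(y, g)
        assert res.table.loc["g", "beta"] == pytest.approx(8.0 - 2.0)

    def test_matches_hand_solved_normal_equations(self):
        rng = np.random.default_rng(31)
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"])
        y = rng.normal(size=20)
        res = linear_fit(y, X)
        Xd = np.column_stack([np.ones(20), X.to_numpy()])
        beta_hand = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        got = res.table.loc[["const", "a", "b", "c"], "beta"].to_numpy()
        assert np.allclose(got, beta_hand, rtol=0, atol=1e-8)

    def test_exact_collinearity_names_offender(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        X["b"] = 2.0 * X["a"]
        with pytest.raises(Exception, match="b"):
            linear_fit([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], X)

    def test_logistic_on_grouped_2x2_recovers_or(self):
        """Saturated logistic model: exp(beta) equals the closed-form OR."""
        t = TwoByTwo(26, 139, 27, 50)
        y = [1] * 26 + [0] * 113 + [1] * 27 + [0] * 23
        x = [1.0] * 139 + [0.0] * 50
        res = logistic_fit(y, pd.DataFrame({"exposed": x}))
        got = res.table.loc["exposed", "odds_ratio"]
        want = odds_ratio(t).odds_ratio
        assert got == pytest.approx(want, rel=1e-6)

    def test_perfect_separation_flagged(self):
        y = [0, 0, 0, 0, 1, 1, 1, 1]
        x = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 13.0]})
        with pytest.raises(SeparationError):
            logistic_fit(y, x)

    def test_logistic_requires_both_classes(self):
        with pytest.raises(ValidationError):
            logistic_fit([1, 1, 1, 1, 1],
                         pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0]}))


class TestVif:
    def test_orthogonal_columns_unity(self):
        X = pd.DataFrame({
            "a": [1.0, 1.0, -1.0, -1.0],
            "b": [1.0, -1.0, 1.0, -1.0],
        })
        assert vif(X).to_numpy() == pytest.approx([1.0, 1.0])

    def test_bivariate_closed_form(self):
        """Two columns with correlation rho have VIF = 1/(1-rho^2)."""
        rng = np.random.default_rng(5)
        z1, z2 = rng.normal(size=500), rng.normal(size=500)
        rho_target = 0.8
        x1 = z1
        x2 = rho_target * z1 + math.sqrt(1 - rho_target**2) * z2
        X = pd.DataFrame({"x1": x1, "x2": x2})
        rho = np.corrcoef(x1, x2)[0, 1]
        expected = 1.0 / (1.0 - rho**2)
        assert vif(X).to_numpy() == pytest.approx([expected, expected],
                                                  rel=1e-9)

    def test_constant_column_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        with pytest.raises(ValidationError, match="c"):
            vif(X)

    def test_duplicated_column_infinite(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 5.0]})
        X["a2"] = X["a"]
        v = vif(X)
        assert math.isinf(v["a"]) and math.isinf(v["a2"])


class TestModelSelection:
    def test_single_significant_candidate_collapses(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        noise = rng.normal(size=200)
        y = 3.0 * x + noise
        cands = pd.DataFrame({"x": x, "junk": rng.normal(size=200)})
        sel = univariate_then_multivariate(y, cands)
        assert sel.selected == ["x"]
        uni_beta = sel.univariate.loc["x", "beta"]
        assert sel.model.table.loc["x", "beta"] == pytest.approx(uni_beta)

    def test_duplicated_column_excluded_by_vif(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=300)
        y = 2.0 * x + rng.normal(size=300)
        cands = pd.DataFrame({"x": x, "x_copy": x.copy()})
        sel = univariate_then_multivariate(y, cands)
        assert sorted(sel.promoted) == ["x", "x_copy"]
        assert len(sel.selected) == 1
        assert any(r.startswith("vif") for r in sel.excluded.values())

    def test_weight_preferred_over_bmi(self):
        rng = np.random.default_rng(4)
        y, cands = synthetic_bolus_dataset(500, rng)
        sel = univariate_then_multivariate(y, cands)
        assert "bmi" not in sel.selected
        if "bmi" in sel.promoted:
            assert sel.excluded["bmi"] == "preference:weight"

    def test_recovers_true_predictor_set(self):
        """Known nonzero effects are promoted; the pure null usually not."""
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(50):
            y, cands = synthetic_bolus_dataset(500, rng)
            sel = univariate_then_multivariate(y, cands)
            if sorted(sel.selected) == ["baseline_act", "warfarin", "weight"]:
                hits += 1
        assert hits >= 45


class TestSus:
    @pytest.mark.parametrize(
        "scores, expected",
        [
            ([5, 1, 5, 1, 5, 1, 5, 1, 5, 1], 100.0),
            ([3] * 10, 50.0),
            ([5, 1, 4, 2, 5, 1, 4, 2, 5, 1], 90.0),
        ],
    )
    def test_hand_scored_examples(self, scores, expected):
        assert sus_score(scores) == expected

    def test_granularity_and_range(self):
        for scores in ([1, 5, 1, 5, 1, 5, 1, 5, 1, 5], [2, 4, 3, 2, 5, 1, 4, 3, 2, 4]):
            s = sus_score(scores)
            assert 0.0 <= s <= 100.0
            assert (s / 2.5) == int(s / 2.5)

    def test_requires_ten_items_in_range(self):
        with pytest.raises(ValidationError):
            sus_score([3] * 9)
        with pytest.raises(ValidationError):
            sus_score([3] * 9 + [6])


class TestSummarizeTrial:
    def fig3_table(self):
        """A trial table carrying exactly the published outcome counts."""
        rows = []
        for i in range(50):
            rows.append({
                "arm": "control", "anticoagulant": "apixaban",
                "time_to_goal_min": 33.0, "censored": False,
                "any_below_in_la": i < 27, "any_above_400": i < 10,
                "minutes_below_in_la": 0.0, "total_bolus_units": 12000.0,
            })
        for i in range(139):
            rows.append({
                "arm": "algorithm", "anticoagulant": "apixaban",
                "time_to_goal_min": 17.0, "censored": False,
                "any_below_in_la": i < 26, "any_above_400": i < 7,
                "minutes_below_in_la": 0.0, "total_bolus_units": 12000.0,
            })
        return pd.DataFrame(rows)

    def test_reproduces_published_outcome_statistics(self):
        s = summarize_trial(self.fig3_table())
        assert s.arms["control"].pct_below_in_la == pytest.approx(54.0)
        assert round(s.arms["algorithm"].pct_below_in_la) == 19
        assert s.arms["control"].pct_above_400 == pytest.approx(20.0)
        assert round(s.arms["algorithm"].pct_above_400) == 5
        assert round(s.or_below_in_la.odds_ratio, 2) == 0.20
        assert round(s.or_above_400.odds_ratio, 2) == 0.21

    def test_single_arm_has_no_comparisons(self):
        table = self.fig3_table()
        s = summarize_trial(table[table.arm == "control"])
        assert s.or_below_in_la is None
        assert s.time_to_goal_beta is None

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            summarize_trial(pd.DataFrame(columns=["arm"]))

    def test_report_text_renders(self):
        text = summarize_trial(self.fig3_table()).to_text()
        assert "OR 0.20" in text and "OR 0.21" in text
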