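import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phenoflor import (
    check_assumptions,
    event_summary,
    fit_aov,
    pairwise_bonferroni,
    simple_effects,
    three_factor_screen,
    two_factor_aov,
)
from phenoflor.inference import bonferroni
from tests._oracles import naive_oneway, naive_pooled_t, naive_type2_twoway


def balanced_table(rng, a=3, b=4, r=3, effects=False):
    rows = []
    for i in range(a):
        for j in range(b):
            for _ in range(r):
                mu = 0.3 * i + 0.1 * j + (0.2 * i * j if effects else 0.0)
                rows.append(
                    {
                        "department": f"D{i}",
                        "semester": f"S{j}",
                        "r_i": mu + rng.normal(),
                    }
                )
    return pd.DataFrame(rows)


class TestFitAov:
    def test_balanced_design_type2_equals_sequential(self):
        """On a balanced complete design Type-II SS match Type-I term by term."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(11)
        table = balanced_table(rng, effects=True)
        mine = fit_aov(
            table, "r_i", ["department", "semester"], [("department", "semester")]
        )
        fit = smf.ols('r_i ~ C(department)*C(semester)', table).fit()
        seq = sm.stats.anova_lm(fit, typ=1)
        for term, label in [
            ("department", "C(department)"),
            ("semester", "C(semester)"),
            ("department:semester", "C(department):C(semester)"),
        ]:
            assert mine.table.loc[term, "sum_sq"] == pytest.approx(
                seq.loc[label, "sum_sq"], rel=1e-10
            )

    def test_single_factor_f_is_t_squared(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(
            {"department": ["A"] * 8 + ["B"] * 8, "r_i": rng.normal(size=16)}
        )
        res = fit_aov(table, "r_i", ["department"])
        t, p = stats.ttest_ind(
            table.loc[table.department == "A", "r_i"],
            table.loc[table.department == "B", "r_i"],
        )
        assert res.f_value("department") == pytest.approx(t**2, rel=1e-10)
        assert res.p_value("department") == pytest.approx(p, rel=1e-10)

    def test_unbalanced_toy_matches_residual_ss_subtraction_oracle(self):
        # 2x2 with cell sizes 3/1/2/2.
        table = pd.DataFrame(
            {
                "department": ["A", "A", "A", "A", "B", "B", "B", "B"],
                "semester": ["1st", "1st", "1st", "2nd", "1st", "1st", "2nd", "2nd"],
                "r_i": [0.61, 0.55, 0.70, 0.92, 0.43, 0.49, 0.77, 0.81],
            }
        )
        res = fit_aov(
            table, "r_i", ["department", "semester"], [("department", "semester")]
        )
        oracle = naive_type2_twoway(table.department, table.semester, table.r_i)
        for term, key in [
            ("department", "a"),
            ("semester", "b"),
            ("department:semester", "a:b"),
        ]:
            ss, df, f, p = oracle[key]
            assert res.table.loc[term, "sum_sq"] == pytest.approx(ss, abs=1e-12)
            assert res.table.loc[term, "df"] == df
            assert res.f_value(term) == pytest.approx(f, rel=1e-10)
            assert res.p_value(term) == pytest.approx(p, rel=1e-10)

    def test_matches_statsmodels_type2_on_full_rank_designs(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(3)
        table = balanced_table(rng, a=2, b=3, r=4, effects=True)
        # knock out rows to unbalance (but keep all cells occupied)
        table = table.drop(index=[0, 5, 13]).reset_index(drop=True)
        mine = fit_aov(
            table, "r_i", ["department", "semester"], [("department", "semester")]
        )
        ref = sm.stats.anova_lm(
            smf.ols('r_i ~ C(department)*C(semester)', table).fit(), typ=2
        )
        assert mine.table.loc["department", "sum_sq"] == pytest.approx(
            ref.loc["C(department)", "sum_sq"], rel=1e-10
        )
        assert mine.table.loc["department:semester", "F"] == pytest.approx(
            ref.loc["C(department):C(semester)", "F"], rel=1e-10
        )

    def test_missing_cell_design_raises_unless_dropping_aliased(self):
        rng = np.random.default_rng(4)
        table = balanced_table(rng, a=2, b=2, r=3)
        table = table[
            ~((table.department == "D0") & (table.semester == "S1"))
        ].reset_index(drop=True)
        with pytest.raises(ValueError, match="aliased"):
            fit_aov(
                table, "r_i", ["department", "semester"], [("department", "semester")]
            )
        res = fit_aov(
            table,
            "r_i",
            ["department", "semester"],
            [("department", "semester")],
            on_aliased="drop",
        )
        assert res.table.loc["department:semester", "df"] == 0.0

    def test_single_level_factor_rejected(self):
        table = pd.DataFrame({"department": ["A"] * 5, "r_i": np.arange(5.0)})
        with pytest.raises(ValueError, match="level"):
            fit_aov(table, "r_i", ["department"])

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=10)
    def test_type2_invariant_to_factor_level_ordering(self, seed):
        rng = np.random.default_rng(seed)
        table = balanced_table(rng, a=3, b=2, r=2, effects=True)
        relabel = {"D0": "Z9", "D1": "A0", "D2": "M5"}
        shuffled = table.assign(department=table.department.map(relabel))
        a = fit_aov(
            table, "r_i", ["department", "semester"], [("department", "semester")]
        )
        b = fit_aov(
            shuffled, "r_i", ["department", "semester"], [("department", "semester")]
        )
        np.testing.assert_allclose(
            a.table["sum_sq"].to_numpy(), b.table["sum_sq"].to_numpy(), rtol=1e-9
        )


class TestSimpleEffects:
    def test_identical_site_means_give_f_near_zero(self):
        table = pd.DataFrame(
            {
                "department": ["A", "A", "B", "B"] * 2,
                "semester": ["1st"] * 4 + ["2nd"] * 4,
                "r_i": [0.5, 0.7, 0.5, 0.7] * 2,
            }
        )
        se = simple_effects(table, "r_i")
        assert (se["F"] < 1e-20).all()
        assert not se["significant"].any()

    def test_bonferroni_over_strata(self):
        rng = np.random.default_rng(8)
        table = balanced_table(rng, a=3, b=4, r=3, effects=True)
        se = simple_effects(table, "r_i")
        assert len(se) == 4
        np.testing.assert_allclose(
            se["p_adj"], np.minimum(1.0, 4 * se["p_raw"]), rtol=1e-12
        )

    def test_stratum_f_matches_hand_oneway_anova(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame(
            {
                "department": ["A"] * 4 + ["B"] * 4 + ["C"] * 4,
                "semester": "1st",
                "r_i": rng.normal(size=12),
            }
        )
        se = simple_effects(table, "r_i")
        groups = [table.loc[table.department == d, "r_i"].tolist() for d in "ABC"]
        f, df_b, p = naive_oneway(groups)
        assert se.loc[0, "F"] == pytest.approx(f, rel=1e-10)
        assert se.loc[0, "p_raw"] == pytest.approx(p, rel=1e-10)

    def test_single_site_stratum_skipped(self):
        table = pd.DataFrame(
            {
                "department": ["A", "A", "B", "B", "A", "A"],
                "semester": ["1st"] * 4 + ["2nd"] * 2,
                "r_i": [0.1, 0.2, 0.4, 0.3, 0.2, 0.25],
            }
        )
        se = simple_effects(table, "r_i")
        assert list(se["semester"]) == ["1st"]


class TestPairwiseBonferroni:
    def test_adjustment_arithmetic_and_cap(self):
        np.testing.assert_allclose(bonferroni(0.01, 6), 0.06)
        np.testing.assert_allclose(bonferroni(0.5, 6), 1.0)

    def test_adjusted_p_monotone_in_raw_p_and_m(self):
        p = np.array([0.001, 0.01, 0.02, 0.2])
        adj = bonferroni(p, 5)
        assert (np.diff(adj) >= 0).all()
        assert (bonferroni(p, 10) >= adj).all()

    def test_t_and_p_match_pooled_oracle(self):
        table = pd.DataFrame(
            {
                "department": ["A"] * 4 + ["B"] * 5,
                "semester": "1st",
                "r_i": [0.61, 0.55, 0.70, 0.66, 0.43, 0.49, 0.40, 0.52, 0.47],
            }
        )
        cs = pairwise_bonferroni(table, "r_i")
        t, p = naive_pooled_t(
            table.loc[table.department == "A", "r_i"].tolist(),
            table.loc[table.department == "B", "r_i"].tolist(),
        )
        assert cs.m == 1
        assert cs.frame.loc[0, "t"] == pytest.approx(t, rel=1e-10)
        assert cs.frame.loc[0, "p_raw"] == pytest.approx(p, rel=1e-10)
        assert cs.frame.loc[0, "p_adj"] == cs.frame.loc[0, "p_raw"]

    def test_family_is_pairs_times_strata(self):
        rng = np.random.default_rng(10)
        table = balanced_table(rng, a=4, b=4, r=3)
        cs = pairwise_bonferroni(table, "r_i")
        assert cs.m == 6 * 4
        np.testing.assert_allclose(
            cs.frame["p_adj"], np.minimum(1.0, cs.m * cs.frame["p_raw"]), rtol=1e-12
        )

    def test_tiny_group_skipped(self):
        table = pd.DataFrame(
            {
                "department": ["A", "A", "B", "C", "C"],
                "semester": "1st",
                "r_i": [0.1, 0.2, 0.15, 0.3, 0.4],
            }
        )
        cs = pairwise_bonferroni(table, "r_i")
        assert cs.m == 1  # only A vs C testable
        assert set(cs.frame[["group_a", "group_b"]].iloc[0]) == {"A", "C"}


class TestAssumptions:
    def test_identical_groups_give_levene_statistic_zero(self):
        table = pd.DataFrame(
            {
                "department": ["A"] * 4 + ["B"] * 4,
                "semester": "1st",
                "r_i": [0.1, 0.2, 0.3, 0.4] * 2,
            }
        )
        stat = stats.levene(
            *[g for _, g in table.groupby("department")["r_i"]], center="median"
        ).statistic
        assert stat == pytest.approx(0.0, abs=1e-12)
        rep = check_assumptions(table, "r_i", ["department"])
        assert 0 <= rep.shapiro_p <= 1 and 0 <= rep.levene_p <= 1

    def test_pvalues_in_unit_interval_and_pass_flag(self):
        rng = np.random.default_rng(12)
        table = balanced_table(rng, a=2, b=2, r=6)
        rep = check_assumptions(table, "r_i", ["department", "semester"])
        assert 0 <= rep.shapiro_p <= 1
        assert 0 <= rep.levene_p <= 1
        assert rep.passed == (rep.shapiro_p > 0.05 and rep.levene_p > 0.05)

    def test_shapiro_agrees_with_reference_on_fixed_sample(self):
        # Skewed 10-point sample; residuals of the trivial one-group model
        # are the centred values, so Shapiro on them matches a direct call.
        x = [0.1, 0.2, 0.2, 0.3, 0.4, 0.5, 0.9, 1.8, 3.5, 7.2]
        table = pd.DataFrame(
            {"department": ["A"] * 5 + ["B"] * 5, "semester": "1st", "r_i": x}
        )
        rep = check_assumptions(table, "r_i", ["department"])
        resid = np.concatenate(
            [np.array(x[:5]) - np.mean(x[:5]), np.array(x[5:]) - np.mean(x[5:])]
        )
        assert rep.shapiro_p == pytest.approx(stats.shapiro(resid).pvalue, abs=1e-6)

    def test_constant_response_yields_undefined_signal(self):
        table = pd.DataFrame(
            {"department": ["A", "A", "B", "B"], "semester": "1st", "r_i": [1.0] * 4}
        )
        rep = check_assumptions(table, "r_i", ["department"])
        assert math.isnan(rep.shapiro_p) and math.isnan(rep.levene_p)
        assert not rep.passed


class TestEventSummary:
    def test_single_row_is_its_own_median(self):
        table = pd.DataFrame(
            {
                "department": ["A"],
                "semester": ["1st"],
                "accession": ["X"],
                "event": [7],
            }
        )
        assert event_summary(table)["overall"] == 7

    def test_median_resists_outliers(self):
        table = pd.DataFrame(
            {
                "department": "A",
                "semester": "1st",
                "accession": list("xyz"),
                "event": [2, 2, 15],
            }
        )
        assert event_summary(table)["overall"] == 2

    def test_grouped_medians_match_sort_and_pick(self):
        rng = np.random.default_rng(13)
        table = pd.DataFrame(
            {
                "department": rng.choice(["A", "B"], size=20),
                "semester": rng.choice(["1st", "2nd"], size=20),
                "accession": rng.choice(["x", "y", "z"], size=20),
                "event": rng.integers(0, 26, size=20),
            }
        )
        out = event_summary(table)
        for acc, sub in table.groupby("accession"):
            vals = sorted(sub["event"])
            n = len(vals)
            med = (
                vals[n // 2] if n % 2 else (vals[n // 2 - 1] + vals[n // 2]) / 2
            )
            assert out["by_accession"][acc] == med

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            event_summary(pd.DataFrame(columns=["department", "semester", "accession", "event"]))


class TestThreeFactorScreen:
    def test_screen_reports_accession_terms(self):
        rng = np.random.default_rng(14)
        rows = []
        for d in ("A", "B"):
            for s in ("1st", "2nd"):
                for g in ("x", "y", "z"):
                    for _ in range(2):
                        rows.append(
                            {
                                "department": d,
                                "semester": s,
                                "accession": g,
                                "r_i": rng.normal(0.5 + (d == "B") * 0.2, 0.05),
                            }
                        )
        res = three_factor_screen(pd.DataFrame(rows), "r_i")
        assert {
            "department",
            "semester",
            "accession",
            "department:semester",
            "department:accession",
            "semester:accession",
        } <= set(res.terms)
        assert all(0 <= res.p_value(t) <= 1 for t in res.terms)
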