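"""Statistical engine: chi-square, ANOVA/KW, ANCOVA, Bonferroni, matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from sleepqeeg.stats import (
    AncovaResult,
    DegenerateTableError,
    InsufficientControlsError,
    RankDeficientDesignError,
    ancova_group_comparison,
    anova_from_summary,
    bonferroni,
    format_p,
    kruskal_wallis,
    one_way_anova,
    pearson_chi_square,
    propensity_design,
    propensity_match,
)
from sleepqeeg.synthetic import SyntheticConfig, generate_feature_cohort

COVARIATES = ["age", "sex_female", "ahi", "current_smoking",
              "alcohol_per_day", "tca", "non_tca", "benzodiazepine"]


def chi_square_oracle(table):
    """Brute-force cell loop: chi2 = sum (O-E)^2 / E with margin expectations."""
    t = np.asarray(table, dtype=float)
    total = t.sum()
    chi2 = 0.0
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            e = t[i].sum() * t[:, j].sum() / total
            chi2 += (t[i, j] - e) ** 2 / e
    return chi2


class TestChiSquare:
    def test_uniform_table_gives_zero(self):
        res = pearson_chi_square([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.df == (1.0,)

    def test_agrees_with_cell_loop_oracle(self, rng):
        for _ in range(25):
            t = rng.integers(1, 80, size=(rng.integers(2, 5), rng.integers(2, 4)))
            assert pearson_chi_square(t).statistic == pytest.approx(
                chi_square_oracle(t), abs=1e-12)

    def test_invariant_to_row_and_column_permutation(self, rng):
        t = rng.integers(1, 60, size=(4, 3))
        base = pearson_chi_square(t).statistic
        perm = t[rng.permutation(4)][:, rng.permutation(3)]
        assert pearson_chi_square(perm).statistic == pytest.approx(base, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            pearson_chi_square([[0, 5], [0, 7]])


class TestAnova:
    def test_identical_means_give_f_zero(self):
        values = [1.0, 2.0, 3.0, 0.0, 2.0, 4.0]
        labels = ["a"] * 3 + ["b"] * 3
        assert one_way_anova(values, labels).statistic == 0.0

    def test_two_group_f_equals_t_squared(self, rng):
        for _ in range(10):
            a = rng.normal(0, 1, size=12)
            b = rng.normal(0.5, 1, size=9)
            f = one_way_anova(np.r_[a, b], ["a"] * 12 + ["b"] * 9).statistic
            t = sps.ttest_ind(a, b, equal_var=True).statistic
            assert f == pytest.approx(t ** 2, rel=1e-10)

    def test_raw_and_summary_forms_agree(self, rng):
        groups = [rng.normal(m, 1.3, size=n)
                  for m, n in ((0, 20), (0.4, 15), (0.1, 30))]
        values = np.concatenate(groups)
        labels = sum(([g] * len(v) for g, v in
                      zip("abc", groups)), [])
        raw = one_way_anova(values, labels)
        summ = anova_from_summary([len(g) for g in groups],
                                  [g.mean() for g in groups],
                                  [g.std(ddof=1) for g in groups])
        assert raw.statistic == pytest.approx(summ.statistic, rel=1e-12)
        # and both agree with the reference implementation
        f_ref, p_ref = sps.f_oneway(*groups)
        assert raw.statistic == pytest.approx(f_ref, rel=1e-10)
        assert raw.p_raw == pytest.approx(p_ref, rel=1e-10)

    def test_degenerate_constant_groups_flagged(self):
        res = anova_from_summary([5, 5], [2.0, 2.0], [0.0, 0.0])
        assert res.statistic == 0.0 and res.degenerate


class TestKruskalWallis:
    def test_all_equal_values_give_h_zero(self):
        res = kruskal_wallis([3, 3, 3, 3], ["a", "a", "b", "b"])
        assert res.statistic == 0.0 and res.degenerate

    def test_hand_computed_two_group_case(self):
        # ranks 1,2 vs 3,4 -> H = 12/(4*5) * (2*(1.5-2.5)^2 + 2*(3.5-2.5)^2)
        res = kruskal_wallis([1, 2, 3, 4], ["a", "a", "b", "b"])
        assert res.statistic == pytest.approx(2.4, abs=1e-12)

    @given(st.sampled_from([np.exp, np.cbrt, lambda x: 3 * x + 1]))
    def test_invariant_under_monotone_transform(self, f):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        base = kruskal_wallis(x, labels).statistic
        assert kruskal_wallis(f(x), labels).statistic == pytest.approx(
            base, rel=1e-12)


class TestBonferroni:
    def test_multiplies_and_caps(self):
        assert bonferroni(0.01, 5) == pytest.approx(0.05)
        assert bonferroni(0.5, 10) == 1.0
        assert bonferroni(0.0, 1000) == 0.0

    def test_report_rendering(self):
        assert format_p(bonferroni(0.5, 10)) == ">0.999"
        assert format_p(0.0234) == "0.023"
        assert format_p(1e-5) == "<0.001"

    @given(st.floats(min_value=0, max_value=1),
           st.floats(min_value=1, max_value=20))
    def test_corrected_at_least_raw_and_in_unit_interval(self, p, factor):
        c = bonferroni(p, factor)
        assert p <= c <= 1.0


class TestAncova:
    def test_reduces_to_anova_without_covariates(self, rng):
        y = rng.normal(size=60)
        labels = np.repeat(["NI", "INH", "HNI", "HI"], 15)
        res = ancova_group_comparison(y, labels)
        ref = one_way_anova(y, labels)
        assert res.f_statistic == pytest.approx(ref.statistic, abs=1e-9)
        assert res.p_raw == pytest.approx(ref.p_raw, abs=1e-9)
        assert len(res.posthoc) == 6

    def test_agrees_with_statsmodels_formula_anova(self, rng):
        """Cross-check the extra-SS group F against the formula interface."""
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        n = 120
        df = pd.DataFrame({
            "y": rng.normal(size=n),
            "g": rng.choice(["NI", "INH", "HI"], size=n),
            "x1": rng.normal(size=n),
            "x2": rng.normal(size=n),
        })
        df["y"] += 0.4 * df["x1"] + (df["g"] == "HI") * 0.5
        res = ancova_group_comparison(df["y"], df["g"], df[["x1", "x2"]])
        fit = smf.ols("y ~ C(g) + x1 + x2", data=df).fit()
        table = anova_lm(smf.ols("y ~ x1 + x2", data=df).fit(), fit)
        assert res.f_statistic == pytest.approx(float(table["F"].iloc[1]), rel=1e-9)
        assert res.p_raw == pytest.approx(float(table["Pr(>F)"].iloc[1]), rel=1e-6)

    def test_invariant_to_affine_covariate_rescaling(self, rng):
        n = 90
        y = rng.normal(size=n)
        labels = rng.choice(["NI", "HI"], size=n)
        cov = pd.DataFrame({"age": rng.normal(60, 10, size=n)})
        base = ancova_group_comparison(y, labels, cov)
        scaled = ancova_group_comparison(
            y, labels, pd.DataFrame({"age": 3.7 * cov["age"] - 12.0}))
        assert scaled.f_statistic == pytest.approx(base.f_statistic, rel=1e-9)

    def test_collinear_design_reported(self, rng):
        n = 40
        y = rng.normal(size=n)
        labels = rng.choice(["NI", "HI"], size=n)
        x = rng.normal(size=n)
        cov = pd.DataFrame({"x": x, "x_copy": 2 * x})
        with pytest.raises(RankDeficientDesignError, match="x_copy"):
            ancova_group_comparison(y, labels, cov)

    def test_adjusted_means_at_covariate_means(self, rng):
        n = 200
        labels = np.repeat(["NI", "HI"], n // 2)
        x = rng.normal(size=n)
        y = 1.0 + 0.5 * (labels == "HI") + 2.0 * x + rng.normal(0, 0.1, size=n)
        res = ancova_group_comparison(y, labels, pd.DataFrame({"x": x}))
        diff = res.adjusted_means["HI"] - res.adjusted_means["NI"]
        assert diff == pytest.approx(0.5, abs=0.05)

    def test_posthoc_bonferroni_times_pair_count(self, rng):
        y = rng.normal(size=80)
        labels = np.repeat(["NI", "INH", "HNI", "HI"], 20)
        res = ancova_group_comparison(y, labels)
        for _, row in res.posthoc.iterrows():
            assert row["p_bonferroni"] == pytest.approx(
                min(1.0, row["p_raw"] * 6), abs=1e-12)

    def test_constant_outcome_reports_null_effect(self):
        y = np.full(40, 7.0)
        labels = np.repeat(["NI", "HI"], 20)
        res = ancova_group_comparison(y, labels)
        assert res.f_statistic == 0.0 and res.p_raw == 1.0
        assert not res.posthoc["significant"].any()


class TestPropensityMatching:
    def test_one_to_five_selects_325_unique_controls(self, full_cohort):
        df = full_cohort.participants
        res = propensity_match(df, "HI", "NI", ratio=5, seed=0)
        ids = res.matched_control_ids
        assert len(ids) == 325
        assert len(set(ids)) == 325
        assert all(len(v) == 5 for v in res.matches.values())

    def test_deterministic_given_seed_even_with_identical_covariates(self):
        n = 30
        df = pd.DataFrame({
            "participant_id": [f"p{i}" for i in range(n)],
            "group": ["HI"] * 3 + ["NI"] * 27,
            "age": 60.0, "sex_female": 1, "ahi": 10.0,
            "alcohol_per_day": 1.0, "current_smoking": 0,
            "tca": 0, "non_tca": 0, "benzodiazepine": 0,
        })
        a = propensity_match(df, "HI", "NI", ratio=5, seed=9)
        b = propensity_match(df, "HI", "NI", ratio=5, seed=9)
        assert a.matches == b.matches

    def test_insufficient_controls_rejected(self):
        df = pd.DataFrame({
            "participant_id": [f"p{i}" for i in range(7)],
            "group": ["HI"] * 2 + ["NI"] * 5,
            "age": np.linspace(50, 70, 7), "sex_female": 0, "ahi": 10.0,
            "alcohol_per_day": 1.0, "current_smoking": 0,
            "tca": 0, "non_tca": 0, "benzodiazepine": 0,
        })
        with pytest.raises(InsufficientControlsError):
            propensity_match(df, "HI", "NI", ratio=5, seed=0)

    def test_design_bins_age_and_ahi(self):
        df = pd.DataFrame({
            "age": [45, 55, 65, 75], "sex_female": [0, 1, 0, 1],
            "ahi": [10, 20, 15, 16], "alcohol_per_day": [0, 1, 2, 3],
            "current_smoking": [0, 0, 1, 1], "tca": 0, "non_tca": 0,
            "benzodiazepine": [1, 0, 0, 0],
        })
        d = propensity_design(df)
        assert list(d["age_lt50"]) == [1, 0, 0, 0]
        assert list(d["age_50_59"]) == [0, 1, 0, 0]
        assert list(d["age_60_69"]) == [0, 0, 1, 0]
        assert list(d["ahi_gt15"]) == [0, 1, 0, 1]

    def test_matched_subset_preserves_group_effect_direction(self, full_cohort):
        """The NI-vs-HI sigma elevation survives matched re-analysis."""
        df = full_cohort.participants
        res = propensity_match(df, "HI", "NI", ratio=5, seed=0)
        sub = df[df["participant_id"].isin(res.matched_ids())]
        anc = ancova_group_comparison(
            sub["total_sigma"], sub["group"], sub[COVARIATES])
        assert anc.adjusted_means["HI"] > anc.adjusted_means["NI"]
        assert anc.p_raw < 0.05
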