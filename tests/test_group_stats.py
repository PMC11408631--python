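import numpy as np
import pandas as pd
import pytest
from scipy import stats

from otoprov.group_stats import (
    SingularSSCPError,
    assumption_battery,
    differenced_pearson,
    games_howell,
    kruskal_wallis,
    manova_wilks,
    studentized_range_sf,
)


class TestManova:
    def test_identical_group_means_give_null_result(self):
        x = np.tile(np.arange(10, dtype=float)[:, None], (3, 2))
        x[:, 1] = x[:, 0] ** 2  # any shape, shared across groups
        g = np.repeat(["a", "b", "c"], 10)
        out = manova_wilks(x, g)
        assert out["wilks_lambda"] == pytest.approx(1.0)
        assert out["F"] == pytest.approx(0.0, abs=1e-10)
        assert out["p"] == pytest.approx(1.0)

    def test_single_variable_reduces_to_anova(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=45)
        g = np.repeat(["a", "b", "c"], 15)
        own = manova_wilks(x[:, None], g)
        F, p = stats.f_oneway(x[:15], x[15:30], x[30:])
        assert own["F"] == pytest.approx(F, abs=1e-10)
        assert own["p"] == pytest.approx(p, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_reference(self, seed):
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 4))
        p = int(rng.integers(2, 4))
        ns = rng.integers(p + 2, 15, size=k)
        X = np.concatenate([rng.normal(i * 0.3, 1.0, size=(n, p)) for i, n in enumerate(ns)])
        g = np.concatenate([[f"g{i}"] * n for i, n in enumerate(ns)])
        df = pd.DataFrame(X, columns=[f"y{j}" for j in range(p)])
        df["g"] = g
        formula = "+".join(df.columns[:-1]) + " ~ g"
        ref = MANOVA.from_formula(formula, df).mv_test().results["g"]["stat"]
        wilks = ref.loc["Wilks' lambda"]
        own = manova_wilks(X, g)
        assert own["wilks_lambda"] == pytest.approx(float(wilks["Value"]), abs=1e-8)
        assert own["F"] == pytest.approx(float(wilks["F Value"]), abs=1e-8)
        assert own["df1"] == pytest.approx(float(wilks["Num DF"]))
        assert own["df2"] == pytest.approx(float(wilks["Den DF"]), abs=1e-8)

    def test_singular_within_sscp_raises(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 2))
        X = np.c_[x, x[:, 0] + x[:, 1]]  # exactly collinear
        with pytest.raises(SingularSSCPError):
            manova_wilks(X, np.repeat(["a", "b", "c"], 10))

    def test_null_rejection_rate_calibrated(self):
        """Under a shared multivariate normal, the 5%-level MANOVA rejects in
        4-6% of replicates."""
        rng = np.random.default_rng(12345)
        g = np.repeat(["a", "b", "c"], 15)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            X = rng.normal(size=(45, 3))
            if manova_wilks(X, g)["p"] < 0.05:
                rejections += 1
        assert 0.04 <= rejections / reps <= 0.06


class TestAssumptionBattery:
    def test_identical_groups_give_zero_boxs_m(self):
        x = np.random.default_rng(0).normal(size=(12, 3))
        X = np.vstack([x, x, x])
        g = np.repeat(["a", "b", "c"], 12)
        out = assumption_battery(X, g)
        assert out["boxs_m"]["M"] == pytest.approx(0.0, abs=1e-9)

    def test_duplicated_variable_flags_collinearity(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 2))
        X = np.c_[x, x[:, 0]]
        out = assumption_battery(X, np.repeat(["a", "b"], 15))
        assert out["collinearity_flag"]
        assert not np.isfinite(out["vif"]["x2"]) or out["vif"]["x2"] > 10

    def test_small_group_cells_marked_not_computable(self):
        X = np.random.default_rng(2).normal(size=(12, 3))
        g = np.array(["a"] * 10 + ["b"] * 2)
        out = assumption_battery(X, g)
        assert out["shapiro_wilk"][("b", "x0")] == {"computable": False}
        assert out["mardia"]["b"] == {"computable": False}

    def test_levene_type_I_error_near_nominal(self):
        """Brown-Forsythe Levene rejects at about the nominal 5% rate on
        equal-variance normal data."""
        rng = np.random.default_rng(99)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            X = rng.normal(size=(45, 1))
            out = assumption_battery(X, np.repeat(["a", "b", "c"], 15))
            if out["levene_brown_forsythe"]["x0"]["p"] < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07


class TestKruskalWallis:
    def test_hand_computed_example(self):
        out = kruskal_wallis([1, 2, 3, 4], ["a", "a", "b", "b"])
        assert out["H"] == pytest.approx(2.4)
        assert out["df"] == 1

    def test_identical_data_across_groups_gives_zero(self):
        out = kruskal_wallis([5, 5, 5, 5, 5, 5], ["a", "b", "c"] * 2)
        assert out["H"] == 0.0 and out["p"] == 1.0

    def test_no_ties_means_unit_tie_correction(self):
        out = kruskal_wallis([3.1, 1.2, 5.0, 2.2, 4.4, 0.1], ["a", "a", "a", "b", "b", "b"])
        assert out["tie_correction"] == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, size=40).astype(float)  # heavy ties
        g = rng.choice(["a", "b", "c"], size=40)
        own = kruskal_wallis(x, g)
        H, p = stats.kruskal(*(x[g == c] for c in ["a", "b", "c"]))
        assert own["H"] == pytest.approx(H, abs=1e-12)
        assert own["p"] == pytest.approx(p, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        g = np.repeat(["a", "b", "c"], 10)
        h1 = kruskal_wallis(x, g)["H"]
        h2 = kruskal_wallis(np.exp(x), g)["H"]  # strictly increasing transform
        assert h1 == pytest.approx(h2, abs=1e-12)


class TestStudentizedRange:
    @pytest.mark.parametrize(
        "q,k,df", [(1.0, 3, 5), (2.5, 3, 10), (3.8, 4, 7), (0.5, 2, 30), (5.5, 5, 12)]
    )
    def test_tail_matches_scipy_reference(self, q, k, df):
        assert studentized_range_sf(q, k, df) == pytest.approx(
            stats.studentized_range.sf(q, k, df), abs=1e-4
        )

    def test_nonpositive_q_has_full_tail(self):
        assert studentized_range_sf(0.0, 3, 10) == 1.0

    def test_infinite_df_uses_pure_range_distribution(self):
        assert studentized_range_sf(3.3, 3, np.inf) == pytest.approx(
            stats.studentized_range.sf(3.3, 3, 1e7), abs=1e-4
        )


class TestGamesHowell:
    def test_hand_computed_q_and_welch_df(self):
        out = games_howell([1, 2, 3, 2, 3, 4], ["A"] * 3 + ["B"] * 3)
        row = out.iloc[0]
        assert row["q"] == pytest.approx(np.sqrt(3), abs=1e-12)
        assert row["welch_df"] == pytest.approx(4.0, abs=1e-12)

    def test_identical_groups(self):
        out = games_howell([1, 2, 3, 1, 2, 3], ["A"] * 3 + ["B"] * 3)
        assert out.iloc[0]["q"] == 0.0 and out.iloc[0]["p_adj"] == 1.0

    def test_two_groups_equal_welch_t_test(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, size=14)
        b = rng.normal(0.8, 2.5, size=9)
        out = games_howell(np.r_[a, b], ["A"] * 14 + ["B"] * 9)
        t = stats.ttest_ind(a, b, equal_var=False)
        assert out.iloc[0]["p_adj"] == pytest.approx(t.pvalue, abs=1e-6)

    def test_matches_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(m, s, size=n) for m, s, n in [(0, 1, 12), (0.5, 2, 9), (1.2, 0.7, 15)]])
        g = np.array(["a"] * 12 + ["b"] * 9 + ["c"] * 15)
        own = games_howell(x, g).set_index(["group_i", "group_j"])
        ref = pingouin.pairwise_gameshowell(
            data=pd.DataFrame({"x": x, "g": g}), dv="x", between="g"
        ).set_index(["A", "B"])
        for pair in ref.index:
            mine = own.loc[pair] if pair in own.index else own.loc[(pair[1], pair[0])]
            assert mine["p_adj"] == pytest.approx(float(ref.loc[pair, "pval"]), abs=1e-4)
            assert mine["welch_df"] == pytest.approx(float(ref.loc[pair, "df"]), abs=1e-8)

    def test_table_has_all_pairs_and_p_decreases_in_q(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=40)
        g = np.repeat(["a", "b", "c", "d"], 10)
        out = games_howell(x, g)
        assert len(out) == 6  # k(k-1)/2
        # at fixed (k, df), a larger q must not have a larger p
        p1 = studentized_range_sf(2.0, 4, 10.0)
        p2 = studentized_range_sf(3.0, 4, 10.0)
        assert p2 < p1

    def test_degenerate_zero_variance_pairs(self):
        out = games_howell([1.0, 1.0, 1.0, 1.0], ["A", "A", "B", "B"])
        assert out.iloc[0]["p_adj"] == 1.0 and not out.iloc[0]["degenerate"]
        out2 = games_howell([1.0, 1.0, 2.0, 2.0], ["A", "A", "B", "B"])
        assert out2.iloc[0]["p_adj"] == 0.0 and bool(out2.iloc[0]["degenerate"])


class TestDifferencedPearson:
    def test_identical_series_correlate_perfectly(self):
        s = pd.Series([1.0, 3.0, 2.0, 5.0, 4.0], index=range(2010, 2015))
        out = differenced_pearson(s, s)
        assert out["r"] == pytest.approx(1.0)

    def test_negated_series_anticorrelate(self):
        s = pd.Series([1.0, 3.0, 2.0, 5.0, 4.0], index=range(2010, 2015))
        out = differenced_pearson(s, -s)
        assert out["r"] == pytest.approx(-1.0)

    def test_matches_scipy_on_random_walks(self):
        rng = np.random.default_rng(10)
        years = range(2000, 2020)
        a = pd.Series(np.cumsum(rng.normal(size=20)), index=years)
        b = pd.Series(np.cumsum(rng.normal(size=20)), index=years)
        out = differenced_pearson(a, b)
        r, p = stats.pearsonr(np.diff(a.values), np.diff(b.values))
        assert out["r"] == pytest.approx(r, abs=1e-12)
        assert out["p"] == pytest.approx(p, abs=1e-12)

    def test_constant_differences_flagged(self):
        s = pd.Series(np.arange(5.0), index=range(2010, 2015))  # diffs all 1
        out = differenced_pearson(s, s * 2)
        assert not out["defined"]

    def test_too_few_overlapping_years_rejected(self):
        a = pd.Series([1.0, 2.0], index=[2010, 2011])
        with pytest.raises(ValueError):
            differenced_pearson(a, a)
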