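"""Tests of the one-way tests, covariate adjustment, pointwise profile
comparison and the tract-exclusion rule."""

import numpy as np
import pytest
from scipy import stats

from mmdti import (
    GroupSummary,
    ProfileConfig,
    adjust_covariates,
    anova_from_summaries,
    anova_oneway,
    brown_forsythe,
    chi_square_independence,
    exclude_untrackable_tracts,
    generate_tract_profiles,
    pointwise_profile_test,
    posthoc_pairwise,
    welch_anova,
)
from mmdti.tractstats import TractExcludedError

from oracles import anova_f_from_sums_of_squares, permutation_anova_p


class TestAnovaOneway:
    def test_identical_groups_give_zero(self):
        F, _, p = anova_oneway([[3.0, 3.0, 3.0], [3.0, 3.0, 3.0]])
        assert F == 0.0 and p == 1.0

    def test_matches_sums_of_squares_oracle(self):
        groups = [[1, 2, 3], [2, 3, 4], [3, 4, 5]]
        F, (df1, df2), p = anova_oneway(groups)
        assert F == pytest.approx(anova_f_from_sums_of_squares(groups), rel=1e-12)
        assert (df1, df2) == (2, 6)
        assert p == pytest.approx(stats.f.sf(F, 2, 6))

    def test_matches_scipy(self, rng):
        groups = [rng.normal(size=n) for n in (8, 12, 10)]
        F, _, p = anova_oneway(groups)
        ref = stats.f_oneway(*groups)
        assert F == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_two_groups_equal_pooled_t_squared(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=9), rng.normal(1.0, 1.0, size=6)
            F, _, _ = anova_oneway([a, b])
            t, _ = stats.ttest_ind(a, b)  # pooled-variance t
            assert F == pytest.approx(t ** 2, rel=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0], [1.0, 2.0]])

    def test_rank_ordering_agrees_with_permutation_oracle(self, rng):
        ps, perm_ps = [], []
        for _ in range(30):
            shift = rng.uniform(0, 1.5)
            groups = [rng.normal(i * shift, 1.0, size=5) for i in range(3)]
            _, _, p = anova_oneway(groups)
            ps.append(p)
            perm_ps.append(permutation_anova_p(groups, 600, rng))
        rho = stats.spearmanr(ps, perm_ps).statistic
        assert rho > 0.95


class TestAnovaFromSummaries:
    def test_matches_raw_anova_exactly(self, rng):
        groups = [rng.normal(size=n) for n in (10, 15, 12)]
        summaries = [GroupSummary(len(g), float(g.mean()), float(g.std(ddof=1)))
                     for g in groups]
        F1, dfs1, p1 = anova_oneway(groups)
        F2, dfs2, p2 = anova_from_summaries(summaries)
        assert F1 == pytest.approx(F2, rel=1e-10)
        assert dfs1 == dfs2
        assert p1 == pytest.approx(p2, rel=1e-10)

    def test_equal_means_give_zero(self):
        s = [GroupSummary(10, 5.0, 1.0), GroupSummary(12, 5.0, 2.0)]
        F, _, p = anova_from_summaries(s)
        assert F == 0.0 and p == 1.0

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            GroupSummary(10, 0.0, -1.0)


class TestWelch:
    def test_equal_means_give_zero(self):
        W, _, p = welch_anova([[1.0, -1.0, 0.0], [2.0, -2.0, 0.0]])
        assert W == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_two_groups_equal_welch_t_squared(self, rng):
        for _ in range(20):
            a, b = rng.normal(0, 1, 9), rng.normal(1, 3, 14)
            W, (df1, df2), p = welch_anova([a, b])
            t, pt = stats.ttest_ind(a, b, equal_var=False)
            assert W == pytest.approx(t ** 2, rel=1e-10)
            assert p == pytest.approx(pt, rel=1e-8)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.oneway import anova_oneway as sm_oneway

        groups = [rng.normal(i, 1 + i, size=10 + 3 * i) for i in range(3)]
        W, (df1, df2), p = welch_anova(groups)
        ref = sm_oneway(groups, use_var="unequal", welch_correction=True)
        assert W == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_anova([[1.0, 1.0, 1.0], [2.0, 3.0, 4.0]])


class TestBrownForsythe:
    def test_equal_means_give_zero(self):
        S, _, p = brown_forsythe([[1.0, -1.0, 0.0], [2.0, -2.0, 0.0]])
        assert S == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_balanced_equal_variance_equals_classic_f(self, rng):
        # construct groups with exactly equal sizes and sample variances
        base = rng.normal(size=12)
        base = (base - base.mean()) / base.std(ddof=1)
        groups = [base + shift for shift in (0.0, 0.7, 1.1)]
        S, _, _ = brown_forsythe(groups)
        F, _, _ = anova_oneway(groups)
        assert S == pytest.approx(F, rel=1e-6)

    def test_hand_computed_toy(self):
        # groups {0,2} and {1,5}: n=(2,2), means (1,3), variances (2,8)
        # numerator = 2(1-2)^2 + 2(3-2)^2 = 4; denominator = .5*2 + .5*8 = 5
        # S* = 0.8 ; c = (0.2, 0.8) ; 1/f = 0.04 + 0.64 => df2 = 1/0.68
        S, (df1, df2), _ = brown_forsythe([[0.0, 2.0], [1.0, 5.0]])
        assert S == pytest.approx(0.8, abs=1e-12)
        assert df1 == 1
        assert df2 == pytest.approx(1 / 0.68, abs=1e-9)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.oneway import anova_oneway as sm_oneway

        groups = [rng.normal(i, 1 + i, size=8 + 2 * i) for i in range(3)]
        S, (df1, df2), p = brown_forsythe(groups)
        ref = sm_oneway(groups, use_var="bf")
        # statsmodels' headline pvalue adds Mehrotra's df_num correction;
        # pvalue2/df2 is the standard Brown-Forsythe reference distribution
        assert S == pytest.approx(ref.statistic, rel=1e-10)
        assert (df1, df2) == pytest.approx(ref.df2, rel=1e-10)
        assert p == pytest.approx(ref.pvalue2, rel=1e-10)


def test_three_tests_coincide_in_balanced_equal_variance_limit(rng):
    # Brown-Forsythe equals classic F exactly in this design; Welch's
    # small-sample denominator correction vanishes only as n grows, so the
    # coincidence is checked at large balanced n
    base = rng.normal(size=500_000)
    base = (base - base.mean()) / base.std(ddof=1)
    groups = [base + shift for shift in (0.0, 0.004, 0.009)]
    F, _, _ = anova_oneway(groups)
    W, _, _ = welch_anova(groups)
    S, _, _ = brown_forsythe(groups)
    assert W == pytest.approx(F, rel=1e-6)
    assert S == pytest.approx(F, rel=1e-9)


class TestChiSquare:
    def test_proportional_rows_give_zero(self):
        chi2, df, p = chi_square_independence([[10, 20], [5, 10]])
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_df2_closed_form_survival(self):
        chi2, df, p = chi_square_independence([[13, 20, 18], [21, 27, 21]])
        assert df == 2
        assert p == pytest.approx(np.exp(-chi2 / 2), abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [1, 2]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([[1.5, 2.0], [3.0, 4.0]])


class TestAdjustCovariates:
    def test_perfect_fit_leaves_constant(self, rng):
        age = rng.uniform(60, 80, 50)
        sex = rng.integers(0, 2, 50)
        vals = 2.0 * age
        adj = adjust_covariates(vals, age, sex)
        assert np.allclose(adj, vals.mean(), atol=1e-8)

    def test_grand_mean_preserved(self, rng):
        vals = rng.normal(5, 2, 80)
        adj = adjust_covariates(vals, rng.uniform(60, 80, 80), rng.integers(0, 2, 80))
        assert adj.mean() == pytest.approx(vals.mean(), abs=1e-10)

    def test_independent_values_barely_change(self):
        # expected R^2 of noise on 2 junk covariates is ~2/n, so the
        # before/after correlation should stay near 1 (checked across seeds)
        cors = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            vals = rng.normal(size=200)
            adj = adjust_covariates(vals, rng.uniform(60, 80, 200),
                                    rng.integers(0, 2, 200))
            cors.append(np.corrcoef(vals, adj)[0, 1])
        assert np.median(cors) > 0.99
        assert min(cors) > 0.95

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError):
            adjust_covariates([1.0, 2.0, 3.0], [5.0, 5.0, 5.0], [1, 1, 1])


def profiles_with_effect(n_per_group=40, delta=0.04, seed=0, window=(40, 60)):
    """One-tract profile set with an FA effect of `delta` at `window`."""
    tract = "Left Cingulum Cingulate"
    cfg = ProfileConfig(
        tract_names=(tract,), noise_sd={"FA": 0.04, "MD": 0.04},
        fa_effect_tracts=(), md_effect_tracts=(), tracking_failure_probs={},
        extra_effects=((tract, "FA", "AD", window[0], window[1], -delta),),
        seed=seed)
    groups = {f"n{i}": "NC" for i in range(n_per_group)} | \
             {f"a{i}": "AD" for i in range(n_per_group)}
    rng = np.random.default_rng(seed + 10_000)
    age = {s: float(rng.uniform(60, 80)) for s in groups}
    sex = {s: int(rng.integers(0, 2)) for s in groups}
    return generate_tract_profiles(cfg, groups, age=age, sex=sex), tract


class TestPointwise:
    def test_result_length_is_n_nodes(self, small_profiles):
        res = pointwise_profile_test(small_profiles, "FA", "Left Cingulum Cingulate")
        assert len(res) == 100
        assert set(res.columns) >= {"node", "statistic", "df1", "df2", "p", "significant"}
        assert res["p"].between(0, 1).all()
        assert (res["statistic"] >= 0).all()

    def test_detects_injected_effect(self):
        # 1-sd effect at nodes 40-60, n = 40/group: expect >= 80% of the
        # affected nodes flagged on average over replicates
        hits, total = 0, 0
        for rep in range(20):
            prof, tract = profiles_with_effect(seed=rep)
            res = pointwise_profile_test(prof, "FA", tract,
                                         max_failure_fraction=None)
            sig = res.set_index("node")["significant"]
            hits += int(sig.loc[40:60].sum())
            total += 21
        assert hits / total >= 0.80

    def test_null_false_positive_rate(self):
        # identical group mean curves: raw alpha=0.05 flags ~5% of nodes
        fracs = []
        for rep in range(30):
            prof, tract = profiles_with_effect(delta=0.0, seed=100 + rep)
            res = pointwise_profile_test(prof, "FA", tract,
                                         max_failure_fraction=None)
            fracs.append(res["significant"].mean())
        assert abs(np.mean(fracs) - 0.05) < 0.02

    def test_excluded_tract_refused(self, small_profiles):
        with pytest.raises(TractExcludedError):
            pointwise_profile_test(small_profiles, "FA", "Left Cingulum Hippocampus")

    def test_unknown_test_rejected(self, small_profiles):
        with pytest.raises(ValueError):
            pointwise_profile_test(small_profiles, "FA", "Left IFOF", test="anova2")


class TestPosthoc:
    def test_symmetry_under_group_order_swap(self):
        prof, tract = profiles_with_effect(delta=0.03, seed=5)
        res = posthoc_pairwise(prof, tract, "FA", (40, 60))
        assert len(res) == 1
        # reversing subject order reverses group discovery order: t flips
        # sign, p unchanged
        prof.group = prof.group[::-1]
        prof.fa = prof.fa[::-1]
        prof.md = prof.md[::-1]
        prof.tracked = prof.tracked[::-1]
        prof.age = prof.age[::-1]
        prof.sex = prof.sex[::-1]
        res2 = posthoc_pairwise(prof, tract, "FA", (40, 60))
        assert (res2["group_a"].iloc[0], res2["group_b"].iloc[0]) == \
            (res["group_b"].iloc[0], res["group_a"].iloc[0])
        assert res2["t"].iloc[0] == pytest.approx(-res["t"].iloc[0], rel=1e-9)
        assert res2["p"].iloc[0] == pytest.approx(res["p"].iloc[0], rel=1e-9)

    def test_large_separation_tiny_p(self):
        prof, tract = profiles_with_effect(n_per_group=30, delta=0.2, seed=8)
        res = posthoc_pairwise(prof, tract, "FA", (40, 60))
        assert res["p"].iloc[0] < 1e-6

    def test_null_pvalues_uniform(self):
        # identical groups: pairwise p ~ Uniform(0,1) across replicates
        ps = []
        for rep in range(300):
            rng = np.random.default_rng(rep)
            a, b = rng.normal(size=10), rng.normal(size=10)
            _, p = stats.ttest_ind(a, b)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestExclusion:
    def make_profiles(self, failures):
        cfg = ProfileConfig(noise_sd={"FA": 0.0, "MD": 0.0},
                            tracking_failure_probs={}, seed=0)
        groups = {f"s{i}": "NC" for i in range(120)}
        prof = generate_tract_profiles(cfg, groups)
        for tract, n_fail in failures.items():
            j = prof.tract_index(tract)
            prof.tracked[:n_fail, j] = False
        return prof

    def test_reproduces_18_tract_retention(self):
        prof = self.make_profiles({"Left Cingulum Hippocampus": 62,
                                   "Right Cingulum Hippocampus": 32})
        retained, report = exclude_untrackable_tracts(prof, 0.25)
        assert len(retained) == 18
        assert "Left Cingulum Hippocampus" not in retained
        assert "Right Cingulum Hippocampus" not in retained
        assert report["n_failures"].sum() == 94

    def test_no_failures_retains_all_20(self):
        retained, _ = exclude_untrackable_tracts(self.make_profiles({}), 0.25)
        assert len(retained) == 20

    def test_zero_threshold_drops_any_failure(self):
        prof = self.make_profiles({"Left IFOF": 1})
        retained, _ = exclude_untrackable_tracts(prof, 0.0)
        assert "Left IFOF" not in retained and len(retained) == 19
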