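"""Inferential machinery against closed forms and independent oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from glioconn.stats import (StatsError, anova_oneway, bonferroni_threshold,
                            chi_square_independence, manova_pillai,
                            partial_corr_significance, partial_correlation,
                            posthoc_bonferroni)

STUDY_SIZES = {"control": 27, "IDHmut": 15, "IDHwt": 14}


def study_labels():
    return np.repeat(list(STUDY_SIZES), list(STUDY_SIZES.values()))


class TestManova:
    def test_study_sized_degrees_of_freedom(self, rng):
        res = manova_pillai(study_labels(), rng.standard_normal((56, 3)))
        assert (res.df1, res.df2) == (6, 104)
        assert res.n_per_group == (27, 15, 14)

    def test_matches_statsmodels_pillai(self, rng):
        from statsmodels.multivariate.manova import MANOVA
        labels = study_labels()
        y = rng.standard_normal((56, 3)) + np.where(
            labels == "IDHwt", 0.5, 0.0)[:, None]
        frame = pd.DataFrame(y, columns=["y1", "y2", "y3"])
        frame["g"] = labels
        oracle = MANOVA.from_formula("y1 + y2 + y3 ~ g",
                                     data=frame).mv_test()
        tab = oracle.results["g"]["stat"]
        mine = manova_pillai(labels, y)
        assert mine.pillai_V == pytest.approx(
            tab.loc["Pillai's trace", "Value"], abs=1e-10)
        assert mine.F == pytest.approx(
            tab.loc["Pillai's trace", "F Value"], abs=1e-8)
        assert mine.p == pytest.approx(
            tab.loc["Pillai's trace", "Pr > F"], abs=1e-10)
        assert mine.wilks_lambda == pytest.approx(
            tab.loc["Wilks' lambda", "Value"], abs=1e-10)

    def test_single_dv_reduces_to_anova(self, rng):
        labels = study_labels()
        y = rng.standard_normal(56)
        multi = manova_pillai(labels, y[:, None])
        uni = anova_oneway(labels, y)
        assert multi.F == pytest.approx(uni.F, abs=1e-10)
        assert multi.p == pytest.approx(uni.p, abs=1e-10)
        assert (multi.df1, multi.df2) == (uni.df1, uni.df2)

    def test_invariant_to_relabelling_and_affine_dv_transform(self, rng):
        labels = study_labels()
        y = rng.standard_normal((56, 3))
        base = manova_pillai(labels, y)
        renamed = np.array([{"control": "x", "IDHmut": "y",
                             "IDHwt": "z"}[g] for g in labels])
        scaled = y * np.array([3.0, -0.5, 7.0]) + np.array([1.0, -2.0, 0.1])
        for variant in (manova_pillai(renamed, y),
                        manova_pillai(labels, scaled)):
            assert variant.pillai_V == pytest.approx(base.pillai_V, abs=1e-8)
            assert variant.p == pytest.approx(base.p, abs=1e-8)

    def test_null_rejection_rate_is_calibrated(self):
        rng = np.random.default_rng(2024)
        labels = study_labels()
        n_reps, rejections = 2000, 0
        for _ in range(n_reps):
            res = manova_pillai(labels, rng.standard_normal((56, 3)))
            rejections += res.p < 0.05
        rate = rejections / n_reps
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / n_reps)
        assert 0.05 - half_width < rate < 0.05 + half_width

    def test_collinear_dvs_rejected(self, rng):
        y = rng.standard_normal((56, 2))
        y = np.column_stack([y, y[:, 0] * 2.0])
        with pytest.raises(StatsError, match="rank"):
            manova_pillai(study_labels(), y)

    def test_group_too_small_rejected(self, rng):
        labels = np.array(["a"] * 3 + ["b"] * 10)
        with pytest.raises(StatsError, match="a"):
            manova_pillai(labels, rng.standard_normal((13, 3)))


class TestAnova:
    def test_study_sized_degrees_of_freedom(self, rng):
        res = anova_oneway(study_labels(), rng.standard_normal(56))
        assert (res.df1, res.df2) == (2, 53)

    def test_two_groups_equals_squared_t(self, rng):
        labels = np.repeat(["a", "b"], [12, 9])
        y = rng.standard_normal(21)
        res = anova_oneway(labels, y)
        t, p = scipy.stats.ttest_ind(y[labels == "a"], y[labels == "b"])
        assert res.F == pytest.approx(t ** 2, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_identical_group_means_give_zero_f(self):
        y = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        res = anova_oneway(np.repeat(["a", "b"], 3), y)
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(7)
        labels = study_labels()
        pvals = [anova_oneway(labels, rng.standard_normal(56)).p
                 for _ in range(2000)]
        assert scipy.stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPosthoc:
    def test_bonferroni_multiplies_by_pair_count_and_caps(self, rng):
        labels = study_labels()
        y = rng.standard_normal(56)
        for res in posthoc_bonferroni(labels, y):
            assert res.p_bonferroni == pytest.approx(
                min(1.0, 3 * res.p_raw), abs=1e-12)
            assert res.df == 53

    def test_uses_pooled_error_degrees_of_freedom(self, rng):
        labels = study_labels()
        y = rng.standard_normal(56)
        results = posthoc_bonferroni(labels, y)
        assert {r.df for r in results} == {53}
        assert len(results) == 3

    def test_planted_separation_detected_specifically(self):
        rng = np.random.default_rng(99)
        labels = np.repeat(["g1", "g2", "g3"], 20)
        hits = 0
        n_reps = 500
        for _ in range(n_reps):
            y = rng.normal(np.repeat([0.0, 0.0, 1.0], 20), 0.5)
            res = {frozenset((r.group_a, r.group_b)): r.p_bonferroni
                   for r in posthoc_bonferroni(labels, y)}
            specific = (res[frozenset(("g1", "g3"))] < 0.05
                        and res[frozenset(("g2", "g3"))] < 0.05
                        and res[frozenset(("g1", "g2"))] >= 0.05)
            hits += specific
        assert hits / n_reps >= 0.95


class TestPartialCorrelation:
    def test_residual_method_equals_closed_form(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            x, y, z = rng.standard_normal((3, 25))
            res = partial_correlation(x, y, z[:, None])
            rxy = np.corrcoef(x, y)[0, 1]
            rxz = np.corrcoef(x, z)[0, 1]
            ryz = np.corrcoef(y, z)[0, 1]
            closed = (rxy - rxz * ryz) / np.sqrt(
                (1 - rxz ** 2) * (1 - ryz ** 2))
            assert res.r_partial == pytest.approx(closed, abs=1e-10)

    def test_matches_pingouin(self, rng):
        import pingouin as pg
        frame = pd.DataFrame(rng.standard_normal((40, 3)),
                             columns=["x", "y", "z"])
        oracle = pg.partial_corr(frame, x="x", y="y", covar="z")
        mine = partial_correlation(frame["x"], frame["y"],
                                   frame[["z"]].to_numpy())
        assert mine.r_partial == pytest.approx(float(oracle["r"].iloc[0]),
                                               abs=1e-10)
        assert mine.p_two_sided == pytest.approx(
            float(oracle["p_val"].iloc[0]), abs=1e-10)

    def test_no_covariates_equals_pearson(self, rng):
        x, y = rng.standard_normal((2, 30))
        res = partial_correlation(x, y)
        r, p = scipy.stats.pearsonr(x, y)
        assert res.r_partial == pytest.approx(r, abs=1e-12)
        assert res.p_two_sided == pytest.approx(p, abs=1e-10)
        assert res.df == 28

    def test_irrelevant_covariate_leaves_correlation_untouched(self, rng):
        n = 4000
        z = rng.standard_normal(n)
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        plain = partial_correlation(x, y).r_partial
        partial = partial_correlation(x, y, z[:, None]).r_partial
        assert abs(plain - partial) < 3.0 / np.sqrt(n)

    def test_degrees_of_freedom_account_for_covariates(self, rng):
        x, y = rng.standard_normal((2, 20))
        z = rng.standard_normal((20, 3))
        assert partial_correlation(x, y, z).df == 20 - 2 - 3

    def test_rank_deficient_covariates_rejected(self, rng):
        x, y = rng.standard_normal((2, 20))
        z = rng.standard_normal(20)
        with pytest.raises(StatsError, match="rank"):
            partial_correlation(x, y, np.column_stack([z, 2 * z]))

    def test_zero_residual_variance_rejected(self, rng):
        z = rng.standard_normal(20)
        y = rng.standard_normal(20)
        with pytest.raises(StatsError, match="residual"):
            partial_correlation(3.0 * z + 1.0, y, z[:, None])

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(2000):
            x, y, z = rng.standard_normal((3, 27))
            pvals.append(partial_correlation(x, y, z[:, None]).p_two_sided)
        assert scipy.stats.kstest(pvals, "uniform").pvalue > 0.01


class TestChiSquare:
    def test_perfect_independence(self):
        res = chi_square_independence([[10, 10], [10, 10]])
        assert res.chi2 == pytest.approx(0.0)
        assert res.df == 1
        assert res.p == pytest.approx(1.0)

    def test_hand_worked_two_by_two(self):
        res = chi_square_independence([[20, 10], [10, 20]])
        assert res.chi2 == pytest.approx(4 * 25 / 15)
        assert res.df == 1

    def test_three_by_two_degrees_of_freedom(self):
        res = chi_square_independence([[9, 8], [5, 10], [8, 6]])
        assert res.df == 2

    def test_empty_row_rejected(self):
        with pytest.raises(StatsError):
            chi_square_independence([[0, 0], [5, 10]])


class TestBonferroniThreshold:
    def test_nine_comparison_family(self):
        assert round(bonferroni_threshold(0.05, 9), 3) == 0.006

    def test_identity_for_single_test(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_three_way_family(self):
        assert bonferroni_threshold(0.05, 3) == pytest.approx(0.0166667,
                                                              abs=1e-6)

    def test_invalid_family_rejected(self):
        with pytest.raises(StatsError):
            bonferroni_threshold(0.05, 0)


def test_partial_corr_significance_from_reported_coefficients():
    """Significance recomputed from (r, n) alone matches the full method."""
    rng = np.random.default_rng(3)
    x, y, z = rng.standard_normal((3, 20))
    full = partial_correlation(x, y, z[:, None])
    short = partial_corr_significance(full.r_partial, 20, k=1)
    assert short.p_two_sided == pytest.approx(full.p_two_sided, abs=1e-12)
    assert short.df == full.df
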