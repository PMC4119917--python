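"""Smoothing, orientation, correlation, the test battery, variance partition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sitevar.io import SiteProfile
from sitevar.stats import (
    compare_predictors,
    correlate,
    orient_profile,
    smooth_profile,
    summarize_partitions,
    variance_partition,
)


class TestSmoothing:
    def test_constant_profile_unchanged(self):
        p = SiteProfile(np.full(7, 3.5), "WCN")
        np.testing.assert_allclose(smooth_profile(p).values, 3.5)

    def test_truncated_window_at_termini(self):
        p = SiteProfile([1.0, 2.0, 3.0], "WCN")
        np.testing.assert_allclose(smooth_profile(p).values, [1.5, 2.0, 2.5])

    def test_window_one_is_identity(self):
        p = SiteProfile([4.0, 1.0, 7.0], "EN")
        np.testing.assert_allclose(smooth_profile(p, 1).values, p.values)

    def test_missing_values_excluded_from_local_mean(self):
        p = SiteProfile([1.0, np.nan, 3.0], "EN")
        np.testing.assert_allclose(smooth_profile(p).values, [1.0, 2.0, 3.0])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile(SiteProfile([1.0, 2.0], "EN"), window=2)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=60))
    def test_never_exceeds_original_range(self, values):
        p = SiteProfile(values, "ASA")
        s = smooth_profile(p).values
        assert s.min() >= min(values) - 1e-9
        assert s.max() <= max(values) + 1e-9


class TestOrientation:
    def test_packing_measures_negated(self):
        p = SiteProfile([0.2, 0.5], "WCN")
        np.testing.assert_allclose(orient_profile(p).values, [-0.2, -0.5])

    def test_variability_measures_unchanged(self):
        p = SiteProfile([0.2, 0.5], "CS")
        np.testing.assert_allclose(orient_profile(p).values, [0.2, 0.5])

    def test_double_orientation_is_error(self):
        p = orient_profile(SiteProfile([0.2, 0.5], "KBSP"))
        with pytest.raises(ValueError, match="already oriented"):
            orient_profile(p)


class TestCorrelate:
    def test_affine_transform_gives_unit_pearson(self):
        a = np.array([1.0, 2.0, 4.0, 8.0])
        assert correlate(a, 2 * a + 1) == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        a = np.array([1.0, 2.0, 4.0, 8.0])
        assert correlate(a, -a) == pytest.approx(-1.0)

    def test_monotone_nonlinear_spearman_one_pearson_below(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a**3
        assert correlate(a, b, "spearman") == pytest.approx(1.0)
        assert correlate(a, b, "pearson") < 1.0

    def test_spearman_equals_pearson_on_ranks_without_ties(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        from scipy.stats import rankdata

        assert correlate(x, y, "spearman") == pytest.approx(
            correlate(rankdata(x), rankdata(y), "pearson")
        )

    def test_missing_sites_dropped_pairwise(self):
        a = np.array([1.0, np.nan, 3.0, 4.0, 5.0])
        b = np.array([2.0, 9.0, 6.0, np.nan, 10.0])
        assert correlate(a, b) == pytest.approx(1.0)

    def test_zero_variance_flagged_nan(self):
        assert np.isnan(correlate(np.ones(5), np.arange(5.0)))


class TestCompareBattery:
    def test_uniform_advantage_twenty_proteins(self):
        rng = np.random.default_rng(0)
        rho2 = rng.uniform(0.3, 0.7, size=20)
        rho1 = rho2 + 0.05
        res = compare_predictors(rho1, rho2)
        assert res.proportion_x1_wins == 1.0
        assert res.p_binomial == pytest.approx(0.5**20)
        assert res.delta == pytest.approx(0.05)
        assert res.significant  # t and Wilcoxon are far below 0.01 here

    def test_all_ties_safe_and_not_significant(self):
        rho = np.linspace(0.2, 0.8, 10)
        res = compare_predictors(rho, rho)
        assert res.delta == 0.0
        assert res.proportion_x1_wins == 0.0
        assert not res.significant

    def test_antisymmetry_under_predictor_swap(self, rng):
        rho1 = rng.uniform(0, 1, 15)
        rho2 = rng.uniform(0, 1, 15)
        a = compare_predictors(rho1, rho2)
        b = compare_predictors(rho2, rho1)
        assert a.delta == pytest.approx(-b.delta)
        assert a.proportion_x1_wins == pytest.approx(1 - b.proportion_x1_wins)

    def test_p_values_match_sign_flip_permutation_oracle(self, rng):
        # Monte-Carlo null: flip the sign of each paired difference
        rho2 = rng.uniform(0.3, 0.7, size=20)
        rho1 = rho2 + rng.normal(0.03, 0.04, size=20)
        res = compare_predictors(rho1, rho2)
        d = rho1 - rho2
        n, B = len(d), 100_000
        signs = rng.choice([-1.0, 1.0], size=(B, n))
        flipped = signs * d
        # t statistic under sign-flipping
        t_obs = d.mean() / (d.std(ddof=1) / np.sqrt(n))
        t_null = flipped.mean(1) / (flipped.std(1, ddof=1) / np.sqrt(n))
        p_t_perm = (t_null >= t_obs).mean()
        # Wilcoxon signed-rank statistic (sum of positive ranks)
        from scipy.stats import rankdata

        ranks = rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        w_null = np.where(signs > 0, ranks[None, :], 0.0).sum(1)
        p_w_perm = (w_null >= w_obs).mean()
        mc = 4 / np.sqrt(B)  # generous Monte-Carlo tolerance
        assert abs(res.p_t - p_t_perm) < max(mc, 0.25 * res.p_t + 1e-4)
        assert abs(res.p_wilcoxon - p_w_perm) < max(mc, 0.25 * res.p_wilcoxon + 1e-4)


class TestVariancePartition:
    def test_orthogonal_predictors_have_no_common_part(self):
        x1 = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        x2 = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0])
        y = x1 + x2
        part = variance_partition(y, x1, x2)
        assert part.common == pytest.approx(0.0, abs=1e-12)
        assert part.total_r2 == pytest.approx(1.0)
        assert part.unique_x1 == pytest.approx(np.corrcoef(y, x1)[0, 1] ** 2)

    def test_redundant_noisy_copy(self, rng):
        x1 = rng.normal(size=300)
        x2 = x1 + rng.normal(scale=0.05, size=300)
        y = x1.copy()
        part = variance_partition(y, x1, x2)
        assert part.unique_x2 == pytest.approx(0.0, abs=0.01)
        assert part.common == pytest.approx(
            np.corrcoef(y, x2)[0, 1] ** 2, abs=0.02
        )

    def test_identity_holds_to_machine_precision(self, rng):
        for _ in range(20):
            y, x1, x2 = rng.normal(size=(3, 40))
            part = variance_partition(y, x1, x2)
            assert part.common + part.unique_x1 + part.unique_x2 == (
                pytest.approx(part.total_r2, abs=1e-10)
            )
            assert 0.0 <= part.total_r2 <= 1.0

    def test_unique_equals_r2_increase_from_adding_variable(self, rng):
        # independent OLS oracle: R2 from the normal equations
        y, x1, x2 = rng.normal(size=(3, 60))
        part = variance_partition(y, x1, x2)

        def ols_r2(Xcols):
            X = np.column_stack([np.ones(len(y))] + Xcols)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            return 1 - resid.var() / y.var()

        assert part.total_r2 == pytest.approx(ols_r2([x1, x2]), abs=1e-10)
        assert part.unique_x2 == pytest.approx(
            ols_r2([x1, x2]) - ols_r2([x1]), abs=1e-10
        )

    def test_collinear_predictors_rejected(self):
        x = np.arange(8.0)
        with pytest.raises(ValueError, match="collinear"):
            variance_partition(np.sin(x), x, 2 * x + 3)

    def test_summary_averages_per_protein(self, rng):
        parts = [
            variance_partition(*rng.normal(size=(3, 30))) for _ in range(5)
        ]
        summary = summarize_partitions(parts)
        assert summary.n == 5
        assert summary.mean["total"] == pytest.approx(
            np.mean([p.total_r2 for p in parts])
        )
        assert summary.mean_pct["total"] == pytest.approx(100.0)
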