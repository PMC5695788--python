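"""Correlation testing, thresholding, analytic power, CIs, error balancing."""

import numpy as np
import pytest
from scipy import stats

import voxpower as vp
from oracles import mc_power, pearson_sums


class TestPearsonMap:
    def test_perfect_correlation(self):
        y = np.arange(10.0)
        out = vp.pearson_map(y, y[:, None])
        assert out.r[0] == pytest.approx(1.0)
        assert out.p[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_five_points(self):
        y = np.array([1.0, 2, 3, 4, 5])
        x = np.array([2.0, 1, 4, 3, 5])
        out = vp.pearson_map(y, x[:, None])
        assert out.r[0] == pytest.approx(0.8)
        assert out.r[0] == pytest.approx(pearson_sums(x, y))

    def test_agrees_with_scipy_per_voxel(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(25)
        X = rng.standard_normal((25, 8))
        out = vp.pearson_map(y, X)
        for v in range(8):
            ref = stats.pearsonr(y, X[:, v])
            assert out.r[v] == pytest.approx(ref.statistic, abs=1e-12)
            assert out.p[v] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_t_statistic_identity(self):
        rng = np.random.default_rng(1)
        out = vp.pearson_map(rng.standard_normal(30), rng.standard_normal((30, 5)))
        expected = out.r * np.sqrt((30 - 2) / (1 - out.r**2))
        np.testing.assert_allclose(out.t, expected)

    def test_constant_column_policy(self, caplog):
        y = np.arange(10.0)
        X = np.column_stack([y, np.full(10, 3.0)])
        with caplog.at_level("WARNING", logger="voxpower"):
            out = vp.pearson_map(y, X)
        assert out.r[1] == 0.0 and out.p[1] == 1.0
        assert "constant" in caplog.text

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            vp.pearson_map(np.arange(3.0), np.arange(3.0)[:, None])


class TestCriticalR:
    def test_reference_value(self):
        # t*(28 df, .005 upper) = 2.7633 -> r* = 2.7633/sqrt(2.7633^2 + 28)
        assert vp.critical_r(0.01, 30) == pytest.approx(0.4629, abs=1e-4)

    @pytest.mark.parametrize("alpha,n", [(0.05, 5), (0.01, 30), (0.001, 150)])
    def test_round_trip_with_p_value(self, alpha, n):
        r_star = vp.critical_r(alpha, n)
        t = r_star * np.sqrt((n - 2) / (1 - r_star**2))
        assert 2 * stats.t.sf(t, n - 2) == pytest.approx(alpha, abs=1e-10)

    def test_liberal_limit(self):
        assert vp.critical_r(0.999, 30) < 1e-3

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            vp.critical_r(0.0, 30)
        with pytest.raises(ValueError):
            vp.critical_r(0.05, 3)


class TestThreshold:
    @staticmethod
    def _statmap_from_p(p, n=30):
        p = np.asarray(p, dtype=float)
        t = stats.t.isf(p / 2, n - 2)
        r = t / np.sqrt(t**2 + n - 2)
        return vp.VoxelStatMap(n=n, r=r, t=t, p=p)

    def test_bh_step_up_hand_example(self):
        # .001<=.0125, .02<=.025, .03<=.0375, .2>.05 -> 3 rejections
        stat = self._statmap_from_p([0.001, 0.02, 0.03, 0.2])
        sig = vp.threshold(stat, vp.ThresholdSpec("fdr_bh", 0.05))
        assert sig.sig.tolist() == [True, True, True, False]

    def test_uncorrected_all_below_alpha(self):
        stat = self._statmap_from_p([0.009] * 6)
        sig = vp.threshold(stat, vp.ThresholdSpec("uncorrected", 0.01))
        assert sig.sig.all()

    def test_uncorrected_equals_critical_r_mask(self):
        rng = np.random.default_rng(2)
        stat = vp.pearson_map(rng.standard_normal(30), rng.standard_normal((30, 500)))
        sig = vp.threshold(stat, vp.ThresholdSpec("uncorrected", 0.01))
        by_r = np.abs(stat.r) > vp.critical_r(0.01, 30)
        np.testing.assert_array_equal(sig.sig, by_r)

    def test_bh_empirical_fdr_controlled(self):
        """BH keeps the empirical false-discovery proportion below q on a
        small mixed null/effect simulation."""
        rng = np.random.default_rng(3)
        q, n, reps = 0.05, 30, 2000
        fdp = []
        for _ in range(reps):
            y = rng.standard_normal(n)
            X = rng.standard_normal((n, 50))
            X[:, :20] = 0.8 * y[:, None] + 0.6 * X[:, :20]  # 20 strong effects
            sig = vp.threshold(vp.pearson_map(y, X), vp.ThresholdSpec("fdr_bh", q))
            n_rej = sig.sig.sum()
            fdp.append(sig.sig[20:].sum() / n_rej if n_rej else 0.0)
        assert np.mean(fdp) <= q + 2 * np.std(fdp) / np.sqrt(reps)


class TestPValueCalibration:
    def test_null_p_values_uniform(self):
        """Pooled single-voxel null p-values pass a KS uniformity check."""
        rng = np.random.default_rng(4)
        pvals = [vp.pearson_map(rng.standard_normal(30),
                                rng.standard_normal((30, 1))).p[0]
                 for _ in range(500)]
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3

    def test_null_rejection_rate_matches_alpha(self):
        rng = np.random.default_rng(5)
        stat = vp.pearson_map(rng.standard_normal(30), rng.standard_normal((30, 20000)))
        rate = np.mean(stat.p < 0.05)
        assert rate == pytest.approx(0.05, abs=0.01)


class TestPowerCorrelation:
    def test_exact_matches_monte_carlo_grid(self):
        """Exact quadrature power agrees with a Wishart/Bartlett Monte-Carlo
        oracle over a rho x n x alpha grid."""
        rng = np.random.default_rng(6)
        for rho in (0.1, 0.3, 0.7):
            for n in (10, 30, 150):
                for alpha in (0.05, 0.01, 0.001):
                    exact = vp.power_correlation(rho, n, alpha, method="exact")
                    mc = mc_power(rho, n, alpha, 1_000_000, rng, vp.critical_r)
                    assert exact == pytest.approx(mc, abs=0.003), (rho, n, alpha)

    def test_density_normalized(self):
        from voxpower.core import _exact_r_density
        from scipy import integrate

        for rho, n in [(0.0, 10), (0.3, 30), (0.7, 15)]:
            total, _ = integrate.quad(_exact_r_density, -1, 1, args=(rho, n), limit=200)
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_null_power_equals_alpha(self):
        for alpha in (0.05, 0.01):
            assert vp.power_correlation(0.0, 30, alpha, method="exact") == \
                pytest.approx(alpha, abs=1e-5)

    def test_fisher_approximation_tracks_exact(self):
        for rho in (0.1, 0.3, 0.5):
            for n in (20, 50, 150):
                exact = vp.power_correlation(rho, n, 0.01, method="exact")
                approx = vp.power_correlation(rho, n, 0.01, method="fisher_approx")
                assert approx == pytest.approx(exact, abs=0.01)

    def test_strictly_increasing_in_rho_n_alpha(self):
        by_rho = [vp.power_correlation(r, 30, 0.01) for r in (0.1, 0.3, 0.5, 0.7)]
        by_n = [vp.power_correlation(0.3, n, 0.01) for n in (10, 30, 90, 150)]
        by_alpha = [vp.power_correlation(0.3, 30, a) for a in (0.001, 0.01, 0.05)]
        for seq in (by_rho, by_n, by_alpha):
            assert np.all(np.diff(seq) > 0)

    def test_vectorized_fisher(self):
        out = vp.power_correlation(np.array([0.1, 0.3]), 30, 0.05, method="fisher_approx")
        assert out.shape == (2,) and np.all((0 < out) & (out < 1))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            vp.power_correlation(1.0, 30, 0.05)
        with pytest.raises(ValueError):
            vp.power_correlation(0.3, 30, 0.0)
        with pytest.raises(ValueError):
            vp.power_correlation(0.3, 3, 0.05)


class TestConfidenceInterval:
    def test_symmetric_null_interval(self):
        lo, hi = vp.ci_correlation(0.0, 100, 0.95)
        assert lo == pytest.approx(-0.196, abs=1e-3)
        assert hi == pytest.approx(0.196, abs=1e-3)

    def test_large_sample_width(self):
        lo, hi = vp.ci_correlation(0.3, 10_000, 0.95)
        assert hi - lo < 0.04
        assert lo < 0.3 < hi

    def test_level_collapse(self):
        lo, hi = vp.ci_correlation(0.4, 50, 1e-9)
        assert lo == pytest.approx(0.4, abs=1e-6)
        assert hi == pytest.approx(0.4, abs=1e-6)

    def test_degenerate_perfect_correlation(self, caplog):
        with caplog.at_level("WARNING", logger="voxpower"):
            assert vp.ci_correlation(1.0, 30) == (1.0, 1.0)


class TestBalanceErrorRatio:
    def test_fixed_point_consistency(self, wd_field):
        """Asking for the ratio realized at alpha = .05 returns .05."""
        from voxpower.core import _error_counts_analytic

        counts, _, _ = _error_counts_analytic(wd_field, 30, 0.05)
        fn, fp = counts(0.05)
        alpha = vp.balance_error_ratio(wd_field, 30, target_ratio=fn / fp,
                                       mode="analytic")
        assert alpha == pytest.approx(0.05, abs=1e-3)

    def test_analytic_and_simulation_modes_agree(self, wd_field):
        a_analytic = vp.balance_error_ratio(wd_field, 30, 4.0, mode="analytic")
        a_sim = vp.balance_error_ratio(wd_field, 30, 4.0, mode="sim",
                                       n_reps=2000, seed=11)
        assert abs(a_analytic - a_sim) < 0.02

    def test_ratio_decreasing_in_alpha(self, wd_field):
        from voxpower.core import _error_counts_analytic

        counts, _, _ = _error_counts_analytic(wd_field, 30, 0.05)
        ratios = [fn / fp for fn, fp in (counts(a) for a in (0.01, 0.1, 0.3, 0.6))]
        assert np.all(np.diff(ratios) < 0)

    def test_no_comparison_voxels_rejected(self, wd_field):
        with pytest.raises(vp.UndefinedMetricError):
            vp.balance_error_ratio(wd_field, 30, 4.0, band_min=0.0)

    def test_unreachable_target_reported(self, wd_field):
        with pytest.raises(ValueError, match="no solution"):
            vp.balance_error_ratio(wd_field, 30, 1e9, mode="analytic",
                                   alpha_bounds=(0.2, 0.9))
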