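import numpy as np
import pytest
from scipy import sparse

from pafit import FitConfig, fit_pafit
from pafit.netevents import SuffStats
from pafit.postfit import (
    VarianceReport,
    approx_variances,
    confidence_intervals,
    fit_exponent_cumulative,
    fit_exponent_wls,
    operation_count,
)
from pafit.results import KernelEstimate


def single_step_stats(m_k, n_k):
    m_k = np.asarray(m_k, dtype=np.int64)
    n_k = np.asarray(n_k, dtype=np.int64)
    return SuffStats(
        m_k_t=sparse.csc_matrix(m_k.reshape(-1, 1)),
        n_k_t=sparse.csc_matrix(n_k.reshape(-1, 1)),
        m_t=np.array([int(m_k.sum())]),
        N_t=np.array([int(n_k.sum())]),
        times=np.array([1]),
        K=m_k.size - 1,
        T=1,
    )


class TestVariances:
    def test_b_only_closed_form(self):
        # degree 1 has 4 events and A_hat fixed to 1 -> v = 1/4
        stats = single_step_stats([8, 4], [10, 5])
        fit = fit_pafit(stats, FitConfig(B=2, eps=1e-12))
        var = approx_variances(fit, stats, "B_only")
        assert var.v[1] == pytest.approx(0.25)
        M = stats.m_per_degree()
        np.testing.assert_allclose(var.v, fit.estimate.A_hat**2 / M)

    def test_woodbury_equals_dense_inverse(self, toy_stats):
        fit = fit_pafit(toy_stats, FitConfig(B=toy_stats.K + 1, eps=1e-12))
        vf = approx_variances(fit, toy_stats, "full_inverse")
        vw = approx_variances(fit, toy_stats, "woodbury")
        mask = np.isfinite(vf.v)
        np.testing.assert_array_equal(mask, np.isfinite(vw.v))
        np.testing.assert_allclose(vf.v[mask], vw.v[mask], atol=1e-8)

    def test_b_only_within_factor_of_full(self, linear_stats):
        # fine bins: the low-rank (normalizer-uncertainty) part of the
        # information is small relative to the per-parameter diagonal
        fit = fit_pafit(linear_stats, FitConfig(B=100, eps=1e-10))
        vb = approx_variances(fit, linear_stats, "B_only")
        vf = approx_variances(fit, linear_stats, "full_inverse")
        events = fit.bins.expand(
            np.asarray(fit.bins.aggregate(linear_stats.m_k_t).sum(axis=1)).ravel())
        ref = fit.estimate.reference_degree()
        mask = (np.isfinite(vf.v) & np.isfinite(vb.v) & (events >= 20)
                & (vf.v > 0) & (fit.estimate.degrees != ref))
        ratio = vb.v[mask] / vf.v[mask]
        assert 0.5 <= np.median(ratio) <= 2.0

    def test_operation_count_ordering(self):
        K, T = 2000, 10
        assert (operation_count("B_only", K, T)
                <= operation_count("woodbury", K, T)
                <= operation_count("full_inverse", K, T))

    def test_regularized_fit_rejected(self, linear_stats):
        fit = fit_pafit(linear_stats, FitConfig(B=20, lambda_ratio=0.1))
        with pytest.raises(ValueError, match="unpenalised"):
            approx_variances(fit, linear_stats)


class TestConfidenceIntervals:
    def test_zero_variance_degenerate_interval(self):
        est = KernelEstimate(degrees=np.arange(2), A_hat=np.array([1.0, 2.0]),
                             method="t")
        var = VarianceReport(v=np.zeros(2), method="B_only")
        out = confidence_intervals(est, var)
        np.testing.assert_allclose(out.ci_lower, out.A_hat)
        np.testing.assert_allclose(out.ci_upper, out.A_hat)

    def test_log_scale_closed_form(self):
        # A_hat = 1, sd(log) = 0.1, 95%: bounds exp(+-1.96 * 0.1)
        est = KernelEstimate(degrees=np.arange(2), A_hat=np.ones(2), method="t")
        var = VarianceReport(v=np.full(2, 0.01), method="B_only")
        out = confidence_intervals(est, var, level=0.95)
        assert out.ci_lower[0] == pytest.approx(np.exp(-0.195996), rel=1e-4)
        assert out.ci_upper[0] == pytest.approx(np.exp(0.195996), rel=1e-4)
        assert (out.ci_lower > 0).all()

    def test_monte_carlo_coverage(self):
        """95% intervals from the observed information cover the true kernel
        in 90-99% of single-step experiments, per well-populated degree."""
        rng = np.random.default_rng(7)
        n_k = np.array([50, 30, 20])
        A_true = np.array([1.0, 2.0, 3.0])
        p = n_k * A_true / (n_k * A_true).sum()
        R = 200
        cover = np.zeros(3)
        for _ in range(R):
            m_k = rng.multinomial(400, p)
            stats = single_step_stats(m_k, n_k)
            fit = fit_pafit(stats, FitConfig(B=3, eps=1e-12))
            var = approx_variances(fit, stats, "full_inverse")
            est = confidence_intervals(fit.estimate, var)
            truth = A_true / A_true[fit.estimate.reference_degree()]
            cover += (est.ci_lower <= truth) & (truth <= est.ci_upper)
        for k in (0, 2):  # degree 1 is the scale reference (always covered)
            assert 0.90 <= cover[k] / R <= 0.99


class TestExponentFits:
    def test_wls_exact_on_noiseless_power_law(self):
        k = np.arange(51)
        est = KernelEstimate(degrees=k,
                             A_hat=np.maximum(k, 1).astype(float) ** 1.2,
                             method="t")
        fit = fit_exponent_wls(est)
        assert fit.alpha == pytest.approx(1.2, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)

    def test_wls_scale_invariance_of_exponent(self):
        k = np.arange(31)
        for c in (0.5, 7.0):
            est = KernelEstimate(degrees=k,
                                 A_hat=c * np.maximum(k, 1).astype(float) ** 0.7,
                                 method="t")
            fit = fit_exponent_wls(est)
            assert fit.alpha == pytest.approx(0.7, abs=1e-10)
            assert fit.intercept == pytest.approx(np.log(c), abs=1e-8)

    def test_wls_needs_two_points(self):
        est = KernelEstimate(degrees=np.arange(2),
                             A_hat=np.array([np.nan, 1.0]), method="t")
        with pytest.raises(ValueError, match="at least two"):
            fit_exponent_wls(est)

    def test_cumulative_constant_kernel_gives_zero(self):
        k = np.arange(1001)
        est = KernelEstimate(degrees=k, A_hat=np.ones(k.size), method="t")
        fit = fit_exponent_cumulative(est)
        assert abs(fit.alpha) < 0.05

    def test_cumulative_linear_kernel_gives_one(self):
        k = np.arange(1001)
        est = KernelEstimate(degrees=k, A_hat=k.astype(float), method="t")
        fit = fit_exponent_cumulative(est)
        assert fit.alpha == pytest.approx(1.0, abs=0.05)

    def test_cumulative_needs_two_supported(self):
        est = KernelEstimate(degrees=np.arange(3),
                             A_hat=np.array([np.nan, 2.0, np.nan]), method="t")
        with pytest.raises(ValueError, match="two supported"):
            fit_exponent_cumulative(est)
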