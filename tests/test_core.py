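import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from pafit import FitConfig, TemporalEdgeList, compute_suff_stats, fit_pafit, make_bins
from pafit.core import log_likelihood, mm_update


@pytest.fixture(scope="module")
def two_step_net():
    """K = 2, T = 2 instance with attachment events at degrees 0, 1, 2."""
    edges = [(0, "a", "b"), (0, "b", "c"),
             (1, "d", "b"), (1, "c", "a"),
             (2, "a", "b"), (2, "d", "a"), (2, "b", "d")]
    return TemporalEdgeList(tuple(edges), {"a": 0, "b": 0, "c": 0, "d": 1})


@pytest.fixture(scope="module")
def two_step_stats(two_step_net):
    return compute_suff_stats(two_step_net)


@pytest.fixture(scope="module")
def single_step_stats():
    # seed x->b; step 1: one edge to the degree-0 node, one to the degree-1 node
    net = TemporalEdgeList(((0, "x", "b"), (1, "b", "x"), (1, "x", "b")),
                           {"x": 0, "b": 0})
    return compute_suff_stats(net)


class TestLogLikelihood:
    def test_hand_computed_value(self, single_step_stats):
        # n_0 = n_1 = 1, m_0 = m_1 = 1, A = (1,1): l = 2 log 1 - 2 log 2
        assert log_likelihood([1.0, 1.0], single_step_stats) == pytest.approx(-2 * np.log(2))

    def test_scale_invariance(self, linear_stats):
        rng = np.random.default_rng(0)
        A = rng.uniform(0.5, 3.0, linear_stats.K + 1)
        l1 = log_likelihood(A, linear_stats)
        for c in (0.1, 10.0, 123.4):
            assert log_likelihood(c * A, linear_stats) == pytest.approx(l1, rel=1e-9)

    def test_zero_at_supported_degree_raises(self, single_step_stats):
        with pytest.raises(ValueError, match="positive at every degree"):
            log_likelihood([0.0, 1.0], single_step_stats)

    def test_vanishing_normalizer_raises(self, single_step_stats):
        with pytest.raises(ValueError):
            log_likelihood([0.0, 0.0], single_step_stats)


class TestMMUpdate:
    def test_single_step_fixed_point_is_ratio(self, single_step_stats):
        A1 = mm_update(np.ones(2), single_step_stats)
        ratio = A1 / A1[0]
        # m_k / n_k = (1/1, 1/1) -> constant after normalization
        np.testing.assert_allclose(ratio, [1.0, 1.0])
        np.testing.assert_allclose(mm_update(A1, single_step_stats), A1)

    def test_update_never_decreases_likelihood(self, linear_stats):
        rng = np.random.default_rng(1)
        bins = make_bins(linear_stats.K, 15)
        A = bins.expand(rng.uniform(0.2, 5.0, bins.B))
        prev = log_likelihood(A, linear_stats)
        for _ in range(100):
            A = mm_update(A, linear_stats, bins)
            cur = log_likelihood(A, linear_stats)
            assert cur >= prev - 1e-8 * (abs(prev) + 1)
            prev = cur

    def test_mm_limit_matches_grid_search(self, two_step_stats):
        """Dense two-stage grid search over (A_0, A_2) with A_1 = 1 finds the
        same maximizer as the MM iteration, to three decimals."""
        fit = fit_pafit(two_step_stats, FitConfig(B=3, eps=1e-13))
        omega = fit.omega

        def best_on(grid0, grid2):
            best, arg = -np.inf, None
            for a0 in grid0:
                for a2 in grid2:
                    ll = log_likelihood(np.array([a0, 1.0, a2]), two_step_stats)
                    if ll > best:
                        best, arg = ll, (a0, a2)
            return best, arg

        _, (a0, a2) = best_on(np.linspace(0.05, 5, 120), np.linspace(0.05, 5, 120))
        _, (a0, a2) = best_on(np.linspace(a0 - 0.1, a0 + 0.1, 201),
                              np.linspace(a2 - 0.1, a2 + 0.1, 201))
        assert omega[0] == pytest.approx(a0, abs=1e-3)
        assert omega[2] == pytest.approx(a2, abs=1e-3)


class TestFitPafit:
    def test_single_step_closed_form(self, single_step_stats):
        fit = fit_pafit(single_step_stats, FitConfig(B=2, eps=1e-10))
        est = fit.estimate
        np.testing.assert_allclose(est.A_hat, [1.0, 1.0])  # m_k/n_k up to scale
        assert fit.converged

    def test_reference_degree_normalization(self, linear_stats):
        fit = fit_pafit(linear_stats, FitConfig(B=20))
        assert fit.estimate.A_hat[1] == pytest.approx(1.0)
        assert "degree 1" in fit.estimate.normalization

    def test_trace_monotone_unregularized(self, linear_stats):
        fit = fit_pafit(linear_stats, FitConfig(B=20, eps=1e-10))
        tr = fit.loglik_trace
        assert (np.diff(tr) >= -1e-8 * (np.abs(tr[:-1]) + 1)).all()

    def test_trace_monotone_regularized(self, linear_stats):
        fit = fit_pafit(linear_stats, FitConfig(B=20, lambda_ratio=0.5, eps=1e-10))
        tr = fit.loglik_trace
        assert fit.converged
        assert (np.diff(tr) >= -1e-8 * (np.abs(tr[:-1]) + 1)).all()

    def test_two_random_starts_reach_same_global_maximum(self, linear_stats):
        rng = np.random.default_rng(9)
        cfg = FitConfig(B=20, eps=1e-12)
        fits = [fit_pafit(linear_stats, cfg, start=rng.uniform(0.1, 10.0, 20))
                for _ in range(2)]
        l0, l1 = (f.loglik_trace[-1] for f in fits)
        assert abs(l0 - l1) / (abs(l0) + 1) < 1e-8
        sup = fits[0].estimate.supported() & fits[1].estimate.supported()
        np.testing.assert_allclose(fits[0].estimate.A_hat[sup],
                                   fits[1].estimate.A_hat[sup], rtol=1e-4)

    def test_scaled_start_gives_identical_normalized_estimate(self, linear_stats):
        cfg = FitConfig(B=20, eps=1e-12)
        f1 = fit_pafit(linear_stats, cfg, start=np.ones(20))
        f2 = fit_pafit(linear_stats, cfg, start=10.0 * np.ones(20))
        sup = f1.estimate.supported()
        np.testing.assert_allclose(f1.estimate.A_hat[sup], f2.estimate.A_hat[sup],
                                   rtol=1e-6)

    def test_matches_generic_concave_maximizer(self, toy_stats):
        """In beta = log A space the objective is concave; a generic
        quasi-Newton maximizer must reach the MM objective value."""
        fit = fit_pafit(toy_stats, FitConfig(B=toy_stats.K + 1, eps=1e-12))
        M = toy_stats.m_per_degree().astype(float)
        sup = M > 0
        n = toy_stats.n_k_t.toarray().astype(float)[sup]
        m_t = toy_stats.m_t.astype(float)

        def negl(beta):
            return -(M[sup] @ beta - m_t @ np.log(np.exp(beta) @ n))

        res = optimize.minimize(negl, np.zeros(int(sup.sum())), method="L-BFGS-B",
                                options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12})
        assert fit.loglik_trace[-1] == pytest.approx(-res.fun, abs=1e-6)

    def test_strong_regularization_straightens_log_log_curve(self, linear_stats):
        def max_curvature(fit):
            good = fit.omega > 0
            x = np.log(fit.bins.representatives()[1:])[good[1:]]
            b = np.log(fit.omega[1:][good[1:]])
            slopes = np.diff(b) / np.diff(x)
            return np.max(np.abs(np.diff(slopes)))

        curv = [max_curvature(fit_pafit(linear_stats,
                                        FitConfig(B=20, lambda_ratio=r, eps=1e-10)))
                for r in (0.1, 1000.0)]
        assert curv[1] < curv[0]
        assert curv[1] < 0.05

    def test_non_convergence_is_flagged(self, linear_stats):
        fit = fit_pafit(linear_stats, FitConfig(B=20, eps=1e-14, max_iter=2))
        assert not fit.converged
        assert fit.iterations == 2

    def test_no_events_raises(self):
        net = TemporalEdgeList(((0, "a", "b"),), {"a": 0, "b": 0})
        with pytest.raises(ValueError, match="no attachment events"):
            fit_pafit(compute_suff_stats(net))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_likelihood_scale_invariance_property(two_step_stats, seed):
    rng = np.random.default_rng(seed)
    A = rng.uniform(0.1, 10.0, 3)
    c = rng.uniform(0.01, 100.0)
    assert log_likelihood(c * A, two_step_stats) == pytest.approx(
        log_likelihood(A, two_step_stats), rel=1e-9)
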