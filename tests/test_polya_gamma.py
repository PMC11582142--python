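"""Polya-Gamma sampling and the two conjugate Gibbs kernels."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import ks_2samp

from isingmiss import (
    GaussianPrior,
    IsingMatrix,
    PriorSpec,
    build_alpha_design,
    draw_pg,
    log_pseudo_likelihood,
    pg_logistic_update,
    pg_mean,
    sample_alpha,
    sample_beta_j,
    sample_exact,
    unvech,
    vech,
)
from isingmiss.ising import _linear_predictors
from isingmiss.polya_gamma import beta_design

from conftest import random_ising


class TestDrawPg:
    @pytest.mark.parametrize("method", ["devroye", "gamma"])
    @pytest.mark.parametrize("c", [0.0, 1.0, 2.0, 6.0])
    def test_sample_mean_matches_closed_form(self, method, c):
        n = 200_000
        x = draw_pg(1.0, np.full(n, c), seed=17, method=method)
        assert (x > 0).all()
        se = x.std() / np.sqrt(n)
        assert abs(x.mean() - pg_mean(1.0, c)) < 4 * se

    def test_general_shape_mean(self):
        x = draw_pg(np.full(50_000, 7.0), 1.3, seed=3, method="gamma")
        se = x.std() / np.sqrt(x.size)
        assert abs(x.mean() - pg_mean(7.0, 1.3)) < 4 * se

    def test_devroye_and_gamma_agree_in_distribution(self):
        rng = np.random.default_rng(11)
        xd = draw_pg(1.0, np.full(100_000, 1.5), rng, method="devroye")
        xg = draw_pg(1.0, np.full(100_000, 1.5), rng, method="gamma")
        assert ks_2samp(xd, xg).statistic < 0.01

    def test_rejects_nonpositive_shape_and_devroye_b_not_one(self):
        with pytest.raises(ValueError):
            draw_pg(0.0, 1.0, seed=0)
        with pytest.raises(ValueError):
            draw_pg(-1.0, 1.0, seed=0)
        with pytest.raises(ValueError):
            draw_pg(2.0, 1.0, seed=0, method="devroye")


class TestLogisticUpdate:
    def test_no_rows_draws_from_prior(self):
        prior = GaussianPrior(np.array([1.0, -2.0]), np.array([4.0, 0.25]))
        rng = np.random.default_rng(0)
        draws = np.array([
            pg_logistic_update(np.empty((0, 2)), np.empty(0), prior, None, rng)
            for _ in range(4000)
        ])
        np.testing.assert_allclose(draws.mean(0), prior.mean, atol=0.12)
        np.testing.assert_allclose(draws.var(0), prior.variances, rtol=0.1)

    def test_one_parameter_chain_matches_grid_posterior(self):
        """Long-run draws of an intercept-only logistic posterior reproduce
        the grid-integration oracle (KS distance)."""
        n, ones = 40, 26
        X = np.ones((n, 1))
        u = np.r_[np.ones(ones), np.zeros(n - ones)]
        prior = GaussianPrior(np.zeros(1), np.array([100.0]))
        # grid oracle
        grid = np.linspace(-3, 4, 4001)
        logpost = (ones * grid - n * np.logaddexp(0, grid)
                   - 0.5 * grid ** 2 / 100.0)
        w = np.exp(logpost - logpost.max())
        cdf = np.cumsum(w) / w.sum()
        rng = np.random.default_rng(5)
        b = np.zeros(1)
        draws = np.empty(20_000)
        for t in range(draws.size):
            b = pg_logistic_update(X, u, prior, b, rng)
            draws[t] = b[0]
        draws = np.sort(draws[2000:])
        emp = np.arange(1, draws.size + 1) / draws.size
        ks = np.abs(np.interp(draws, grid, cdf) - emp).max()
        assert ks < 0.02

    def test_rejects_non_binary_responses(self):
        prior = GaussianPrior(np.zeros(1), np.ones(1))
        with pytest.raises(ValueError):
            pg_logistic_update(np.ones((2, 1)), np.array([0.0, 2.0]), prior, None, 0)


class TestBetaKernel:
    def test_design_row_construction(self):
        # item 2 of 3 (0-based j=1), y = (1, 0, 1) -> row (1, 1/2, 1), response 0
        X, u = beta_design(1, np.array([[1, 0, 1]]))
        np.testing.assert_array_equal(X, [[1.0, 0.5, 1.0]])
        assert u[0] == 0

    def test_grouped_kernel_matches_per_row_kernel(self, toy3):
        """The grouped PG(n_g, c) kernel and the per-row PG(1, c) kernel
        target the same posterior."""
        Y = sample_exact(toy3, 2000, seed=8).y
        prior = PriorSpec().beta_prior(3, 2)
        rng = np.random.default_rng(1)
        b = np.zeros(3)
        grouped = np.array([b := sample_beta_j(2, Y, prior, b, rng)
                            for _ in range(1500)])[300:]
        X, u = beta_design(2, Y)
        b = np.zeros(3)
        perrow = np.array([b := pg_logistic_update(X, u, prior, b, rng)
                           for _ in range(1500)])[300:]
        np.testing.assert_allclose(grouped.mean(0), perrow.mean(0), atol=0.04)
        np.testing.assert_allclose(grouped.std(0), perrow.std(0), atol=0.02)

    def test_exactly_invariant_to_row_relabeling(self, toy3):
        """Grouping by pattern makes the draw bit-identical under any row
        permutation of the data (exchangeability)."""
        Y = sample_exact(toy3, 500, seed=2).y
        perm = np.random.default_rng(3).permutation(500)
        prior = PriorSpec().beta_prior(3, 0)
        d1 = sample_beta_j(0, Y, prior, None, np.random.default_rng(7))
        d2 = sample_beta_j(0, Y[perm], prior, None, np.random.default_rng(7))
        np.testing.assert_array_equal(d1, d2)

    def test_posterior_concentrates_at_true_conditional_coefficients(self, toy3):
        """With Ising data, beta_j concentrates near row j of the true S
        (compatibility of the logistic conditionals)."""
        Y = sample_exact(toy3, 20_000, seed=3).y
        prior = PriorSpec().beta_prior(3, 2)
        rng = np.random.default_rng(4)
        b = np.zeros(3)
        draws = np.array([b := sample_beta_j(2, Y, prior, b, rng)
                          for _ in range(2000)])[400:]
        sd = draws.std(0)
        assert np.all(np.abs(draws.mean(0) - toy3.values[2]) < 5 * sd)

    def test_prior_only_moments(self):
        prior = GaussianPrior(np.zeros(2), np.array([100.0, 1.0]))
        rng = np.random.default_rng(9)
        draws = np.array([sample_beta_j(0, np.empty((0, 2), dtype=np.int8),
                                        prior, None, rng) for _ in range(3000)])
        np.testing.assert_allclose(draws.var(0), prior.variances, rtol=0.12)

    def test_rejects_missing_cells(self):
        from isingmiss import ResponseData
        d = ResponseData(np.array([[1, 0]]), np.array([[True, False]]))
        with pytest.raises(ValueError, match="missing"):
            sample_beta_j(0, d, None, None, 0)


class TestAlphaKernel:
    def test_design_rows_for_two_items(self):
        # alpha = (s11, s21, s22); y = (1,1): rows (1/2, 1, 0) and (0, 1, 1/2)
        X, u = build_alpha_design(np.array([[1, 1]]))
        np.testing.assert_array_equal(X, [[0.5, 1.0, 0.0], [0.0, 1.0, 0.5]])
        np.testing.assert_array_equal(u, [1, 1])
        X0, u0 = build_alpha_design(np.array([[0, 0]]))
        np.testing.assert_array_equal(X0, [[0.5, 0.0, 0.0], [0.0, 0.0, 0.5]])
        np.testing.assert_array_equal(u0, [0, 0])

    def test_design_reproduces_conditional_linear_predictors(self):
        rng = np.random.default_rng(12)
        S = random_ising(4, rng)
        Y = (rng.random((7, 4)) < 0.5).astype(np.int8)
        X, u = build_alpha_design(Y)
        eta_design = (X @ vech(S)).reshape(7, 4)
        np.testing.assert_allclose(eta_design, _linear_predictors(S.values, Y),
                                   atol=1e-12)
        np.testing.assert_array_equal(u.reshape(7, 4), Y)

    def test_prior_only_draw_moments(self):
        prior = PriorSpec().alpha_prior(2)
        rng = np.random.default_rng(2)
        draws = np.array([sample_alpha(np.empty((0, 2), dtype=np.int8),
                                       prior, None, rng) for _ in range(3000)])
        np.testing.assert_allclose(draws.var(0), prior.variances, rtol=0.12)

    def test_draw_unvechs_to_symmetric_matrix(self, toy3):
        Y = sample_exact(toy3, 100, seed=0).y
        a = sample_alpha(Y, None, None, np.random.default_rng(0))
        M = unvech(a)
        np.testing.assert_array_equal(M.values, M.values.T)

    def test_chain_mean_matches_pseudo_posterior_mode(self):
        """Long-run alpha draws sit at the numerically optimized mode of the
        log pseudo-posterior (complete data, J=2)."""
        S0 = IsingMatrix(np.array([[0.3, -0.7], [-0.7, -0.2]]))
        Y = sample_exact(S0, 2000, seed=6).y
        prior = PriorSpec().alpha_prior(2)
        rng = np.random.default_rng(7)
        a = np.zeros(3)
        draws = np.array([a := sample_alpha(Y, prior, a, rng)
                          for _ in range(3000)])[500:]

        def neg_log_post(alpha):
            S = unvech(alpha)
            ll = log_pseudo_likelihood(S, Y).sum()
            return -(ll - 0.5 * np.sum(alpha ** 2 / prior.variances))

        mode = minimize(neg_log_post, np.zeros(3), method="L-BFGS-B").x
        sd = draws.std(0)
        assert np.all(np.abs(draws.mean(0) - mode) < 3 * sd)


class TestPriorSpec:
    def test_variances_follow_intercept_slope_convention(self):
        p = PriorSpec()
        bp = p.beta_prior(3, 1)
        np.testing.assert_array_equal(bp.variances, [1.0, 100.0, 1.0])
        ap = p.alpha_prior(3)
        # vech order s11, s21, s31, s22, s32, s33
        np.testing.assert_array_equal(ap.variances, [100, 1, 1, 100, 1, 100])

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            GaussianPrior(np.zeros(2), np.array([1.0, 0.0]))
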