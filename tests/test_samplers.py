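import numpy as np
import pytest
from scipy import stats

from ibag.samplers import (
    HyperConfig,
    sample_coefficients_block,
    sample_error_variance,
    sample_gene_loadings,
    sample_latent_binary,
    sample_latent_survival,
    sample_mixing_scales,
    sample_shrinkage,
    truncated_normal,
)

KS_ALPHA = 0.01


def _ks_against_grid(draws, grid, log_density):
    """KS test of draws against an unnormalized density evaluated on a grid."""
    dens = np.exp(log_density - log_density.max())
    cdf = np.cumsum(dens)
    cdf /= cdf[-1]
    return stats.ks_1samp(draws, lambda x: np.interp(x, grid, cdf)).pvalue


class TestCoefficientsBlock:
    def test_huge_prior_recovers_ols_mean(self, rng):
        n = 40
        d = rng.standard_normal(n)
        d /= np.linalg.norm(d)
        beta_true = 1.7
        y = beta_true * d + rng.standard_normal(n)
        ols = float(d @ y)  # orthonormal column
        draws = np.array(
            [
                sample_coefficients_block(y, d[:, None], np.array([1e10]), 1.0, rng)[0]
                for _ in range(10000)
            ]
        )
        mc_se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - ols) < 3 * mc_se
        assert draws.std(ddof=1) == pytest.approx(1.0, rel=0.05)  # sigma for unit-norm column

    def test_prior_scale_zero_limit_collapses(self, rng):
        d = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        draws = sample_coefficients_block(y, d, np.full(3, 1e-12), 1.0, rng)
        assert np.abs(draws).max() < 1e-4

    @pytest.mark.parametrize("state_seed", [1, 2, 3])
    def test_marginals_match_conjugate_posterior(self, state_seed):
        rng = np.random.default_rng(state_seed)
        n, p = 20, 2
        D = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        scales = np.array([0.5, 2.0])
        sigma = 1.3
        # oracle: explicit normal posterior via matrix inversion
        A = D.T @ D + np.diag(sigma**2 / scales)
        cov = sigma**2 * np.linalg.inv(A)
        mean = np.linalg.inv(A) @ D.T @ y
        draw_rng = np.random.default_rng(1000 + state_seed)
        draws = np.array(
            [sample_coefficients_block(y, D, scales, sigma, draw_rng) for _ in range(12000)]
        )
        for j in range(p):
            p_ks = stats.ks_1samp(
                draws[:, j], stats.norm(mean[j], np.sqrt(cov[j, j])).cdf
            ).pvalue
            assert p_ks > KS_ALPHA

    def test_empty_block(self, rng):
        out = sample_coefficients_block(np.zeros(5), np.zeros((5, 0)), np.zeros(0), 1.0, rng)
        assert out.shape == (0,)


class TestMixingScales:
    def test_inverse_draws_match_inverse_gaussian(self, rng):
        beta = np.array([0.8])
        lam, sigma = 1.5, 0.9
        draws = np.concatenate(
            [1.0 / sample_mixing_scales(beta, lam, sigma, rng) for _ in range(10000)]
        )
        mu = np.sqrt(lam**2 * sigma**2 / beta[0] ** 2)
        mc_se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - mu) < 3 * mc_se
        # full-distribution check at one state
        p_ks = stats.ks_1samp(draws, stats.invgauss(mu / lam**2, scale=lam**2).cdf).pvalue
        assert p_ks > KS_ALPHA

    def test_larger_beta_gives_stochastically_larger_tau2(self, rng):
        betas = np.linspace(0.1, 3.0, 30)
        tau2 = np.vstack(
            [sample_mixing_scales(betas, 1.0, 1.0, rng) for _ in range(1000)]
        ).mean(axis=0)
        assert stats.spearmanr(betas, tau2).statistic > 0.5

    def test_zero_beta_fallback_is_finite_positive(self, rng):
        tau2 = sample_mixing_scales(np.zeros(100), 2.0, 1.0, rng)
        assert np.all(np.isfinite(tau2)) and np.all(tau2 > 0)


class TestShrinkage:
    def test_empty_model_reduces_to_prior(self, rng):
        alpha, xi = 2.0, 3.0
        draws = np.array(
            [sample_shrinkage(np.zeros(0), 0, (alpha, xi), rng) for _ in range(5000)]
        )
        assert stats.ks_1samp(draws, stats.gamma(alpha, scale=1 / xi).cdf).pvalue > KS_ALPHA

    def test_conditional_mean(self, rng):
        tau2 = np.array([0.5, 1.5, 2.0])
        draws = np.array(
            [sample_shrinkage(tau2, 3, (1.0, 1.0), rng) for _ in range(10000)]
        )
        expected = (1.0 + 3) / (1.0 + tau2.sum() / 2)
        mc_se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 3 * mc_se

    def test_mean_decreases_with_tau2_mass(self, rng):
        tau2 = np.full(5, 1.0)
        m1 = np.mean([sample_shrinkage(tau2, 5, (1, 1), rng) for _ in range(3000)])
        m2 = np.mean([sample_shrinkage(2 * tau2, 5, (1, 1), rng) for _ in range(3000)])
        assert m2 < m1


class TestErrorVariance:
    def test_inverse_gamma_mean(self, rng):
        resid = np.full(20, 0.7)
        beta = np.array([1.0, -2.0])
        tau2 = np.array([0.5, 1.0])
        shape = 20 / 2 + 2 / 2
        rate = (resid @ resid) / 2 + np.sum(beta**2 / (2 * tau2))
        draws = np.array(
            [sample_error_variance(resid, beta, tau2, rng) for _ in range(20000)]
        )
        expected = rate / (shape - 1)
        mc_se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 3 * mc_se
        assert stats.ks_1samp(draws, stats.invgamma(shape, scale=rate).cdf).pvalue > KS_ALPHA

    def test_residual_scaling_scales_sigma(self, rng):
        resid = np.random.default_rng(0).standard_normal(500)
        none = np.zeros(0)
        base = np.median(
            [np.sqrt(sample_error_variance(resid, none, none, rng)) for _ in range(2000)]
        )
        scaled = np.median(
            [np.sqrt(sample_error_variance(3 * resid, none, none, rng)) for _ in range(2000)]
        )
        assert scaled / base == pytest.approx(3.0, rel=0.05)

    def test_prior_only_reduction_with_coefficients(self, rng):
        draw = sample_error_variance(np.zeros(0), np.array([1.0]), np.array([0.5]), rng)
        assert draw > 0

    def test_empty_conditional_rejected(self, rng):
        with pytest.raises(ValueError, match="improper"):
            sample_error_variance(np.zeros(0), np.zeros(0), np.zeros(0), rng)


class TestGeneLoadings:
    def _context(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        m = rng.uniform(size=(n, 1))
        m -= m.mean(axis=0)
        g = -0.8 * m[:, 0] + 0.4 * rng.standard_normal(n)
        g -= g.mean()
        resid = 0.5 * m[:, 0] + rng.standard_normal(n)
        return g, m, resid

    def test_decoupled_case_equals_mechanistic_posterior(self, rng):
        g, m, _ = self._context(5)
        sigma_k, v_om = 0.4, 2.0
        prec = (m[:, 0] @ m[:, 0]) / sigma_k**2 + 1 / v_om
        mean = (m[:, 0] @ g) / sigma_k**2 / prec
        draws = np.array(
            [
                sample_gene_loadings(
                    g, m, sigma_k, rng, v_omega=v_om,
                    clin_resid=np.zeros_like(g), beta_m=0.0, beta_mbar=0.0,
                )[0]
                for _ in range(6000)
            ]
        )
        assert draws.mean() == pytest.approx(mean, abs=4 * draws.std() / np.sqrt(len(draws)))
        assert draws.std(ddof=1) == pytest.approx(np.sqrt(1 / prec), rel=0.05)

    @pytest.mark.parametrize("state_seed", [11, 12, 13])
    def test_matches_density_grid_oracle_with_clinical_coupling(self, state_seed):
        g, m, resid = self._context(state_seed)
        sigma_k, v_om, sigma = 0.4, 2.0, 0.8
        b_m, b_mb = 1.2, -0.5
        rng = np.random.default_rng(500 + state_seed)
        draws = np.array(
            [
                sample_gene_loadings(
                    g, m, sigma_k, rng, v_omega=v_om,
                    clin_resid=resid, beta_m=b_m, beta_mbar=b_mb, sigma=sigma,
                )[0]
                for _ in range(4000)
            ]
        )
        grid = np.linspace(draws.min() - 1, draws.max() + 1, 4001)
        # brute-force log joint density on the grid
        mcol = m[:, 0]
        logd = np.empty_like(grid)
        for i, w in enumerate(grid):
            mech = -0.5 * np.sum((g - mcol * w) ** 2) / sigma_k**2
            clin = -0.5 * np.sum((resid - b_m * (mcol * w) - b_mb * (g - mcol * w)) ** 2) / sigma**2
            prior = -0.5 * w**2 / v_om
            logd[i] = mech + clin + prior
        assert _ks_against_grid(draws, grid, logd) > KS_ALPHA

    def test_vanishing_prior_variance_collapses(self, rng):
        g, m, _ = self._context(7)
        draws = [
            sample_gene_loadings(g, m, 0.4, rng, v_omega=1e-12)[0] for _ in range(100)
        ]
        assert np.abs(draws).max() < 1e-4


class TestLatentSamplers:
    def test_binary_truncation_signs(self, rng):
        y = np.array([1.0, 0.0, 1.0, 0.0] * 25)
        lp = np.zeros(100)
        for _ in range(50):
            z = sample_latent_binary(y, lp, rng)
            assert np.all(z[y == 1.0] > 0) and np.all(z[y == 0.0] <= 0)

    def test_binary_truncated_mean_matches_closed_form(self, rng):
        lp = 0.4
        draws = np.concatenate(
            [sample_latent_binary(np.ones(1000), np.full(1000, lp), rng) for _ in range(20)]
        )
        expected = stats.truncnorm.mean(-lp, np.inf, loc=lp, scale=1.0)
        mc_se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 3 * mc_se

    def test_far_from_boundary_is_plain_normal(self, rng):
        draws = sample_latent_binary(np.ones(20000), np.full(20000, 10.0), rng)
        assert stats.ks_1samp(draws, stats.norm(10.0, 1.0).cdf).pvalue > KS_ALPHA

    def test_survival_observed_events_fixed(self, rng):
        t = np.array([1.0, 2.0, 3.0])
        z = sample_latent_survival(t, np.ones(3), np.zeros(3), 1.0, rng)
        np.testing.assert_array_equal(z, np.log(t))

    def test_survival_censored_above_log_time(self, rng):
        t = np.full(200, 2.0)
        z = sample_latent_survival(t, np.zeros(200), np.zeros(200), 1.0, rng)
        assert np.all(z > np.log(2.0))

    def test_survival_censored_mean_matches_closed_form(self, rng):
        t, lp, sigma = 1.5, 0.2, 0.7
        draws = np.concatenate(
            [
                sample_latent_survival(
                    np.full(1000, t), np.zeros(1000), np.full(1000, lp), sigma, rng
                )
                for _ in range(20)
            ]
        )
        a = (np.log(t) - lp) / sigma
        expected = stats.truncnorm.mean(a, np.inf, loc=lp, scale=sigma)
        mc_se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 3 * mc_se

    def test_nonpositive_time_rejected(self, rng):
        with pytest.raises(ValueError, match="positive"):
            sample_latent_survival(np.array([0.0]), np.ones(1), np.zeros(1), 1.0, rng)

    def test_far_tail_truncation_is_robust(self, rng):
        lower = np.full(1000, 8.0)
        draws = truncated_normal(lower, np.full(1000, np.inf), np.zeros(1000), 1.0, rng)
        assert np.all(np.isfinite(draws)) and np.all(draws >= 8.0)


def test_kernels_are_bit_reproducible():
    args = dict(
        response=np.arange(10, dtype=float),
        design=np.eye(10)[:, :3],
        prior_scales=np.ones(3),
        sigma=1.0,
    )
    a = sample_coefficients_block(rng=np.random.default_rng(5), **args)
    b = sample_coefficients_block(rng=np.random.default_rng(5), **args)
    np.testing.assert_array_equal(a, b)
    t1 = sample_mixing_scales(np.ones(4), 1.0, 1.0, np.random.default_rng(6))
    t2 = sample_mixing_scales(np.ones(4), 1.0, 1.0, np.random.default_rng(6))
    np.testing.assert_array_equal(t1, t2)


def test_hyperconfig_validation():
    with pytest.raises(ValueError):
        HyperConfig(alpha_m=0.0)
    with pytest.raises(ValueError):
        HyperConfig(sigma2_shape=-1.0)
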