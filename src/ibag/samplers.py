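"""Closed-form full-conditional kernels for the Gibbs sampler.

The clinical layer uses the scale-mixture representation of the
double-exponential (Bayesian lasso) prior: conditionally on a
per-coefficient mixing scale tau2_p, each shrunk coefficient is normal
with variance sigma^2 * tau2_p; the tau2_p carry exponential priors
with rate lambda^2 / 2, and the squared shrinkage parameter lambda^2
carries a Gamma(alpha, xi) hyperprior (shape/rate).  Every conditional
below is available in closed form, so the whole model is sampled by
systematic-scan Gibbs without Metropolis steps.

All kernels are pure functions of their inputs and a
``numpy.random.Generator``; identical generator states give identical
draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

__all__ = [
    "HyperConfig",
    "sample_coefficients_block",
    "sample_mixing_scales",
    "sample_shrinkage",
    "sample_error_variance",
    "sample_gene_loadings",
    "sample_latent_binary",
    "sample_latent_survival",
    "truncated_normal",
]


@dataclass(frozen=True)
class HyperConfig:
    """Hyperparameters of the hierarchical prior.

    ``alpha_*`` / ``xi_*`` are the shape and rate of the gamma
    hyperpriors on the squared shrinkage parameters of the type-M and
    type-Mbar blocks (default 1 and 1).  ``v_gamma`` is the prior
    variance of the unshrunk clinical-covariate effects (large: 1e6 for
    unit-scale covariates); ``v_omega`` the prior variance of the
    gene-methylation loadings (1e2 on centered data).
    ``sigma2_shape`` / ``sigma2_rate`` parameterize an optional proper
    inverse-gamma prior on the error variances; the default (0, 0)
    recovers the improper 1/sigma^2 prior.
    """

    alpha_m: float = 1.0
    xi_m: float = 1.0
    alpha_mbar: float = 1.0
    xi_mbar: float = 1.0
    v_gamma: float = 1e6
    v_omega: float = 1e2
    sigma2_shape: float = 0.0
    sigma2_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha_m", "xi_m", "alpha_mbar", "xi_mbar", "v_gamma", "v_omega"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.sigma2_shape < 0 or self.sigma2_rate < 0:
            raise ValueError("sigma2 prior shape/rate must be non-negative")


def sample_coefficients_block(
    response: np.ndarray,
    design: np.ndarray,
    prior_scales: np.ndarray,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a coefficient block from its conjugate normal conditional.

    With design D (N x P), partial residual r, error SD sigma and
    independent N(0, scale_p) priors, the conditional is
    ``N(A^-1 D' r, sigma^2 A^-1)`` with
    ``A = D'D + diag(sigma^2 / scale_p)``.
    """
    D = np.atleast_2d(np.asarray(design, dtype=float))
    p = D.shape[1]
    if p == 0:
        return np.empty(0)
    r = np.asarray(response, dtype=float)
    scales = np.asarray(prior_scales, dtype=float)
    if np.any(scales <= 0) or sigma <= 0:
        raise ValueError("prior scales and sigma must be strictly positive")
    A = D.T @ D + np.diag(sigma**2 / scales)
    try:
        chol = linalg.cholesky(A, lower=True)
    except linalg.LinAlgError as exc:  # unreachable with positive scales
        raise ValueError("coefficient precision matrix not positive definite") from exc
    mean = linalg.cho_solve((chol, True), D.T @ r)
    z = rng.standard_normal(p)
    return mean + sigma * linalg.solve_triangular(chol, z, lower=True, trans="T")


def sample_mixing_scales(
    beta: np.ndarray,
    lam: float,
    sigma: float,
    rng: np.random.Generator,
    *,
    zero_tol: float = 1e-12,
) -> np.ndarray:
    """Draw the per-coefficient exponential mixing scales tau2_p.

    The conditional of 1/tau2_p is inverse-Gaussian with mean
    ``sqrt(lambda^2 sigma^2 / beta_p^2)`` and shape ``lambda^2``.  A
    coefficient numerically at zero falls back to the exponential-prior
    conditional ``tau2_p ~ Gamma(1/2, lambda^2 / 2)`` (defensive: the
    continuous sampler never produces exact zeros).
    """
    b = np.asarray(beta, dtype=float)
    if lam <= 0 or sigma <= 0:
        raise ValueError("lambda and sigma must be strictly positive")
    tau2 = np.empty_like(b)
    nz = np.abs(b) > zero_tol
    if nz.any():
        mu = np.sqrt(lam**2 * sigma**2 / b[nz] ** 2)
        inv_tau2 = rng.wald(mu, lam**2)
        tau2[nz] = 1.0 / inv_tau2
    n0 = int((~nz).sum())
    if n0:
        tau2[~nz] = rng.gamma(0.5, 2.0 / lam**2, size=n0)
    return tau2


def sample_shrinkage(
    tau2: np.ndarray,
    p: int,
    hyper: tuple[float, float],
    rng: np.random.Generator,
) -> float:
    """Draw lambda^2 from Gamma(alpha + P, xi + sum(tau2)/2).

    With P = 0 the draw comes from the Gamma(alpha, xi) prior.
    """
    alpha, xi = hyper
    t = np.asarray(tau2, dtype=float)
    if np.any(t <= 0):
        raise ValueError("mixing scales must be strictly positive")
    if len(t) != p:
        raise ValueError("tau2 length must equal the coefficient count")
    return float(rng.gamma(alpha + p, 1.0 / (xi + t.sum() / 2.0)))


def sample_error_variance(
    residuals: np.ndarray,
    beta: np.ndarray,
    tau2: np.ndarray,
    rng: np.random.Generator,
    *,
    prior_shape: float = 0.0,
    prior_rate: float = 0.0,
) -> float:
    """Draw sigma^2 from its inverse-gamma conditional.

    The shape counts the N residual terms and the P lasso-prior
    coefficients (whose normal prior conditions on sigma^2); the rate
    is ``RSS/2 + sum(beta_p^2 / (2 tau2_p))``, plus any proper-prior
    contribution.  Under the default improper 1/sigma^2 prior an empty
    conditional (no data, no coefficients) is rejected.
    """
    r = np.asarray(residuals, dtype=float)
    b = np.asarray(beta, dtype=float)
    t = np.asarray(tau2, dtype=float)
    if b.shape != t.shape:
        raise ValueError("beta and tau2 must align")
    shape = prior_shape + len(r) / 2.0 + len(b) / 2.0
    rate = prior_rate + (r @ r) / 2.0
    if len(b):
        rate += float(np.sum(b**2 / (2.0 * t)))
    if shape <= 0 or rate <= 0:
        raise ValueError("improper sigma^2 conditional (all-zero residuals and coefficients)")
    return float(1.0 / rng.gamma(shape, 1.0 / rate))


def sample_gene_loadings(
    g_k: np.ndarray,
    m_k: np.ndarray,
    sigma_k: float,
    rng: np.random.Generator,
    *,
    v_omega: float | np.ndarray,
    clin_resid: np.ndarray | None = None,
    beta_m: float = 0.0,
    beta_mbar: float = 0.0,
    sigma: float = 1.0,
) -> np.ndarray:
    """Draw omega_k from its normal conditional in the unified model.

    The conditional combines (a) the mechanistic likelihood
    ``g_k ~ N(M_k omega, sigma_k^2 I)``, (b) the clinical likelihood
    through the two channels ``beta_m * (M_k omega)`` and
    ``beta_mbar * (g_k - M_k omega)`` — jointly a coefficient
    ``d = beta_m - beta_mbar`` on ``M_k omega`` against the shifted
    residual ``clin_resid - beta_mbar * g_k`` — and (c) the
    ``N(0, v_omega)`` prior.  With ``clin_resid=None`` (or both betas
    zero) it reduces to the stand-alone mechanistic posterior.

    ``clin_resid`` is the clinical response minus every term except
    gene k's own two expression terms.
    """
    g = np.asarray(g_k, dtype=float)
    M = np.atleast_2d(np.asarray(m_k, dtype=float))
    if M.shape[0] != g.shape[0]:
        raise ValueError("expression vector and probe matrix disagree on sample count")
    j_k = M.shape[1]
    if sigma_k <= 0 or sigma <= 0:
        raise ValueError("error scales must be strictly positive")
    v = np.broadcast_to(np.asarray(v_omega, dtype=float), (j_k,))
    if np.any(v <= 0):
        raise ValueError("v_omega must be strictly positive")

    MtM = M.T @ M
    A = MtM / sigma_k**2 + np.diag(1.0 / v)
    bvec = M.T @ g / sigma_k**2
    if clin_resid is not None:
        d = beta_m - beta_mbar
        if d != 0.0:
            r = np.asarray(clin_resid, dtype=float) - beta_mbar * g
            A = A + (d**2 / sigma**2) * MtM
            bvec = bvec + (d / sigma**2) * (M.T @ r)
    chol = linalg.cholesky(A, lower=True)
    mean = linalg.cho_solve((chol, True), bvec)
    z = rng.standard_normal(j_k)
    return mean + linalg.solve_triangular(chol, z, lower=True, trans="T")


def truncated_normal(
    lower: np.ndarray,
    upper: np.ndarray,
    loc: np.ndarray,
    scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized truncated-normal draws, robust far into the tails."""
    loc = np.asarray(loc, dtype=float)
    a = (np.asarray(lower, dtype=float) - loc) / scale
    b = (np.asarray(upper, dtype=float) - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, random_state=rng)


def sample_latent_binary(
    y: np.ndarray, linear_predictor: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Probit data augmentation: Z_n ~ N(lp_n, 1) truncated by the class.

    Positive support for y_n = 1, non-positive for y_n = 0; the latent
    variance is fixed at 1 for probit identifiability.
    """
    y = np.asarray(y, dtype=float)
    lp = np.asarray(linear_predictor, dtype=float)
    lower = np.where(y == 1.0, 0.0, -np.inf)
    upper = np.where(y == 1.0, np.inf, 0.0)
    return truncated_normal(lower, upper, lp, 1.0, rng)


def sample_latent_survival(
    t: np.ndarray,
    delta: np.ndarray,
    linear_predictor: np.ndarray,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Accelerated-failure-time augmentation on the log-time scale.

    Observed events (delta_n = 1) pin Z_n = log t_n; censored records
    are imputed from N(lp_n, sigma^2) truncated to (log t_n, inf).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("survival times must be strictly positive")
    delta = np.asarray(delta, dtype=float)
    lp = np.asarray(linear_predictor, dtype=float)
    z = np.log(t)
    cens = delta == 0.0
    if cens.any():
        z = z.copy()
        z[cens] = truncated_normal(z[cens], np.full(cens.sum(), np.inf), lp[cens], sigma, rng)
    return z
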