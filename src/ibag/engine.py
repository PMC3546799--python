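"""Model fitting: unified Gibbs sampler, two-stage variant and comparators.

Four clinical models share one systematic-scan Gibbs engine:

* ``unified`` — the joint hierarchical model: gene loadings omega_k,
  their residual scales sigma_k, the expression partition and the
  clinical Bayesian lasso are sampled together, so clinical information
  feeds back into the mechanistic layer.
* ``two_stage`` — the mechanistic layer is fit once by per-gene OLS and
  the clinical lasso runs on the frozen partition.
* ``nonint`` — non-integrative: Bayesian lasso on gene expression
  alone (methylation ignored), single shrinkage parameter.
* ``add`` — additive: Bayesian lasso on the concatenation of
  expression and methylation columns, with a separate shrinkage
  parameter for the methylation block.

The single-gene (SG) comparator is a per-gene classical regression
returning a gene-level p-value rather than posterior draws.

Fixed scan order (omega blocks, gamma, beta blocks, tau2, lambda2,
sigma2 and sigma_k2, latents) makes runs reproducible draw-for-draw
from the seed; Gibbs correctness does not depend on the order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .data import GenomicsDataset
from .mechanistic import GeneLoadings, fit_all_genes
from .samplers import (
    HyperConfig,
    sample_coefficients_block,
    sample_error_variance,
    sample_gene_loadings,
    sample_latent_binary,
    sample_latent_survival,
    sample_mixing_scales,
    sample_shrinkage,
)

__all__ = [
    "McmcConfig",
    "PosteriorSamples",
    "GibbsSampler",
    "run_unified",
    "run_two_stage",
    "fit_nonint",
    "fit_add",
    "fit_sg",
    "predict",
]


@dataclass(frozen=True)
class McmcConfig:
    """MCMC run length and hyperparameters.

    Defaults (10000 iterations, 2000 burn-in) reflect that the chain
    settles within roughly the first two thousand scans on data of the
    intended scale; thinning mainly bounds storage.
    """

    iterations: int = 10000
    burnin: int = 2000
    thin: int = 5
    seed: int = 0
    hyper: HyperConfig = field(default_factory=HyperConfig)
    resample_sigma_k: bool = True
    standardize: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.burnin < self.iterations):
            raise ValueError("need 0 <= burnin < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burnin + self.thin - 1) // self.thin


@dataclass
class PosteriorSamples:
    """Retained Gibbs draws plus the structural metadata to reuse them.

    ``draws`` maps parameter names to ``(S, ...)`` arrays: ``gamma``,
    ``beta_<block>`` / ``tau2_<block>`` / ``lam2_<block>`` for every
    lasso block, ``sigma2``, and for the integrative models ``omega``
    (flattened over mapped genes), ``sigma_k2`` and, for non-continuous
    outcomes, the latent response ``z``.
    """

    model: str
    family: str
    config: McmcConfig
    draws: dict[str, np.ndarray]
    block_names: tuple[str, ...]
    block_labels: dict[str, tuple[str, ...]]
    gamma_labels: tuple[str, ...]
    mapped_genes: tuple[str, ...]
    probe_slices: dict[str, tuple[int, int]]
    centers: dict[str, Any]
    scales: dict[str, np.ndarray]

    @property
    def n_draws(self) -> int:
        return len(self.draws["sigma2"])

    def summary(self) -> pd.DataFrame:
        """Posterior mean/SD and central 95% interval per coefficient.

        Coefficients are reported on the original column scale (draws
        are stored on the unit-norm standardized basis).
        """
        rows = []
        for name in self.block_names:
            arr = self.draws[f"beta_{name}"]
            for j, label in enumerate(self.block_labels[name]):
                col = arr[:, j] / self.scales[name][j]
                rows.append(
                    (label, name, col.mean(), col.std(ddof=1),
                     np.quantile(col, 0.025), np.quantile(col, 0.975))
                )
        for j, label in enumerate(self.gamma_labels):
            col = self.draws["gamma"][:, j]
            rows.append((label, "covariate", col.mean(), col.std(ddof=1),
                         np.quantile(col, 0.025), np.quantile(col, 0.975)))
        return pd.DataFrame(rows, columns=["feature", "type", "mean", "sd", "q2.5", "q97.5"])


def _center(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    arr = frame.to_numpy(dtype=float)
    mean = arr.mean(axis=0) if arr.size else np.zeros(arr.shape[1])
    return arr - mean, mean


class GibbsSampler:
    """Systematic-scan Gibbs sampler shared by all Bayesian model variants.

    Not normally constructed directly — use :func:`run_unified` and
    friends — but exposed so that diagnostics can drive single scans
    (:meth:`step`) and regenerate data from a parameter state
    (:meth:`sample_data`) for joint-distribution checks.
    """

    def __init__(self, ds: GenomicsDataset, cfg: McmcConfig, model: str,
                 loadings: GeneLoadings | None = None):
        if not ds.validated:
            raise ValueError("dataset must pass validate_dataset before fitting")
        if model not in ("unified", "two_stage", "nonint", "add"):
            raise ValueError(f"unknown model {model!r}")
        self.ds = ds
        self.cfg = cfg
        self.model = model
        self.family = ds.outcome.family
        self.hyper = cfg.hyper
        self.n = ds.n_samples

        self.expr_c, self.expr_mean = _center(ds.expression)
        self.meth_c, self.meth_mean = _center(ds.methylation)
        cov_c, self.cov_mean = _center(ds.covariates)
        self.genes = list(ds.genes)
        self.gene_pos = {g: i for i, g in enumerate(self.genes)}

        # covariate design: centered covariates, plus an intercept when the
        # response is a latent variable (whose mean is not removed by centering)
        self.gamma_labels: tuple[str, ...] = tuple(ds.covariates.columns)
        self.C = cov_c
        if self.family != "continuous":
            self.C = np.hstack([np.ones((self.n, 1)), cov_c])
            self.gamma_labels = ("(intercept)",) + self.gamma_labels
        self.n_gamma = self.C.shape[1]

        integrative = model in ("unified", "two_stage")
        self.mapped: list[str] = list(ds.mapped_genes) if integrative else []
        by_gene = ds.probe_map.by_gene()
        meth_pos = {p: i for i, p in enumerate(ds.methylation.columns)}
        self.probe_idx: list[np.ndarray] = [
            np.array([meth_pos[p] for p in by_gene[g]], dtype=int) for g in self.mapped
        ]
        self.probe_slices: dict[str, tuple[int, int]] = {}
        off = 0
        for g, idx in zip(self.mapped, self.probe_idx):
            self.probe_slices[g] = (off, off + len(idx))
            off += len(idx)
        self.n_omega = off
        # genes whose probe count reaches N take a lasso prior on omega_k
        self.omega_lasso = [len(idx) >= self.n for idx in self.probe_idx]

        self.loadings0 = loadings
        if integrative and loadings is None:
            self.loadings0 = fit_all_genes(ds)

        # lasso blocks: (name, column labels); empty blocks are dropped so
        # that structural reductions (no mapped genes, J = 0) follow the
        # same update path as the model they reduce to
        blocks: list[tuple[str, tuple[str, ...]]] = []
        if integrative:
            if self.mapped:
                blocks.append(("m", tuple(self.mapped)))
            blocks.append(("mbar", tuple(self.genes)))
        elif model == "nonint":
            blocks.append(("g", tuple(self.genes)))
        else:  # add
            blocks.append(("g", tuple(self.genes)))
            if ds.methylation.shape[1]:
                blocks.append(("meth", tuple(ds.methylation.columns)))
        self.blocks = [(n, c) for n, c in blocks if len(c)]

        # fixed unit-L2-norm scaling of the lasso design columns: one
        # shrinkage parameter per block is only exchangeable across columns
        # of comparable scale.  For the integrative models the norms are
        # taken from the stage-1 (OLS) partition and then held fixed, so
        # the scaling stays a pure reparameterization of the model.
        self.col_scale: dict[str, np.ndarray] = {}
        if cfg.standardize:
            ref = self._designs_raw(
                {"omega": [np.array(self.loadings0.omega[g], dtype=float) for g in self.mapped]}
                if self.mapped else {}
            )
            for name, _ in self.blocks:
                norms = np.linalg.norm(ref[name], axis=0)
                self.col_scale[name] = np.where(norms > 1e-12, norms, 1.0)
        else:
            self.col_scale = {n: np.ones(len(c)) for n, c in self.blocks}
        self.block_hyper = {
            "m": (self.hyper.alpha_m, self.hyper.xi_m),
            "g": (self.hyper.alpha_m, self.hyper.xi_m),
            "mbar": (self.hyper.alpha_mbar, self.hyper.xi_mbar),
            "meth": (self.hyper.alpha_mbar, self.hyper.xi_mbar),
        }

        # response on the regression scale
        out = ds.outcome
        if self.family == "continuous":
            self.y_mean = float(out.values.mean())
            self.y0 = out.values - self.y_mean
        elif self.family == "binary":
            self.y_mean = 0.0
            self.y_bin = out.values
        else:
            self.y_mean = 0.0
            self.t = out.values
            self.delta = out.event

    # ------------------------------------------------------------------ state

    def init_state(self) -> dict[str, Any]:
        """Deterministic starting point: zero coefficients, unit scales,
        stage-1 OLS loadings."""
        st: dict[str, Any] = {
            "gamma": np.zeros(self.n_gamma),
            "beta": {n: np.zeros(len(c)) for n, c in self.blocks},
            "tau2": {n: np.ones(len(c)) for n, c in self.blocks},
            "lam2": {n: 1.0 for n, c in self.blocks},
        }
        if self.mapped:
            st["omega"] = [np.array(self.loadings0.omega[g], dtype=float) for g in self.mapped]
            st["sigma_k2"] = np.array([self.loadings0.sigma[g] ** 2 for g in self.mapped])
            st["omega_tau2"] = {
                i: np.ones(len(self.probe_idx[i]))
                for i, big in enumerate(self.omega_lasso) if big
            }
            st["omega_lam2"] = {i: 1.0 for i, big in enumerate(self.omega_lasso) if big}
        if self.family == "binary":
            st["z"] = np.where(self.y_bin == 1.0, 0.6745, -0.6745)
            st["sigma2"] = 1.0
        elif self.family == "survival":
            st["z"] = np.log(self.t)
            st["sigma2"] = float(np.var(st["z"]))
        else:
            st["sigma2"] = float(np.var(self.y0))
        return st

    def _response(self, st: dict[str, Any]) -> np.ndarray:
        return self.y0 if self.family == "continuous" else st["z"]

    def _m_columns(self, st: dict[str, Any]) -> np.ndarray:
        cols = np.empty((self.n, len(self.mapped)))
        for i, idx in enumerate(self.probe_idx):
            cols[:, i] = self.meth_c[:, idx] @ st["omega"][i]
        return cols

    def _designs_raw(self, st: dict[str, Any]) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        if self.model in ("unified", "two_stage"):
            if self.mapped:
                m_cols = self._m_columns(st)
                out["m"] = m_cols
                mbar = self.expr_c.copy()
                mapped_pos = [self.gene_pos[g] for g in self.mapped]
                mbar[:, mapped_pos] -= m_cols
                out["mbar"] = mbar
            else:
                out["mbar"] = self.expr_c
        elif self.model == "nonint":
            out["g"] = self.expr_c
        else:
            out["g"] = self.expr_c
            if any(n == "meth" for n, _ in self.blocks):
                out["meth"] = self.meth_c
        return out

    def _designs(self, st: dict[str, Any]) -> dict[str, np.ndarray]:
        raw = self._designs_raw(st)
        return {name: raw[name] / self.col_scale[name] for name, _ in self.blocks}

    # ------------------------------------------------------------------ scan

    def step(self, st: dict[str, Any], rng: np.random.Generator) -> dict[str, Any]:
        """One full systematic scan over all conditionals (in place)."""
        sigma = float(np.sqrt(st["sigma2"]))
        y = self._response(st)

        # --- gene-loading blocks (unified only: clinical feedback active)
        if self.model == "unified" and self.mapped:
            m_cols = self._m_columns(st)
            mapped_pos = np.array([self.gene_pos[g] for g in self.mapped])
            # effective coefficients on the raw (unscaled) columns
            beta_m = st["beta"]["m"] / self.col_scale["m"]
            beta_mbar_all = st["beta"]["mbar"] / self.col_scale["mbar"]
            mbar = self.expr_c.copy()
            mbar[:, mapped_pos] -= m_cols
            fit = self.C @ st["gamma"] + m_cols @ beta_m + mbar @ beta_mbar_all
            for i, gene in enumerate(self.mapped):
                idx = self.probe_idx[i]
                g_c = self.expr_c[:, self.gene_pos[gene]]
                b_m = float(beta_m[i])
                b_mb = float(beta_mbar_all[self.gene_pos[gene]])
                old_m = m_cols[:, i]
                resid_k = y - fit + b_m * old_m + b_mb * (g_c - old_m)
                if self.omega_lasso[i]:
                    v_om = st["sigma_k2"][i] * st["omega_tau2"][i]
                else:
                    v_om = np.full(len(idx), self.hyper.v_omega)
                new_omega = sample_gene_loadings(
                    g_c, self.meth_c[:, idx], float(np.sqrt(st["sigma_k2"][i])), rng,
                    v_omega=v_om, clin_resid=resid_k, beta_m=b_m, beta_mbar=b_mb,
                    sigma=sigma,
                )
                new_m = self.meth_c[:, idx] @ new_omega
                fit += (b_m - b_mb) * (new_m - old_m)
                m_cols[:, i] = new_m
                st["omega"][i] = new_omega
            # lasso-prior loadings: update their mixing scales and shrinkage
            for i in list(st.get("omega_tau2", {})):
                lam = float(np.sqrt(st["omega_lam2"][i]))
                sd_k = float(np.sqrt(st["sigma_k2"][i]))
                st["omega_tau2"][i] = sample_mixing_scales(st["omega"][i], lam, sd_k, rng)
                st["omega_lam2"][i] = sample_shrinkage(
                    st["omega_tau2"][i], len(st["omega"][i]),
                    (self.hyper.alpha_m, self.hyper.xi_m), rng,
                )

        designs = self._designs(st)
        lasso_fit = sum(designs[n] @ st["beta"][n] for n, _ in self.blocks)

        # --- clinical covariates (normal prior, variance not sigma^2-scaled)
        if self.n_gamma:
            st["gamma"] = sample_coefficients_block(
                y - lasso_fit, self.C, np.full(self.n_gamma, self.hyper.v_gamma), sigma, rng
            )
        cov_fit = self.C @ st["gamma"]

        # --- lasso coefficient blocks
        for name, _ in self.blocks:
            others = sum(designs[n] @ st["beta"][n] for n, _ in self.blocks if n != name)
            resid = y - cov_fit - others
            st["beta"][name] = sample_coefficients_block(
                resid, designs[name], st["sigma2"] * st["tau2"][name], sigma, rng
            )

        # --- mixing scales and shrinkage
        for name, _ in self.blocks:
            lam = float(np.sqrt(st["lam2"][name]))
            st["tau2"][name] = sample_mixing_scales(st["beta"][name], lam, sigma, rng)
        for name, _ in self.blocks:
            st["lam2"][name] = sample_shrinkage(
                st["tau2"][name], len(st["beta"][name]), self.block_hyper[name], rng
            )

        # --- error variances
        if self.family != "binary":  # probit fixes the latent variance at 1
            full_fit = cov_fit + sum(designs[n] @ st["beta"][n] for n, _ in self.blocks)
            beta_all = np.concatenate([st["beta"][n] for n, _ in self.blocks])
            tau2_all = np.concatenate([st["tau2"][n] for n, _ in self.blocks])
            st["sigma2"] = sample_error_variance(
                y - full_fit, beta_all, tau2_all, rng,
                prior_shape=self.hyper.sigma2_shape, prior_rate=self.hyper.sigma2_rate,
            )
        if self.model == "unified" and self.mapped and self.cfg.resample_sigma_k:
            for i, gene in enumerate(self.mapped):
                idx = self.probe_idx[i]
                resid = self.expr_c[:, self.gene_pos[gene]] - self.meth_c[:, idx] @ st["omega"][i]
                shape = self.hyper.sigma2_shape + self.n / 2.0
                rate = self.hyper.sigma2_rate + float(resid @ resid) / 2.0
                if self.omega_lasso[i]:
                    shape += len(idx) / 2.0
                    rate += float(np.sum(st["omega"][i] ** 2 / (2.0 * st["omega_tau2"][i])))
                st["sigma_k2"][i] = 1.0 / rng.gamma(shape, 1.0 / rate)

        # --- latent response
        if self.family != "continuous":
            designs = self._designs(st)
            fit = self.C @ st["gamma"] + sum(designs[n] @ st["beta"][n] for n, _ in self.blocks)
            if self.family == "binary":
                st["z"] = sample_latent_binary(self.y_bin, fit, rng)
            else:
                st["z"] = sample_latent_survival(
                    self.t, self.delta, fit, float(np.sqrt(st["sigma2"])), rng
                )

        for name, _ in self.blocks:
            if not np.all(np.isfinite(st["beta"][name])):
                raise FloatingPointError(f"divergent state in coefficient block {name!r}")
        return st

    def sample_data(self, st: dict[str, Any], rng: np.random.Generator) -> None:
        """Regenerate the random data given the parameter state (in place).

        Mapped genes' expression is redrawn from the mechanistic layer
        and the (centered-scale) response from the clinical layer.
        Used by joint-distribution (Geweke-style) diagnostics; only
        meaningful with a fully proper prior.
        """
        for i, gene in enumerate(self.mapped):
            idx = self.probe_idx[i]
            mean = self.meth_c[:, idx] @ st["omega"][i]
            self.expr_c[:, self.gene_pos[gene]] = mean + np.sqrt(st["sigma_k2"][i]) * rng.standard_normal(self.n)
        designs = self._designs(st)
        fit = self.C @ st["gamma"] + sum(designs[n] @ st["beta"][n] for n, _ in self.blocks)
        noise = np.sqrt(st["sigma2"]) * rng.standard_normal(self.n)
        if self.family == "continuous":
            self.y0 = fit + noise
        else:
            st["z"] = fit + noise

    # ------------------------------------------------------------------ run

    def run(self) -> PosteriorSamples:
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)
        st = self.init_state()
        S = cfg.n_retained
        draws: dict[str, np.ndarray] = {
            "gamma": np.empty((S, self.n_gamma)),
            "sigma2": np.empty(S),
        }
        for name, cols in self.blocks:
            draws[f"beta_{name}"] = np.empty((S, len(cols)))
            draws[f"tau2_{name}"] = np.empty((S, len(cols)))
            draws[f"lam2_{name}"] = np.empty(S)
        if self.mapped:
            draws["omega"] = np.empty((S, self.n_omega))
            draws["sigma_k2"] = np.empty((S, len(self.mapped)))
        if self.family != "continuous":
            draws["z"] = np.empty((S, self.n))

        s = 0
        for it in range(cfg.iterations):
            self.step(st, rng)
            if it >= cfg.burnin and (it - cfg.burnin) % cfg.thin == 0:
                draws["gamma"][s] = st["gamma"]
                draws["sigma2"][s] = st["sigma2"]
                for name, _ in self.blocks:
                    draws[f"beta_{name}"][s] = st["beta"][name]
                    draws[f"tau2_{name}"][s] = st["tau2"][name]
                    draws[f"lam2_{name}"][s] = st["lam2"][name]
                if self.mapped:
                    draws["omega"][s] = np.concatenate(st["omega"])
                    draws["sigma_k2"][s] = st["sigma_k2"]
                if self.family != "continuous":
                    draws["z"][s] = st["z"]
                s += 1

        return PosteriorSamples(
            model=self.model,
            family=self.family,
            config=cfg,
            draws=draws,
            block_names=tuple(n for n, _ in self.blocks),
            block_labels={n: c for n, c in self.blocks},
            gamma_labels=self.gamma_labels,
            mapped_genes=tuple(self.mapped),
            probe_slices=dict(self.probe_slices),
            centers={
                "expression": self.expr_mean,
                "methylation": self.meth_mean,
                "covariates": self.cov_mean,
                "y": self.y_mean,
            },
            scales={n: self.col_scale[n].copy() for n, _ in self.blocks},
        )


def run_unified(ds: GenomicsDataset, cfg: McmcConfig) -> PosteriorSamples:
    """Fit the unified integrative model by joint Gibbs sampling."""
    return GibbsSampler(ds, cfg, "unified").run()


def run_two_stage(ds: GenomicsDataset, cfg: McmcConfig) -> PosteriorSamples:
    """Fit mechanistic OLS per gene, then the clinical lasso on the frozen partition."""
    loadings = fit_all_genes(ds)
    return GibbsSampler(ds, cfg, "two_stage", loadings=loadings).run()


def fit_nonint(ds: GenomicsDataset, cfg: McmcConfig) -> PosteriorSamples:
    """Non-integrative comparator: Bayesian lasso on expression alone."""
    return GibbsSampler(ds, cfg, "nonint").run()


def fit_add(ds: GenomicsDataset, cfg: McmcConfig) -> PosteriorSamples:
    """Additive comparator: Bayesian lasso on [expression | methylation]."""
    return GibbsSampler(ds, cfg, "add").run()


def design_blocks(samples: PosteriorSamples, ds: GenomicsDataset, s: int) -> dict[str, np.ndarray]:
    """Clinical design blocks implied by retained draw ``s``.

    For the integrative models the type-M / type-Mbar columns are
    rebuilt from that draw's gene loadings; for nonint/add the blocks
    are the fixed centered matrices.
    """
    expr_c = ds.expression.to_numpy(dtype=float) - samples.centers["expression"]
    out: dict[str, np.ndarray] = {}
    if samples.model in ("unified", "two_stage"):
        if samples.mapped_genes:
            meth_c = ds.methylation.to_numpy(dtype=float) - samples.centers["methylation"]
            meth_pos = {p: i for i, p in enumerate(ds.methylation.columns)}
            by_gene = ds.probe_map.by_gene()
            gene_pos = {g: i for i, g in enumerate(ds.expression.columns)}
            m_cols = np.empty((len(expr_c), len(samples.mapped_genes)))
            for i, gene in enumerate(samples.mapped_genes):
                lo, hi = samples.probe_slices[gene]
                idx = [meth_pos[p] for p in by_gene[gene]]
                m_cols[:, i] = meth_c[:, idx] @ samples.draws["omega"][s, lo:hi]
            mbar = expr_c.copy()
            mbar[:, [gene_pos[g] for g in samples.mapped_genes]] -= m_cols
            out["m"] = m_cols
            out["mbar"] = mbar
        else:
            out["mbar"] = expr_c
    elif samples.model == "nonint":
        out["g"] = expr_c
    else:
        out["g"] = expr_c
        if "meth" in samples.block_names:
            out["meth"] = ds.methylation.to_numpy(dtype=float) - samples.centers["methylation"]
    return {name: out[name] / samples.scales[name] for name in out}


def predict(samples: PosteriorSamples, ds_new: GenomicsDataset) -> np.ndarray:
    """Posterior-mean linear predictor for new samples.

    New data are centered with the training means.  For survival
    outcomes the returned value is the predicted log survival time; for
    binary outcomes the probit score.
    """
    expr_c = ds_new.expression.to_numpy(dtype=float) - samples.centers["expression"]
    cov_c = ds_new.covariates.to_numpy(dtype=float) - samples.centers["covariates"] \
        if ds_new.covariates.shape[1] else np.zeros((len(expr_c), 0))
    C = cov_c
    if samples.family != "continuous":
        C = np.hstack([np.ones((len(expr_c), 1)), cov_c])
    pred = C @ samples.draws["gamma"].mean(axis=0) + samples.centers["y"]

    means = {n: samples.draws[f"beta_{n}"].mean(axis=0) for n in samples.block_names}
    if samples.model in ("unified", "two_stage") and samples.mapped_genes:
        meth_c = ds_new.methylation.to_numpy(dtype=float) - samples.centers["methylation"]
        meth_pos = {p: i for i, p in enumerate(ds_new.methylation.columns)}
        by_gene = ds_new.probe_map.by_gene()
        gene_pos = {g: i for i, g in enumerate(ds_new.expression.columns)}
        omega_mean = samples.draws["omega"].mean(axis=0)
        m_cols = np.empty((len(expr_c), len(samples.mapped_genes)))
        for i, gene in enumerate(samples.mapped_genes):
            lo, hi = samples.probe_slices[gene]
            idx = [meth_pos[p] for p in by_gene[gene]]
            m_cols[:, i] = meth_c[:, idx] @ omega_mean[lo:hi]
        mbar = expr_c.copy()
        mbar[:, [gene_pos[g] for g in samples.mapped_genes]] -= m_cols
        pred = pred + (m_cols / samples.scales["m"]) @ means["m"]
        pred = pred + (mbar / samples.scales["mbar"]) @ means["mbar"]
    else:
        pred = pred + (expr_c / samples.scales["g"]) @ means["g"]
        if "meth" in means:
            meth_c = ds_new.methylation.to_numpy(dtype=float) - samples.centers["methylation"]
            pred = pred + (meth_c / samples.scales["meth"]) @ means["meth"]
    return pred


def save_posterior(samples: PosteriorSamples, outdir) -> None:
    """Persist retained draws (.npz) and structural metadata (JSON)."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(outdir / "draws.npz", **samples.draws)
    meta = {
        "model": samples.model,
        "family": samples.family,
        "config": asdict(samples.config),
        "block_names": list(samples.block_names),
        "block_labels": {k: list(v) for k, v in samples.block_labels.items()},
        "gamma_labels": list(samples.gamma_labels),
        "mapped_genes": list(samples.mapped_genes),
        "probe_slices": {k: list(v) for k, v in samples.probe_slices.items()},
        "centers": {k: (np.asarray(v).tolist()) for k, v in samples.centers.items()},
        "scales": {k: np.asarray(v).tolist() for k, v in samples.scales.items()},
    }
    (outdir / "posterior.json").write_text(json.dumps(meta, indent=2))


def load_posterior(outdir) -> PosteriorSamples:
    """Reload a posterior written by :func:`save_posterior`."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    meta = json.loads((outdir / "posterior.json").read_text())
    with np.load(outdir / "draws.npz") as npz:
        draws = {k: npz[k] for k in npz.files}
    for required in ("sigma2", "gamma"):
        if required not in draws:
            raise ValueError(f"draws file is missing the {required!r} field")
    for name in meta["block_names"]:
        if f"lam2_{name}" not in draws:
            raise ValueError(f"draws file is missing lam2 for block {name!r}")
    hyper = HyperConfig(**meta["config"].pop("hyper"))
    cfg = McmcConfig(hyper=hyper, **meta["config"])
    return PosteriorSamples(
        model=meta["model"],
        family=meta["family"],
        config=cfg,
        draws=draws,
        block_names=tuple(meta["block_names"]),
        block_labels={k: tuple(v) for k, v in meta["block_labels"].items()},
        gamma_labels=tuple(meta["gamma_labels"]),
        mapped_genes=tuple(meta["mapped_genes"]),
        probe_slices={k: (v[0], v[1]) for k, v in meta["probe_slices"].items()},
        centers={k: np.asarray(v) for k, v in meta["centers"].items()},
        scales={k: np.asarray(v) for k, v in meta["scales"].items()},
    )


def fit_sg(ds: GenomicsDataset) -> pd.DataFrame:
    """Single-gene comparator: one classical regression per gene.

    For each gene the outcome is regressed on that gene's expression,
    its mapped methylation probes and the clinical covariates; the
    reported p-value tests the gene's expression+methylation terms
    jointly (F-test for continuous outcomes, likelihood-ratio test for
    binary/probit and censored/log-normal-AFT outcomes).  Genes whose
    design leaves fewer than one residual degree of freedom get an NA
    p-value.
    """
    import statsmodels.api as sm

    out = ds.outcome
    by_gene = ds.probe_map.by_gene()
    cov = ds.covariates.to_numpy(dtype=float) if ds.covariates.shape[1] else np.zeros((ds.n_samples, 0))
    rows = []
    for gene in ds.genes:
        cols = [ds.expression[gene].to_numpy(dtype=float)]
        cols += [ds.methylation[p].to_numpy(dtype=float) for p in by_gene.get(gene, [])]
        gene_terms = np.column_stack(cols)
        X_full = np.hstack([np.ones((ds.n_samples, 1)), cov, gene_terms])
        X_null = np.hstack([np.ones((ds.n_samples, 1)), cov])
        q = gene_terms.shape[1]
        if ds.n_samples - X_full.shape[1] < 1:
            rows.append((gene, np.nan))
            continue
        if out.family == "continuous":
            full = sm.OLS(out.values, X_full).fit()
            null = sm.OLS(out.values, X_null).fit()
            df_denom = ds.n_samples - X_full.shape[1]
            f = (null.ssr - full.ssr) / q / (full.ssr / df_denom)
            from scipy import stats as sps
            pval = float(sps.f.sf(f, q, df_denom))
        elif out.family == "binary":
            full = sm.Probit(out.values, X_full).fit(disp=0)
            null = sm.Probit(out.values, X_null).fit(disp=0)
            from scipy import stats as sps
            pval = float(sps.chi2.sf(2 * (full.llf - null.llf), q))
        else:
            pval = _sg_survival_pvalue(out, cov, gene_terms)
        rows.append((gene, pval))
    return pd.DataFrame(rows, columns=["gene_id", "p_value"])


def _sg_survival_pvalue(out, cov: np.ndarray, gene_terms: np.ndarray) -> float:
    """Likelihood-ratio test of a gene's terms in a log-normal AFT model."""
    from lifelines import LogNormalAFTFitter
    from scipy import stats as sps

    q = gene_terms.shape[1]

    def _fit(X: np.ndarray) -> float:
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
        df["time"] = out.values
        df["event"] = out.event
        f = LogNormalAFTFitter(penalizer=0.0)
        f.fit(df, duration_col="time", event_col="event")
        return float(f.log_likelihood_)

    try:
        ll_full = _fit(np.hstack([cov, gene_terms]) if cov.size else gene_terms)
        ll_null = _fit(cov) if cov.size else _fit(np.zeros((len(out.values), 0)))
        return float(sps.chi2.sf(max(2 * (ll_full - ll_null), 0.0), q))
    except Exception:
        return float("nan")
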