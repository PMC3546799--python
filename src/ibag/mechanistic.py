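"""Mechanistic layer: per-gene regression of expression on promoter methylation.

For gene k with mapped probes the model is

    g_k = M_(k) omega_k + mbar_k,     mbar_k ~ N(0, sigma_k^2 I),

so that expression splits into a methylation-modulated component
``M_(k) omega_k`` (the "type M" predictor of the clinical layer) and a
residual component ``mbar_k`` driven by other mechanisms (the "type
Mbar" predictor).  Genes without promoter probes contribute their
centered expression as a type-Mbar predictor only.

Expression and methylation columns are mean-centered before modeling;
the intercept of each per-gene regression is absorbed by centering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenomicsDataset

__all__ = [
    "GeneLoadings",
    "ExpressionPartition",
    "fit_mechanistic_ols",
    "fit_all_genes",
    "partition_expression",
]

SIGMA_FLOOR = 1e-8  # keeps downstream conditionals proper when a fit is exact


@dataclass(frozen=True)
class GeneLoadings:
    """Per-gene methylation loadings omega_k and residual scales sigma_k."""

    omega: dict[str, np.ndarray]
    sigma: dict[str, float]
    probes: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for gene, om in self.omega.items():
            if len(om) != len(self.probes[gene]):
                raise ValueError(f"gene {gene!r}: loading length != mapped probe count")
            if self.sigma[gene] <= 0:
                raise ValueError(f"gene {gene!r}: sigma_k must be positive")


@dataclass(frozen=True)
class ExpressionPartition:
    """Expression split into methylation-modulated and other-mechanism parts.

    ``m_part`` has one column per mapped gene (``M_(k) omega_k``);
    ``mbar_part`` has one column per gene: the mechanistic residual for
    mapped genes, the centered expression itself for unmapped genes.
    For every mapped gene the two columns sum to the centered
    expression exactly.
    """

    m_part: pd.DataFrame
    mbar_part: pd.DataFrame

    @property
    def mapped_genes(self) -> tuple[str, ...]:
        return tuple(self.m_part.columns)


def fit_mechanistic_ols(
    g_k: np.ndarray, m_k: np.ndarray, *, strict: bool = False
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Least-squares fit of one gene's expression on its probe submatrix.

    Both sides are mean-centered, which absorbs the intercept.  Returns
    ``(omega_hat, sigma_hat, fitted, residual)`` with
    ``fitted + residual`` equal to the centered expression exactly and
    ``sigma_hat^2 = RSS / (N - J_k - 1)``.  A rank-deficient design is
    resolved by the minimum-norm solution with a warning (an error
    under ``strict``); an exact fit is floored at a tiny positive
    ``sigma_hat`` so downstream variance conditionals stay proper.
    """
    g = np.asarray(g_k, dtype=float)
    M = np.asarray(m_k, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    n, j_k = M.shape
    if g.shape != (n,):
        raise ValueError("expression vector and probe matrix disagree on sample count")
    gc = g - g.mean()
    Mc = M - M.mean(axis=0)

    omega, _, rank, _ = np.linalg.lstsq(Mc, gc, rcond=None)
    if rank < j_k:
        if strict:
            raise ValueError("rank-deficient probe design (collinear probe columns)")
        warnings.warn("rank-deficient probe design; using minimum-norm solution", stacklevel=2)
    fitted = Mc @ omega
    residual = gc - fitted
    dof = max(n - j_k - 1, 1)
    sigma = float(np.sqrt(residual @ residual / dof))
    if sigma < SIGMA_FLOOR:
        warnings.warn("degenerate mechanistic fit (zero residual); flooring sigma_k", stacklevel=2)
        sigma = SIGMA_FLOOR
    return omega, sigma, fitted, residual


def fit_all_genes(ds: GenomicsDataset, *, strict: bool = False) -> GeneLoadings:
    """Run the per-gene mechanistic regression for every mapped gene."""
    by_gene = ds.probe_map.by_gene()
    meth = ds.methylation
    omega: dict[str, np.ndarray] = {}
    sigma: dict[str, float] = {}
    probes: dict[str, tuple[str, ...]] = {}
    for gene in ds.mapped_genes:
        cols = by_gene[gene]
        om, sd, _, _ = fit_mechanistic_ols(
            ds.expression[gene].to_numpy(), meth[cols].to_numpy(), strict=strict
        )
        omega[gene] = om
        sigma[gene] = sd
        probes[gene] = tuple(cols)
    return GeneLoadings(omega=omega, sigma=sigma, probes=probes)


def partition_expression(ds: GenomicsDataset, loadings: GeneLoadings) -> ExpressionPartition:
    """Build the two clinical-design blocks from a set of loadings.

    For mapped gene k the type-M column is ``M_(k)c omega_k`` (centered
    probe columns) and the type-Mbar column is the centered expression
    minus that; unmapped genes get a single type-Mbar column equal to
    their centered expression.
    """
    by_gene = ds.probe_map.by_gene()
    expr_c = ds.expression - ds.expression.mean(axis=0)
    meth_c = ds.methylation - ds.methylation.mean(axis=0)

    m_cols: dict[str, np.ndarray] = {}
    mbar_cols: dict[str, np.ndarray] = {}
    for gene in ds.genes:
        gc = expr_c[gene].to_numpy()
        if gene in by_gene:
            if gene not in loadings.omega:
                raise ValueError(f"no loadings supplied for mapped gene {gene!r}")
            om = np.asarray(loadings.omega[gene], dtype=float)
            cols = by_gene[gene]
            if len(om) != len(cols):
                raise ValueError(f"gene {gene!r}: loading length != mapped probe count")
            fitted = meth_c[cols].to_numpy() @ om
            m_cols[gene] = fitted
            mbar_cols[gene] = gc - fitted
        else:
            mbar_cols[gene] = gc

    index = list(ds.sample_ids)
    m_part = pd.DataFrame(m_cols, index=index, columns=[g for g in ds.genes if g in m_cols])
    mbar_part = pd.DataFrame(mbar_cols, index=index, columns=list(ds.genes))
    return ExpressionPartition(m_part=m_part, mbar_part=mbar_part)
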