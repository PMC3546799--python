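"""Synthetic data generator with known truth.

The generator emulates a two-platform tumor study: methylation
beta-values drawn independently from Uniform(0, 1), expression of
methylation-regulated genes linearly repressed by their promoter probe
(negative slope) plus Gaussian noise, expression of the remaining genes
standard normal, and a clinical outcome built from three disjoint
truth groups of genes:

* group 1 — genes whose effect on the outcome runs only through the
  methylation-modulated expression component (type M), the first
  ``group_size`` mapped genes;
* group 2 — genes with only an other-mechanisms (type Mbar) effect,
  the first ``group_size`` unmapped genes;
* group 3 — genes with both effect types, the last ``group_size``
  mapped genes.

The mechanistic noise scale is calibrated so the methylation-expression
correlation of regulated genes hits a target ``rho``; the study grid
crosses four gene-set sizes with three correlation levels (twelve
scenarios).  Identical ``(seed, replicate)`` pairs give bit-identical
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GenomicsDataset, OutcomeSpec, ProbeGeneMap, validate_dataset

__all__ = [
    "SimConfig",
    "SimTruth",
    "calibrate_noise_to_correlation",
    "simulate_dataset",
    "scenario_grid",
    "write_dataset",
]

K_GRID = (400, 600, 800, 1000)
RHO_GRID = (-0.8, -0.6, -0.4)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    ``n`` samples, ``k`` genes of which the first ``j`` carry one
    promoter methylation probe each, target methylation-expression
    correlation ``rho`` for regulated genes, generative slope of the
    methylation effect on expression (negative: methylation represses
    transcription), effect sizes of the two component types and the
    clinical noise SD.  ``censoring`` is the target censoring fraction
    for survival outcomes.
    """

    n: int = 200
    k: int = 1000
    j: int = 200
    rho: float = -0.6
    slope: float = -1.0
    b_m: float = 1.0
    b_mbar: float = 1.0
    sigma_y: float = 1.0
    group_size: int = 20
    replicates: int = 10
    seed: int = 0
    outcome: str = "continuous"
    censoring: float = 0.3

    def __post_init__(self) -> None:
        if self.j > self.k:
            raise ValueError("j (genes with methylation) cannot exceed k")
        if not -1.0 < self.rho < 0.0:
            raise ValueError("rho must lie in (-1, 0)")
        if self.j < 2 * self.group_size:
            raise ValueError("truth groups 1 and 3 need j >= 2 * group_size mapped genes")
        if self.k < self.j + self.group_size:
            raise ValueError("truth group 2 needs k >= j + group_size genes")
        if self.outcome not in ("continuous", "binary", "survival"):
            raise ValueError(f"unknown outcome family {self.outcome!r}")
        if not 0.0 <= self.censoring < 1.0:
            raise ValueError("censoring fraction must lie in [0, 1)")


@dataclass(frozen=True)
class SimTruth:
    """Generative ground truth of one replicate."""

    group1: tuple[str, ...]
    group2: tuple[str, ...]
    group3: tuple[str, ...]
    beta_m: pd.Series  # per mapped gene
    beta_mbar: pd.Series  # per gene
    omega: pd.Series  # generative slope per mapped gene
    sigma_m: float

    @property
    def true_genes(self) -> tuple[str, ...]:
        return self.group1 + self.group2 + self.group3

    def group_of(self, gene: str) -> int:
        for num, grp in ((1, self.group1), (2, self.group2), (3, self.group3)):
            if gene in grp:
                return num
        return 0


def calibrate_noise_to_correlation(rho: float, slope: float = -1.0) -> float:
    """Mechanistic noise SD hitting a target methylation-expression correlation.

    With ``m ~ Uniform(0,1)`` (variance 1/12) and
    ``g = slope*m + eps``, ``eps ~ N(0, sigma_m^2)``, the squared
    correlation is ``slope^2/12 / (slope^2/12 + sigma_m^2)``; solving
    for ``sigma_m`` gives the closed form returned here.
    """
    if not 0.0 < abs(rho) < 1.0:
        raise ValueError("rho must satisfy 0 < |rho| < 1")
    if slope == 0.0:
        raise ValueError("slope must be non-zero")
    return float(abs(slope) * np.sqrt((1.0 / rho**2 - 1.0) / 12.0))


def simulate_dataset(cfg: SimConfig, replicate: int = 0) -> tuple[GenomicsDataset, SimTruth]:
    """Generate one replicate dataset plus its ground truth."""
    rng = np.random.default_rng([int(cfg.seed), int(replicate)])
    gs = cfg.group_size
    genes = [f"gene_{i + 1:04d}" for i in range(cfg.k)]
    probes = [f"probe_{i + 1:04d}" for i in range(cfg.j)]
    sigma_m = calibrate_noise_to_correlation(cfg.rho, cfg.slope)

    meth = rng.uniform(0.0, 1.0, size=(cfg.n, cfg.j))
    eps_m = rng.standard_normal((cfg.n, cfg.j)) * sigma_m
    expr = np.empty((cfg.n, cfg.k))
    m_component = cfg.slope * meth  # methylation-modulated expression
    expr[:, : cfg.j] = m_component + eps_m
    expr[:, cfg.j :] = rng.standard_normal((cfg.n, cfg.k - cfg.j))

    group1 = tuple(genes[:gs])
    group2 = tuple(genes[cfg.j : cfg.j + gs])
    group3 = tuple(genes[cfg.j - gs : cfg.j])

    beta_m = pd.Series(0.0, index=genes[: cfg.j])
    beta_m[list(group1)] = cfg.b_m
    beta_m[list(group3)] = cfg.b_m
    beta_mbar = pd.Series(0.0, index=genes)
    beta_mbar[list(group2)] = cfg.b_mbar
    beta_mbar[list(group3)] = cfg.b_mbar

    # linear predictor from the generative clinical model: type-M effects act
    # on the modulated component, type-Mbar effects on the other-mechanisms
    # component (the mechanistic residual for mapped genes, the whole
    # expression for unmapped genes)
    mbar_component = np.hstack([eps_m, expr[:, cfg.j :]])
    lin = m_component @ beta_m.to_numpy() + mbar_component @ beta_mbar.to_numpy()

    noise = rng.standard_normal(cfg.n) * cfg.sigma_y
    if cfg.outcome == "continuous":
        values, event = lin + noise, None
        family = "continuous"
    elif cfg.outcome == "binary":
        values = (lin - lin.mean() + noise > 0).astype(float)
        event, family = None, "binary"
    else:
        log_t = lin + noise
        t = np.exp(log_t)
        if cfg.censoring > 0:
            from scipy.stats import norm

            shift = -np.sqrt(2.0) * cfg.sigma_y * norm.ppf(cfg.censoring)
            log_c = lin + rng.standard_normal(cfg.n) * cfg.sigma_y + shift
            c = np.exp(log_c)
            event = (t <= c).astype(float)
            values = np.minimum(t, c)
        else:
            event = np.ones(cfg.n)
            values = t
        family = "survival"

    sample_ids = tuple(f"sample_{i + 1:04d}" for i in range(cfg.n))
    ds = GenomicsDataset(
        sample_ids=sample_ids,
        expression=pd.DataFrame(expr, index=list(sample_ids), columns=genes),
        methylation=pd.DataFrame(meth, index=list(sample_ids), columns=probes),
        covariates=pd.DataFrame(index=list(sample_ids)),
        outcome=OutcomeSpec(family, sample_ids, values, event),
        probe_map=ProbeGeneMap(entries=tuple(zip(probes, genes[: cfg.j]))),
    )
    truth = SimTruth(
        group1=group1,
        group2=group2,
        group3=group3,
        beta_m=beta_m,
        beta_mbar=beta_mbar,
        omega=pd.Series(cfg.slope, index=genes[: cfg.j]),
        sigma_m=sigma_m,
    )
    return validate_dataset(ds), truth


def scenario_grid(base: SimConfig = SimConfig()) -> list[SimConfig]:
    """The twelve (k, rho) study scenarios."""
    from dataclasses import replace

    return [replace(base, k=k, rho=rho) for k in K_GRID for rho in RHO_GRID]


def write_dataset(ds: GenomicsDataset, truth: SimTruth | None, outdir: str | Path) -> None:
    """Write the standard dataset TSVs (plus truth.tsv when available)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.expression.rename_axis("sample_id").to_csv(outdir / "expression.tsv", sep="\t", float_format="%.17g")
    ds.methylation.rename_axis("sample_id").to_csv(outdir / "methylation.tsv", sep="\t", float_format="%.17g")
    if ds.covariates.shape[1]:
        ds.covariates.rename_axis("sample_id").to_csv(outdir / "covariates.tsv", sep="\t", float_format="%.17g")
    out = pd.DataFrame({"sample_id": ds.sample_ids, "value": ds.outcome.values})
    if ds.outcome.event is not None:
        out["event"] = ds.outcome.event.astype(int)
    out.to_csv(outdir / "outcome.tsv", sep="\t", index=False, float_format="%.17g")
    pd.DataFrame(ds.probe_map.entries).to_csv(
        outdir / "probe_map.tsv", sep="\t", index=False, header=False
    )
    if truth is not None:
        rows = []
        for gene in ds.genes:
            rows.append(
                (
                    gene,
                    truth.group_of(gene),
                    float(truth.beta_m.get(gene, 0.0)),
                    float(truth.beta_mbar.get(gene, 0.0)),
                )
            )
        pd.DataFrame(rows, columns=["gene_id", "group", "true_beta_M", "true_beta_Mbar"]).to_csv(
            outdir / "truth.tsv", sep="\t", index=False
        )
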