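"""Data model and readers for expression, methylation, outcome and annotation tables.

All rectangular inputs are TSV files with a header row of feature
identifiers and a first column of sample identifiers; matrices are held
as :class:`pandas.DataFrame` with samples in rows and features in
columns.  Genomic coordinates follow the BED convention: 0-based,
half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicsDataset",
    "OutcomeSpec",
    "ProbeGeneMap",
    "load_matrix",
    "load_outcome",
    "load_probe_map",
    "load_dataset",
    "read_bed",
    "read_gff3_genes",
    "map_probes_to_promoters",
    "validate_dataset",
]

OUTCOME_FAMILIES = ("continuous", "binary", "survival")


@dataclass(frozen=True)
class OutcomeSpec:
    """Clinical outcome for N samples.

    ``family`` is one of ``continuous`` (real response), ``binary``
    (0/1 class) or ``survival`` (observed time plus a 0/1 event
    indicator, 1 meaning the event was observed rather than censored).
    """

    family: str
    sample_ids: tuple[str, ...]
    values: np.ndarray
    event: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.family not in OUTCOME_FAMILIES:
            raise ValueError(f"unknown outcome family {self.family!r}")
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or len(values) != len(self.sample_ids):
            raise ValueError("outcome values must be one per sample")
        if not np.all(np.isfinite(values)):
            raise ValueError("outcome values must be finite")
        if self.family == "binary" and not np.isin(values, (0.0, 1.0)).all():
            raise ValueError("binary outcome values must lie in {0, 1}")
        if self.family == "survival":
            if np.any(values <= 0):
                raise ValueError("survival times must be strictly positive")
            if self.event is None:
                raise ValueError("survival outcome requires an event indicator")
            event = np.asarray(self.event, dtype=float)
            if event.shape != values.shape or not np.isin(event, (0.0, 1.0)).all():
                raise ValueError("event indicators must be 0/1, one per sample")
            object.__setattr__(self, "event", event)
        elif self.event is not None:
            raise ValueError(f"event indicator only valid for survival, not {self.family}")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)

    def subset(self, ids: Sequence[str]) -> "OutcomeSpec":
        """Restrict to ``ids`` (in the given order)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return OutcomeSpec(
            family=self.family,
            sample_ids=tuple(ids),
            values=self.values[idx],
            event=None if self.event is None else self.event[idx],
        )


@dataclass(frozen=True)
class ProbeGeneMap:
    """Many-to-many assignment of methylation probes to genes.

    A probe may fall in the promoter of more than one gene; genes with
    no mapped probe are permitted and are treated downstream as not
    regulated by methylation.
    """

    entries: tuple[tuple[str, str], ...]

    def probes_for(self, gene: str) -> tuple[str, ...]:
        return tuple(p for p, g in self.entries if g == gene)

    def by_gene(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for probe, gene in self.entries:
            out.setdefault(gene, []).append(probe)
        return out

    @property
    def genes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for _, g in self.entries:
            seen.setdefault(g)
        return tuple(seen)

    @property
    def probes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p, _ in self.entries:
            seen.setdefault(p)
        return tuple(seen)


@dataclass(frozen=True)
class GenomicsDataset:
    """Aligned multi-platform dataset for N samples.

    ``expression`` is N x K (log-scale), ``methylation`` N x J
    (beta-values in [0, 1]), ``covariates`` N x L (possibly L = 0), all
    sharing one sample order with ``outcome``.
    """

    sample_ids: tuple[str, ...]
    expression: pd.DataFrame
    methylation: pd.DataFrame
    covariates: pd.DataFrame
    outcome: OutcomeSpec
    probe_map: ProbeGeneMap
    validated: bool = field(default=False, compare=False)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.expression.columns)

    @property
    def mapped_genes(self) -> tuple[str, ...]:
        """Genes with at least one promoter probe, in expression column order."""
        with_probes = set(self.probe_map.by_gene())
        return tuple(g for g in self.expression.columns if g in with_probes)

    @property
    def unmapped_genes(self) -> tuple[str, ...]:
        with_probes = set(self.probe_map.by_gene())
        return tuple(g for g in self.expression.columns if g not in with_probes)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    return df


def load_matrix(path: str | Path) -> pd.DataFrame:
    """Read a samples-by-features TSV matrix.

    The header row holds feature IDs and the first column sample IDs.
    Raises :class:`ValueError` on duplicate identifiers or any
    non-numeric cell (naming the offending row and column).
    """
    df = _read_tsv(path)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs in {path}: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature IDs in {path}: {dups}")
    try:
        out = df.astype(float)  # numpy's parser round-trips %.17g exactly
    except (ValueError, TypeError):
        # locate the first bad cell for a precise message
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            if bad.any():
                row = df.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"non-numeric value {df.at[row, col]!r} at row {row!r}, column {col!r} in {path}"
                ) from None
        raise
    if out.isna().to_numpy().any():
        col = out.columns[out.isna().any(axis=0).to_numpy().argmax()]
        row = out.index[out[col].isna().to_numpy().argmax()]
        raise ValueError(f"missing value at row {row!r}, column {col!r} in {path}")
    return out.astype(float)


def load_outcome(path: str | Path, family: str) -> OutcomeSpec:
    """Read an outcome TSV (columns: sample_id, value [, event])."""
    df = pd.read_csv(path, sep="\t", header=0, index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        raise ValueError(f"duplicate sample IDs in outcome table {path}")
    if df.shape[1] < 1:
        raise ValueError(f"outcome table {path} needs a value column")
    values = pd.to_numeric(df.iloc[:, 0], errors="raise").to_numpy(dtype=float)
    event = None
    if family == "survival":
        if df.shape[1] < 2:
            raise ValueError("survival outcome requires an event column")
        event = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(dtype=float)
    return OutcomeSpec(family=family, sample_ids=tuple(df.index), values=values, event=event)


def load_probe_map(path: str | Path) -> ProbeGeneMap:
    """Read a two-column (probe_id, gene_id) TSV, header optional-free."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"probe map {path} needs two columns (probe_id, gene_id)")
    return ProbeGeneMap(entries=tuple(zip(df.iloc[:, 0], df.iloc[:, 1])))


_BED_COLS = ("chrom", "start", "end", "name", "score", "strand")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3..BED6 records into a frame with 0-based half-open coordinates."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least chrom/start/end")
    df = df.iloc[:, : min(df.shape[1], 6)]
    df.columns = _BED_COLS[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if "name" not in df:
        df["name"] = [f"{c}:{s}-{e}" for c, s, e in zip(df["chrom"], df["start"], df["end"])]
    return df


def read_gff3_genes(path: str | Path, feature_type: str = "gene") -> pd.DataFrame:
    """Extract gene records from a GFF3 file.

    Returns a BED-like frame (0-based half-open) with a ``strand``
    column; the gene name is taken from the ``ID`` or ``gene_id``
    attribute.
    """
    cols = ["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=cols, dtype=str)
    df = df[df["type"] == feature_type].copy()

    def _name(attrs: str) -> str:
        fields = dict(kv.split("=", 1) for kv in attrs.strip().split(";") if "=" in kv)
        for key in ("ID", "gene_id", "Name"):
            if key in fields:
                return fields[key]
        raise ValueError(f"GFF3 record without ID/gene_id/Name attribute: {attrs!r}")

    out = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "start": df["start"].astype(int).to_numpy() - 1,  # GFF3 is 1-based inclusive
            "end": df["end"].astype(int).to_numpy(),
            "name": [_name(a) for a in df["attributes"]],
            "strand": df["strand"].to_numpy(),
        }
    )
    return out


def _promoter_interval(start: int, end: int, strand: str, upstream: int, downstream: int) -> tuple[int, int]:
    """Promoter window around the TSS, oriented by strand, half-open."""
    if strand == "+":
        tss = start
        return tss - upstream, tss + downstream
    if strand == "-":
        tss = end - 1  # last transcribed base in half-open coordinates
        return tss - downstream + 1, tss + upstream + 1
    raise ValueError(f"gene record missing strand (got {strand!r})")


def map_probes_to_promoters(
    probes: pd.DataFrame,
    genes: pd.DataFrame,
    window: tuple[int, int] = (1500, 500),
) -> ProbeGeneMap:
    """Assign probes to genes whose promoter window they intersect.

    ``probes`` is a BED-like frame (chrom/start/end/name); ``genes``
    additionally needs a strand.  ``window = (upstream, downstream)``
    in bp around the strand-oriented TSS; a probe maps to a gene when
    its interval overlaps the half-open promoter interval.
    """
    upstream, downstream = window
    if upstream < 0 or downstream < 0:
        raise ValueError("promoter window extents must be non-negative")
    if "strand" not in genes.columns:
        raise ValueError("gene records must carry a strand column")

    trees: dict[str, IntervalTree] = {}
    for rec in genes.itertuples(index=False):
        lo, hi = _promoter_interval(int(rec.start), int(rec.end), str(rec.strand), upstream, downstream)
        if hi <= lo:
            continue
        trees.setdefault(str(rec.chrom), IntervalTree()).addi(lo, hi, str(rec.name))

    entries: list[tuple[str, str]] = []
    for rec in probes.itertuples(index=False):
        tree = trees.get(str(rec.chrom))
        if tree is None:
            continue
        start, end = int(rec.start), int(rec.end)
        hits = sorted({iv.data for iv in tree.overlap(start, max(end, start + 1))})
        entries.extend((str(rec.name), g) for g in hits)
    return ProbeGeneMap(entries=tuple(entries))


def load_dataset(directory: str | Path, family: str) -> GenomicsDataset:
    """Load and validate a dataset directory written by the simulator/CLI.

    Expects ``expression.tsv``, ``methylation.tsv``, ``outcome.tsv``
    and ``probe_map.tsv`` (plus optional ``covariates.tsv``).
    """
    directory = Path(directory)
    expression = load_matrix(directory / "expression.tsv")
    methylation = load_matrix(directory / "methylation.tsv")
    cov_path = directory / "covariates.tsv"
    covariates = load_matrix(cov_path) if cov_path.exists() else pd.DataFrame(index=expression.index)
    outcome = load_outcome(directory / "outcome.tsv", family)
    probe_map = load_probe_map(directory / "probe_map.tsv")
    ds = GenomicsDataset(
        sample_ids=tuple(outcome.sample_ids),
        expression=expression,
        methylation=methylation,
        covariates=covariates,
        outcome=outcome,
        probe_map=probe_map,
    )
    return validate_dataset(ds)


def validate_dataset(ds: GenomicsDataset) -> GenomicsDataset:
    """Align and validate a component-wise loaded dataset.

    Takes the complete-case sample intersection across all tables,
    ordered as in the outcome table, and asserts the data-model
    invariants (methylation in [0, 1], no missing values, probe-map
    references resolvable).  Idempotent.
    """
    tables = [ds.expression, ds.methylation]
    if ds.covariates.shape[1] > 0:
        tables.append(ds.covariates)
    common = set(ds.outcome.sample_ids)
    for t in tables:
        common &= set(map(str, t.index))
    ids = tuple(s for s in ds.outcome.sample_ids if s in common)
    if not ids:
        raise ValueError("no samples shared across outcome, expression and methylation tables")

    expr = ds.expression.loc[list(ids)].astype(float)
    meth = ds.methylation.loc[list(ids)].astype(float)
    cov = ds.covariates.loc[list(ids)].astype(float) if ds.covariates.shape[1] else ds.covariates.iloc[:0]
    if cov.shape[1] == 0:
        cov = pd.DataFrame(index=list(ids))

    if expr.shape[1] < 1:
        raise ValueError("expression matrix must contain at least one gene")
    for name, frame in (("expression", expr), ("methylation", meth), ("covariates", cov)):
        if frame.size and frame.isna().to_numpy().any():
            raise ValueError(f"{name} matrix contains missing values after alignment")
    mvals = meth.to_numpy()
    if mvals.size and (mvals.min() < 0.0 or mvals.max() > 1.0):
        raise ValueError("methylation beta-values must lie in [0, 1]")

    probe_cols = set(meth.columns)
    gene_cols = set(expr.columns)
    for probe, gene in ds.probe_map.entries:
        if probe not in probe_cols:
            raise ValueError(f"probe map references unknown methylation column {probe!r}")
        if gene not in gene_cols:
            raise ValueError(f"probe map references unknown gene column {gene!r}")

    return replace(
        ds,
        sample_ids=ids,
        expression=expr,
        methylation=meth,
        covariates=cov,
        outcome=ds.outcome.subset(ids),
        validated=True,
    )
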