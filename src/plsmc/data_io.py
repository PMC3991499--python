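"""Tabular input/output and the aligned expression/phenotype container.

All files are tab-separated UTF-8 text; lines starting with ``#`` are
comments.  The container aligns a genes x samples log2 expression matrix
with a continuous per-sample phenotype (e.g. a disease severity index such
as the Duke CAD index).  Missing values are a load-time error, never
imputed: every downstream stage assumes a complete normalized matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TSV_KWARGS = dict(sep="\t", comment="#", encoding="utf-8")


class DataValidationError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class ExpressionDataset:
    """Log2 expression matrix aligned with a continuous phenotype.

    Attributes
    ----------
    gene_ids : list of str
        Row identifiers (probe ids or gene symbols), unique, length ``p``.
    sample_ids : list of str
        Column identifiers, unique, length ``n``.
    values : ndarray of shape (p, n)
        Log2 expression; rows align with ``gene_ids``, columns with
        ``sample_ids``.
    phenotype : ndarray of shape (n,) or None
        Continuous disease index, one value per sample.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    phenotype: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataValidationError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataValidationError("duplicate sample identifiers")
        if not np.all(np.isfinite(self.values)):
            raise DataValidationError("expression matrix contains non-finite values")
        if self.phenotype is not None:
            self.phenotype = np.asarray(self.phenotype, dtype=float)
            if self.phenotype.shape != (len(self.sample_ids),):
                raise DataValidationError(
                    "phenotype length does not match sample count"
                )
            if not np.all(np.isfinite(self.phenotype)):
                raise DataValidationError("phenotype contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionDataset":
        """Return a new dataset restricted to ``gene_ids`` (given order)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return ExpressionDataset(
            list(gene_ids), list(self.sample_ids),
            self.values[rows, :], self.phenotype,
        )


@dataclass
class AnnotationTable:
    """Flat gene -> term annotation (unique pairs)."""

    pairs: set[tuple[str, str]]
    term_names: dict[str, str] = field(default_factory=dict)

    def genes(self) -> set[str]:
        return {g for g, _ in self.pairs}

    def terms(self) -> set[str]:
        return {t for _, t in self.pairs}

    def genes_by_term(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for g, t in self.pairs:
            out.setdefault(t, set()).add(g)
        return out


@dataclass
class InteractionList:
    """Order-insensitive gene pairs as loaded; dedup happens in the
    network stage."""

    edges: list[tuple[str, str]]


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, transpose: bool = False) -> ExpressionDataset:
    """Read a genes x samples TSV (header row = sample ids, first column =
    gene ids) into an :class:`ExpressionDataset` without phenotype.

    Parameters
    ----------
    path
        TSV file path.
    transpose
        If True the file is samples x genes and is transposed after reading.
    """
    df = pd.read_csv(path, index_col=0, dtype=str, **TSV_KWARGS)
    if transpose:
        df = df.T
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    if len(set(gene_ids)) != len(gene_ids):
        dups = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise DataValidationError(f"duplicate gene ids in {path}: {dups[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise DataValidationError(
            f"non-numeric cell in {path} at gene {gene_ids[i]!r}, "
            f"sample {sample_ids[j]!r}: {df.iat[i, j]!r}"
        )
    return ExpressionDataset(gene_ids, sample_ids, numeric.to_numpy(dtype=float))


def write_expression(ds: ExpressionDataset, path: str | Path) -> None:
    df = pd.DataFrame(ds.values, index=ds.gene_ids, columns=ds.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", encoding="utf-8")


# ---------------------------------------------------------------------------
# phenotype
# ---------------------------------------------------------------------------

def read_phenotype(path: str | Path, header: bool = True) -> dict[str, float]:
    """Read a two-column (sample_id, value) TSV into a mapping."""
    df = pd.read_csv(path, header=0 if header else None, dtype=str, **TSV_KWARGS)
    if df.shape[1] != 2:
        raise DataValidationError(
            f"phenotype file {path} must have exactly 2 columns, got {df.shape[1]}"
        )
    samples = df.iloc[:, 0].astype(str)
    if samples.duplicated().any():
        dup = samples[samples.duplicated()].iloc[0]
        raise DataValidationError(f"duplicate sample id in {path}: {dup!r}")
    values = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if values.isna().any():
        row = int(values.isna().idxmax())
        raise DataValidationError(
            f"non-numeric phenotype value in {path} for sample "
            f"{samples.iloc[row]!r}"
        )
    return dict(zip(samples, values.astype(float)))


def write_phenotype(pheno: Mapping[str, float], path: str | Path) -> None:
    df = pd.DataFrame({"sample_id": list(pheno), "value": list(pheno.values())})
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def attach_phenotype(
    ds: ExpressionDataset,
    pheno: Mapping[str, float],
    intersect: bool = False,
) -> ExpressionDataset:
    """Join a phenotype mapping onto a dataset by sample id.

    Without ``intersect`` any sample present in exactly one of the two
    inputs is an error: nothing is dropped silently.  With ``intersect``
    the common samples are kept (in the dataset's order) and the number of
    dropped samples is logged.
    """
    ds_samples = set(ds.sample_ids)
    ph_samples = set(pheno)
    common = ds_samples & ph_samples
    if not common:
        raise DataValidationError("expression and phenotype share no samples")
    mismatch = ds_samples ^ ph_samples
    if mismatch and not intersect:
        raise DataValidationError(
            f"{len(mismatch)} samples present in only one input "
            f"(e.g. {sorted(mismatch)[:3]}); pass intersect=True to keep "
            "the common samples"
        )
    keep = [s for s in ds.sample_ids if s in common]
    if mismatch:
        logger.info("sample join dropped %d samples not present in both inputs",
                    len(mismatch))
    cols = [ds.sample_ids.index(s) for s in keep]
    return ExpressionDataset(
        list(ds.gene_ids), keep, ds.values[:, cols],
        np.array([pheno[s] for s in keep], dtype=float),
    )


# ---------------------------------------------------------------------------
# annotation and interactions
# ---------------------------------------------------------------------------

def _read_two_column(path: str | Path) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise DataValidationError(
                    f"{path} line {lineno}: expected 2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            rows.append((fields[0], fields[1]))
    return rows


def read_annotation(path: str | Path) -> AnnotationTable:
    """Read a (gene, term) TSV; duplicate pairs are collapsed with a logged
    count."""
    rows = _read_two_column(path)
    pairs = set(rows)
    n_dup = len(rows) - len(pairs)
    if n_dup:
        logger.info("annotation %s: collapsed %d duplicate pairs", path, n_dup)
    return AnnotationTable(pairs)


def write_annotation(table: AnnotationTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g, t in sorted(table.pairs):
            fh.write(f"{g}\t{t}\n")


def read_interactions(path: str | Path) -> InteractionList:
    """Read a (geneA, geneB) TSV; order preserved, no deduplication."""
    return InteractionList(_read_two_column(path))


def write_interactions(ints: InteractionList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in ints.edges:
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# optional probe -> gene collapsing
# ---------------------------------------------------------------------------

def collapse_max_mean(
    ds: ExpressionDataset, probe_to_gene: Mapping[str, str]
) -> ExpressionDataset:
    """Collapse probes to genes keeping, per gene, the probe with the
    highest mean expression.  Probes without a mapping are dropped."""
    means = ds.values.mean(axis=1)
    best: dict[str, tuple[float, int]] = {}
    for i, probe in enumerate(ds.gene_ids):
        gene = probe_to_gene.get(probe)
        if gene is None:
            continue
        if gene not in best or means[i] > best[gene][0]:
            best[gene] = (means[i], i)
    if not best:
        raise DataValidationError("no probes map to any gene")
    genes = sorted(best)
    rows = [best[g][1] for g in genes]
    return ExpressionDataset(genes, list(ds.sample_ids),
                             ds.values[rows, :], ds.phenotype)
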