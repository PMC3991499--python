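"""Normalization steps applied before model fitting.

Two classical microarray normalizations are provided: quantile
normalization (align every array to the mean distribution of order
statistics) and Tukey's iterative median polish (additive
overall + gene + array decomposition), plus removal of zero-variance
genes, which autoscaled PLS cannot accommodate.  Background correction of
raw probe intensities is out of scope; inputs are assumed to be
probe-level log2 values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionDataset

logger = logging.getLogger(__name__)


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize the columns of a p x n matrix.

    Every column is mapped onto the across-column mean of order
    statistics, preserving within-column ranks.  Entries tied within a
    column receive the mean of the reference values at the tied ranks.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    p, n = values.shape
    if n == 1:
        warnings.warn("single-column matrix: quantile normalization is a no-op")
        return values.copy()
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty(p)
        mapped[order] = reference
        # average the reference over runs of tied input values
        sorted_col = col[order]
        start = 0
        for end in range(1, p + 1):
            if end == p or sorted_col[end] != sorted_col[start]:
                if end - start > 1:
                    mapped[order[start:end]] = reference[start:end].mean()
                start = end
        out[:, j] = mapped
    return out


@dataclass
class MedianPolishResult:
    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    n_iter: int
    converged: bool

    def reconstruct(self) -> np.ndarray:
        return (self.overall
                + self.row_effects[:, None]
                + self.col_effects[None, :]
                + self.residuals)


def median_polish(
    values: np.ndarray, tol: float = 0.01, max_iter: int = 10
) -> MedianPolishResult:
    """Tukey's median polish: alternately sweep row and column medians out
    of the residual matrix (rows first).

    Stops when the total absolute residual changes by less than ``tol``
    between iterations, or after ``max_iter`` sweeps.  The decomposition
    ``overall + row + col + residual`` reconstructs the input exactly at
    every iteration.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    r = np.array(values, dtype=float)
    if r.size == 0:
        raise ValueError("empty matrix")
    p, n = r.shape
    overall = 0.0
    row = np.zeros(p)
    col = np.zeros(n)
    prev_sum = np.abs(r).sum()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rmed = np.median(r, axis=1)
        r -= rmed[:, None]
        row += rmed
        cmed_of_row = np.median(row)
        row -= cmed_of_row
        overall += cmed_of_row

        cmed = np.median(r, axis=0)
        r -= cmed[None, :]
        col += cmed
        rmed_of_col = np.median(col)
        col -= rmed_of_col
        overall += rmed_of_col

        cur_sum = np.abs(r).sum()
        if abs(prev_sum - cur_sum) < tol:
            converged = True
            break
        prev_sum = cur_sum
    return MedianPolishResult(overall, row, col, r, it, converged)


def drop_degenerate_genes(
    ds: ExpressionDataset,
) -> tuple[ExpressionDataset, list[str]]:
    """Remove genes with zero variance across samples.

    Returns the filtered dataset and the list of removed gene ids.
    """
    var = ds.values.var(axis=1)
    keep = var > 0.0
    removed = [g for g, k in zip(ds.gene_ids, keep) if not k]
    if not keep.any():
        raise ValueError("all genes have zero variance")
    if removed:
        logger.info("dropped %d zero-variance genes", len(removed))
    out = ExpressionDataset(
        [g for g, k in zip(ds.gene_ids, keep) if k],
        list(ds.sample_ids),
        ds.values[keep, :],
        ds.phenotype,
    )
    return out, removed
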