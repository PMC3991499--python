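"""Hypergeometric over-representation of a selected gene set.

The background is the set of genes both measured on the array and
annotated (not the whole annotation universe).  For a term annotating K
of the N background genes, with n selected background genes of which k
fall in the term, the enrichment p-value is the exact upper tail

    P(X >= k),  X ~ Hypergeometric(N, K, n),

computed in log space through scipy's survival function.  Raw p-values
are the primary output; Benjamini-Hochberg adjustment is appended as an
optional column.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data_io import AnnotationTable


def hypergeom_upper_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(
            f"invalid contingency counts N={N}, K={K}, n={n}, k={k}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    selected: Iterable[str],
    annotation: AnnotationTable,
    background: Iterable[str],
    min_term_size: int = 1,
    bh_adjust: bool = True,
) -> pd.DataFrame:
    """Per-term enrichment of ``selected`` against ``background``.

    ``background`` should be the measured genes; it is intersected with
    the annotated genes to form the universe N, and the selected set is
    intersected with that universe to form n.  One row per term with at
    least ``min_term_size`` annotated background genes, sorted by
    ascending p-value (ties broken by term id for determinism).
    """
    annotated = annotation.genes()
    universe = set(background) & annotated
    sel = set(selected) & universe
    if not universe:
        raise ValueError("no background genes are annotated")
    if not sel:
        raise ValueError("no selected genes in the annotated background")
    N, n = len(universe), len(sel)

    rows = []
    for term, genes in annotation.genes_by_term().items():
        term_bg = genes & universe
        K = len(term_bg)
        if K < min_term_size or K == 0:
            continue
        k = len(term_bg & sel)
        rows.append({
            "term_id": term,
            "term_name": annotation.term_names.get(term, ""),
            "N": N, "K": K, "n": n, "k": k,
            "p_value": hypergeom_upper_pvalue(N, K, n, k),
        })
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table = table.sort_values(["p_value", "term_id"],
                              kind="mergesort").reset_index(drop=True)
    if bh_adjust:
        table["bh_adjusted_p"] = multipletests(
            table["p_value"].to_numpy(), method="fdr_bh")[1]
    return table
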