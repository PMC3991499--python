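"""Gene selection by permutation-FDR on VIP plus Monte-Carlo coefficient
reliability.

The selection funnel has four stages:

1. choose the number of latent components A* by the RMSECV elbow;
2. fit PLS1 on all genes, compute VIP, and estimate a per-gene empirical
   false discovery rate from B response-permutation replicates (pooled
   tail-ratio estimator with monotonization); genes with FDR < alpha are
   *candidates*;
3. refit PLS1 on the candidates over Monte-Carlo half-sample subsets and
   summarize each gene's regression coefficient across subsets as a
   signal-to-noise ratio (mean / sd), the *reliability*;
4. scan absolute-reliability cutoffs and keep the one minimizing RMSECV
   of the model restricted to genes above the cutoff; the final *selected*
   set is candidates with |reliability| strictly above that cutoff.

Defaults mirror the reference analysis: alpha = 0.05, 1,000 permutations,
100 half-sample subsets, 4-fold cross-validation.

The FDR estimator is the pooled permutation-null tail ratio

    FDR(v) = min(1, V(v) / R(v)),
    R(v) = #{observed VIP >= v},
    V(v) = (1/B) * #{null VIP >= v over all replicates},

monotonized so FDR never increases with VIP.  The reliability statistic
follows Monte-Carlo variable-selection practice: a gene matters when its
coefficient is both large and stable across subsamples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ExpressionDataset
from .pls_core import (
    PLSFitError,
    choose_n_components,
    fit_pls1,
    make_folds,
    max_feasible_components,
    rmsecv,
    vip,
)

logger = logging.getLogger(__name__)

#: reliability assigned when the subset coefficients have (numerically)
#: zero spread; passes any finite cutoff
RELIABILITY_SENTINEL = 1e12


def derive_seed(master: int, stage: str) -> int:
    """Per-stage seed derived from a master seed; stable across runs."""
    ss = np.random.SeedSequence([master & 0x7FFFFFFF,
                                 *(ord(c) for c in stage)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class SelectionParams:
    """Tunable parameters of the selection funnel (reference defaults)."""

    A_max: int = 10
    folds: int = 4
    alpha: float = 0.05
    n_perm: int = 1000
    n_subsets: int = 100
    subset_fraction: float = 0.5
    grid_size: int = 100
    rel_tol: float = 0.01
    scale: bool = True
    order: str = "default"       # "default" or "paper"
    seed: int = 0


@dataclass
class SelectionResult:
    """Per-gene statistics and flags of a completed selection run."""

    gene_ids: list[str]
    vip: np.ndarray
    fdr: np.ndarray
    reliability: np.ndarray      # NaN for non-candidates
    candidate: np.ndarray        # bool: fdr < alpha
    selected: np.ndarray         # bool: candidate and |reliability| > cutoff
    A_star: int
    cutoff: float
    rmsecv_components: np.ndarray
    rmsecv_cutoff: pd.DataFrame
    params: SelectionParams

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": self.gene_ids,
            "vip": self.vip,
            "fdr": self.fdr,
            "reliability": self.reliability,
            "candidate": self.candidate.astype(int),
            "selected": self.selected.astype(int),
        })

    def summary(self) -> dict:
        return {
            "n_genes": len(self.gene_ids),
            "A_star": int(self.A_star),
            "n_candidates": int(self.candidate.sum()),
            "reliability_cutoff": float(self.cutoff),
            "n_selected": int(self.selected.sum()),
            "alpha": self.params.alpha,
            "n_perm": self.params.n_perm,
            "n_subsets": self.params.n_subsets,
            "subset_fraction": self.params.subset_fraction,
            "folds": self.params.folds,
            "order": self.params.order,
            "seed": self.params.seed,
        }


# ---------------------------------------------------------------------------
# stage 2: permutation FDR on VIP
# ---------------------------------------------------------------------------

def permutation_vip_fdr(
    X: np.ndarray,
    y: np.ndarray,
    A: int,
    n_perm: int = 1000,
    seed: int = 0,
    scale: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed VIP and its empirical FDR under response permutation.

    Returns ``(vip_obs, fdr)``.  Each replicate permutes y and refits at
    the observed A (or the largest feasible A if a permuted fit
    degenerates, which is logged).  FDR is the pooled tail-ratio
    estimator, capped at 1 and monotonized so the gene with the largest
    VIP has the smallest FDR.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    model = fit_pls1(X, y, A, scale=scale)
    vip_obs = vip(model)
    p = X.shape[1]

    rng = np.random.default_rng(seed)
    null_pool = np.empty(n_perm * p)
    for b in range(n_perm):
        yp = rng.permutation(y)
        try:
            m = fit_pls1(X, yp, A, scale=scale)
        except PLSFitError:
            a_fallback = A - 1
            m = None
            while a_fallback >= 1:
                try:
                    m = fit_pls1(X, yp, a_fallback, scale=scale)
                    break
                except PLSFitError:
                    a_fallback -= 1
            if m is None:
                raise
            logger.info("permutation %d refit with A=%d", b, a_fallback)
        null_pool[b * p:(b + 1) * p] = vip(m)

    null_sorted = np.sort(null_pool)
    obs_sorted = np.sort(vip_obs)
    # counts of {>= v} via searchsorted on ascending arrays
    r_obs = len(vip_obs) - np.searchsorted(obs_sorted, vip_obs, side="left")
    v_null = (len(null_pool)
              - np.searchsorted(null_sorted, vip_obs, side="left")) / n_perm
    fdr = np.minimum(1.0, v_null / r_obs)

    order = np.argsort(-vip_obs, kind="mergesort")
    monot = np.minimum.accumulate(fdr[order][::-1])[::-1]
    out = np.empty_like(fdr)
    out[order] = monot
    return vip_obs, out


# ---------------------------------------------------------------------------
# stage 3: Monte-Carlo coefficient reliability
# ---------------------------------------------------------------------------

def mc_reliability(
    X: np.ndarray,
    y: np.ndarray,
    candidate_idx: np.ndarray,
    A: int,
    n_subsets: int = 100,
    fraction: float = 0.5,
    seed: int = 0,
    scale: bool = True,
) -> np.ndarray:
    """Mean/sd ratio of each candidate gene's PLS coefficient across
    Monte-Carlo subsamples (without replacement, size floor(fraction*n)).

    Zero spread across subsets yields ``sign(mean) * RELIABILITY_SENTINEL``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if n_subsets < 2:
        raise ValueError("n_subsets must be >= 2 (sd undefined otherwise)")
    candidate_idx = np.asarray(candidate_idx, dtype=int)
    if candidate_idx.size == 0:
        raise ValueError("no candidate genes")
    X = np.asarray(X, dtype=float)[:, candidate_idx]
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    m = int(np.floor(fraction * n))
    if m < A + 2:
        raise ValueError(f"subset size {m} too small for A={A}")

    children = np.random.SeedSequence(seed).spawn(n_subsets)
    coefs = np.empty((n_subsets, candidate_idx.size))
    for b, child in enumerate(children):
        rng = np.random.default_rng(child)
        idx = rng.choice(n, size=m, replace=False)
        a_sub = min(A, max_feasible_components(m, candidate_idx.size))
        model = fit_pls1(X[idx], y[idx], a_sub, scale=scale)
        coefs[b] = model.b

    mean = coefs.mean(axis=0)
    sd = coefs.std(axis=0, ddof=1)
    reliability = np.empty_like(mean)
    degenerate = sd < 1e-12
    if degenerate.any():
        logger.info("%d genes with zero coefficient spread; sentinel applied",
                    int(degenerate.sum()))
    reliability[degenerate] = np.sign(mean[degenerate]) * RELIABILITY_SENTINEL
    reliability[~degenerate] = mean[~degenerate] / sd[~degenerate]
    return reliability


# ---------------------------------------------------------------------------
# stage 4: reliability cutoff by RMSECV
# ---------------------------------------------------------------------------

def select_reliability_cutoff(
    X: np.ndarray,
    y: np.ndarray,
    candidate_idx: np.ndarray,
    reliability: np.ndarray,
    A: int,
    folds: int = 4,
    seed: int = 0,
    grid_size: int = 100,
    scale: bool = True,
) -> tuple[float, pd.DataFrame]:
    """Scan absolute-reliability cutoffs; return the one with lowest
    RMSECV of the model restricted to genes strictly above it.

    The grid is ``grid_size`` quantiles of |reliability| plus 0.  Ties in
    RMSECV break toward the larger cutoff (the sparser model).  Returns
    ``(cutoff, curve)`` where curve has columns (cutoff, n_genes, rmsecv).
    """
    candidate_idx = np.asarray(candidate_idx, dtype=int)
    reliability = np.asarray(reliability, dtype=float)
    if candidate_idx.size < 2:
        raise ValueError("need at least 2 candidate genes")
    abs_rel = np.abs(reliability)
    if np.allclose(abs_rel, abs_rel[0]):
        warnings.warn("all candidate reliabilities equal; cutoff degenerate")
        value = float(abs_rel[0])
        return value, pd.DataFrame(
            {"cutoff": [value], "n_genes": [candidate_idx.size],
             "rmsecv": [np.nan]}
        )
    qs = np.quantile(abs_rel, np.linspace(0, 1, grid_size))
    grid = np.unique(np.concatenate(([0.0], qs)))

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    max_fold = max(len(f) for f in make_folds(X[:, candidate_idx], y,
                                              folds, seed))
    rows = []
    best_cut, best_r = np.nan, np.inf
    for theta in grid:
        keep = candidate_idx[abs_rel > theta]
        if keep.size == 0:
            continue
        a_sub = min(A, max_feasible_components(n - max_fold, keep.size))
        if a_sub < 1:
            continue
        r = rmsecv(X[:, keep], y, a_sub, folds, seed, scale=scale)
        rows.append((float(theta), int(keep.size), r))
        if r <= best_r:          # ascending grid: ties go to the larger theta
            best_r, best_cut = r, float(theta)
    curve = pd.DataFrame(rows, columns=["cutoff", "n_genes", "rmsecv"])
    return best_cut, curve


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_selection(
    ds: ExpressionDataset, params: SelectionParams | None = None
) -> SelectionResult:
    """Run the full selection funnel on an aligned dataset.

    With ``order='default'`` the component count A* is chosen on all genes
    before the VIP/FDR screen.  With ``order='paper'`` the FDR screen runs
    first at the largest feasible provisional A (capped at ``A_max``) and
    A* is then chosen by RMSECV on the candidate genes only; either way
    VIP is computed at a single fixed A.
    """
    if params is None:
        params = SelectionParams()
    if ds.phenotype is None:
        raise ValueError("dataset has no phenotype")
    if ds.n_samples < 8:
        raise ValueError("need at least 8 samples for 4-fold CV")
    X = ds.values.T          # n x p
    y = ds.phenotype
    p = ds.n_genes

    seed_a = derive_seed(params.seed, "components")
    seed_perm = derive_seed(params.seed, "permutation")
    seed_mc = derive_seed(params.seed, "montecarlo")
    seed_cut = derive_seed(params.seed, "cutoff")

    if params.order == "paper":
        fold_max = max(len(f) for f in make_folds(X, y, params.folds, seed_a))
        a_prov = min(params.A_max,
                     max_feasible_components(ds.n_samples - fold_max, p))
        vip_obs, fdr = permutation_vip_fdr(
            X, y, a_prov, params.n_perm, seed_perm, scale=params.scale)
        candidate = fdr < params.alpha
        cand_idx = np.flatnonzero(candidate)
        if cand_idx.size >= 2:
            A_star, curve = choose_n_components(
                X[:, cand_idx], y, params.A_max, params.folds, seed_a,
                params.rel_tol, scale=params.scale)
        else:
            A_star, curve = a_prov, np.array([])
    elif params.order == "default":
        A_star, curve = choose_n_components(
            X, y, params.A_max, params.folds, seed_a, params.rel_tol,
            scale=params.scale)
        vip_obs, fdr = permutation_vip_fdr(
            X, y, A_star, params.n_perm, seed_perm, scale=params.scale)
        candidate = fdr < params.alpha
        cand_idx = np.flatnonzero(candidate)
    else:
        raise ValueError(f"unknown order {params.order!r}")

    reliability = np.full(p, np.nan)
    selected = np.zeros(p, dtype=bool)
    cutoff = np.nan
    cut_curve = pd.DataFrame(columns=["cutoff", "n_genes", "rmsecv"])
    if cand_idx.size >= 2:
        rel_cand = mc_reliability(
            X, y, cand_idx, A_star, params.n_subsets,
            params.subset_fraction, seed_mc, scale=params.scale)
        reliability[cand_idx] = rel_cand
        cutoff, cut_curve = select_reliability_cutoff(
            X, y, cand_idx, rel_cand, A_star, params.folds, seed_cut,
            params.grid_size, scale=params.scale)
        selected[cand_idx] = np.abs(rel_cand) > cutoff
    elif cand_idx.size == 1:
        # a single candidate needs no cutoff scan: it is the selected set
        rel_cand = mc_reliability(
            X, y, cand_idx, min(A_star, 1), params.n_subsets,
            params.subset_fraction, seed_mc, scale=params.scale)
        reliability[cand_idx] = rel_cand
        cutoff = 0.0
        selected[cand_idx] = np.abs(rel_cand) > cutoff
    logger.info("selection funnel: %d genes -> %d candidates -> %d selected "
                "(A*=%d, cutoff=%.4g)", p, cand_idx.size,
                int(selected.sum()), A_star, cutoff)

    return SelectionResult(
        gene_ids=list(ds.gene_ids),
        vip=vip_obs, fdr=fdr, reliability=reliability,
        candidate=candidate, selected=selected,
        A_star=int(A_star), cutoff=float(cutoff),
        rmsecv_components=np.asarray(curve, dtype=float),
        rmsecv_cutoff=cut_curve, params=params,
    )
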