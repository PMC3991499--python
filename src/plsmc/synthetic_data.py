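"""Simulated studies with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
log2-scale genes x samples matrix in which a small planted subset of
genes is linearly associated with a continuous phenotype (a disease
severity index drawn uniformly over a configurable range, optionally
bimodal to mimic a mixed patient/control cohort), optional array-specific
nuisance factors loading on all genes, one annotation term enriched for
the planted genes, and an interaction network with known degrees.

Default sizes describe a reduced-scale cohort study: 120 arrays, 1,000
genes of which 30 carry a planted effect of 1.5 log2 units per phenotype
standard deviation against unit Gaussian noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_io import AnnotationTable, ExpressionDataset, InteractionList


@dataclass
class SimulationConfig:
    """Parameters of a simulated expression study.

    ``effect_sizes`` may be a single magnitude applied to every
    informative gene, a (low, high) tuple to draw magnitudes from, or an
    explicit per-gene sequence; signs are assigned at random either way
    (half up-, half down-regulated on average).
    """

    n_samples: int = 120
    n_genes: int = 1000
    n_informative: int = 30
    effect_sizes: float | tuple[float, float] | Sequence[float] = 1.5
    noise_sd: float = 1.0
    phenotype_range: tuple[float, float] = (0.0, 100.0)
    phenotype_mode: str = "uniform"     # "uniform" or "bimodal"
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    n_batch_factors: int = 0
    batch_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative exceeds n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_samples < 2 or self.n_genes < 2:
            raise ValueError("need at least 2 samples and 2 genes")
        if self.n_batch_factors < 0:
            raise ValueError("n_batch_factors must be >= 0")
        if self.phenotype_mode not in ("uniform", "bimodal"):
            raise ValueError(f"unknown phenotype_mode {self.phenotype_mode!r}")


@dataclass
class GroundTruth:
    """What the generator planted, for scoring recovery."""

    informative_gene_ids: set[str]
    true_effects: dict[str, float]
    enriched_term_id: str | None = None
    planted_network_degrees: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "informative_gene_ids": sorted(self.informative_gene_ids),
            "true_effects": {g: self.true_effects[g]
                             for g in sorted(self.true_effects)},
            "enriched_term_id": self.enriched_term_id,
            "planted_network_degrees": {
                g: self.planted_network_degrees[g]
                for g in sorted(self.planted_network_degrees)},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)


def _effect_magnitudes(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    es = cfg.effect_sizes
    if np.isscalar(es):
        return np.full(cfg.n_informative, float(es))
    es = tuple(es) if isinstance(es, tuple) else list(es)
    if isinstance(es, tuple) and len(es) == 2:
        low, high = es
        return rng.uniform(low, high, cfg.n_informative)
    arr = np.asarray(es, dtype=float)
    if arr.shape != (cfg.n_informative,):
        raise ValueError("effect_sizes sequence must have n_informative entries")
    return arr


def simulate_dataset(cfg: SimulationConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw one study: phenotype, expression matrix, and ground truth.

    Informative gene j follows
    ``x_ij = baseline_j + beta_j * z_i + sum_f lambda_jf u_if + eps_ij``
    with ``z`` the standardized phenotype, batch scores ``u_if`` standard
    normal per array, loadings ``lambda ~ N(0, batch_sd)``, and
    ``eps ~ N(0, noise_sd)``; null genes carry baseline, batch, and noise
    only.  Bit-reproducible from the config seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_samples, cfg.n_genes
    width = len(str(p))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(p)]
    sample_ids = [f"s{i + 1:0{len(str(n))}d}" for i in range(n)]

    low, high = cfg.phenotype_range
    if cfg.phenotype_mode == "uniform":
        y = rng.uniform(low, high, n)
    else:
        # mixed cohort: controls cluster low, patients spread high
        span = high - low
        is_case = rng.random(n) < 0.5
        y = np.where(is_case,
                     rng.uniform(low + 0.4 * span, high, n),
                     rng.uniform(low, low + 0.3 * span, n))
    z = (y - y.mean()) / y.std()

    informative = np.sort(rng.choice(p, size=cfg.n_informative, replace=False))
    magnitudes = _effect_magnitudes(cfg, rng)
    signs = rng.choice([-1.0, 1.0], size=cfg.n_informative)
    betas = np.zeros(p)
    betas[informative] = magnitudes * signs

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, p)
    values = baseline[:, None] + np.outer(betas, z)
    if cfg.n_batch_factors > 0:
        loadings = rng.normal(0.0, cfg.batch_sd, (p, cfg.n_batch_factors))
        scores = rng.normal(0.0, 1.0, (cfg.n_batch_factors, n))
        values += loadings @ scores
    values += rng.normal(0.0, cfg.noise_sd, (p, n))

    truth = GroundTruth(
        informative_gene_ids={gene_ids[i] for i in informative},
        true_effects={gene_ids[i]: float(betas[i]) for i in informative},
    )
    return ExpressionDataset(gene_ids, sample_ids, values, y), truth


def simulate_annotation(
    genes: Sequence[str],
    truth: GroundTruth,
    n_terms: int = 20,
    term_size_range: tuple[int, int] = (10, 50),
    coverage: float = 1.0,
    seed: int = 0,
) -> AnnotationTable:
    """Flat annotation with one term enriched for the planted genes.

    The designated term (``TERM_ENRICHED``) covers ``coverage`` of the
    informative genes (plus uniform fillers up to its drawn size); the
    remaining terms draw genes uniformly.  Updates
    ``truth.enriched_term_id`` in place.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    lo, hi = term_size_range
    if hi > len(genes):
        raise ValueError("term size range exceeds gene count")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    informative = sorted(truth.informative_gene_ids & set(genes))

    pairs: set[tuple[str, str]] = set()
    names: dict[str, str] = {}
    enriched_id = "TERM_ENRICHED"
    n_cov = int(round(coverage * len(informative)))
    covered = list(rng.choice(informative, size=n_cov, replace=False)) \
        if informative else []
    size = int(rng.integers(lo, hi + 1))
    members = set(covered)
    others = [g for g in genes if g not in members]
    if size > len(members):
        fillers = rng.choice(others, size=min(size - len(members), len(others)),
                             replace=False)
        members.update(fillers)
    pairs.update((g, enriched_id) for g in members)
    names[enriched_id] = "planted enriched term"
    truth.enriched_term_id = enriched_id

    for t in range(1, n_terms):
        term = f"TERM_{t:03d}"
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        pairs.update((g, term) for g in members)
        names[term] = f"random term {t}"
    return AnnotationTable(pairs, names)


def _havel_hakimi_edges(degrees: dict[str, int]) -> list[tuple[str, str]]:
    """Label-preserving Havel-Hakimi realization of a degree sequence."""
    remaining = {g: d for g, d in degrees.items() if d > 0}
    if sum(degrees.values()) % 2:
        raise ValueError("degree sequence has odd sum; not graphical")
    edges: list[tuple[str, str]] = []
    while remaining:
        # deterministic: largest remaining degree, ties by gene id
        v = min(remaining, key=lambda g: (-remaining[g], g))
        d = remaining.pop(v)
        partners = sorted(remaining, key=lambda g: (-remaining[g], g))[:d]
        if len(partners) < d:
            raise ValueError("degree sequence is not graphical")
        for u in partners:
            edges.append((v, u))
            remaining[u] -= 1
            if remaining[u] == 0:
                del remaining[u]
    return edges


def simulate_interactions(
    genes: Sequence[str],
    model: str = "preferential-attachment",
    degrees: dict[str, int] | None = None,
    m_attach: int = 2,
    seed: int = 0,
    truth: GroundTruth | None = None,
) -> InteractionList:
    """Interaction pair list with known degree structure.

    ``model='fixed-degree'`` realizes the requested per-gene ``degrees``
    exactly (error if the sequence is not graphical); unlisted genes stay
    isolated.  ``model='preferential-attachment'`` grows a scale-free-ish
    graph (Barabasi-Albert, ``m_attach`` edges per new node) over all
    genes.  Realized degrees are recorded on ``truth`` when given.
    """
    import networkx as nx

    genes = list(genes)
    if model == "fixed-degree":
        if degrees is None:
            raise ValueError("fixed-degree model requires a degrees mapping")
        unknown = set(degrees) - set(genes)
        if unknown:
            raise ValueError(f"degrees given for unknown genes: {sorted(unknown)[:3]}")
        edges = _havel_hakimi_edges(degrees)
        realized: dict[str, int] = dict(degrees)
    elif model == "preferential-attachment":
        if len(genes) <= m_attach:
            raise ValueError("need more genes than m_attach")
        g = nx.barabasi_albert_graph(len(genes), m_attach, seed=seed)
        edges = [(genes[a], genes[b]) for a, b in g.edges()]
        realized = {genes[i]: d for i, d in g.degree()}
    else:
        raise ValueError(f"unknown interaction model {model!r}")
    if truth is not None:
        truth.planted_network_degrees = realized
    return InteractionList(edges)
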