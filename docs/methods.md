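# Methods

## Model and assumptions

The pipeline regresses a continuous per-sample disease index y on a
high-dimensional log2 expression matrix X (p genes ≫ n samples) with
univariate-response partial least squares (PLS1). PLS1 extracts latent
components t_a = Xw_a that maximize covariance with y, which lets the
fit share information across correlated genes and absorb array-wide
nuisance directions that per-gene marginal tests treat as noise. The
model assumes:

- a complete matrix: missing values are a load-time error, never
  imputed;
- approximately linear gene–phenotype relationships on the log2 scale;
- no zero-variance genes (removed up front; autoscaling is undefined
  for them);
- at least 8 samples, so a 4-fold split leaves ≥ 2 samples per fold.

For a scalar response the NIPALS inner loop converges in a single pass,
so the fit is implemented as the direct PLS1 recursion; this is
algebraically identical to iterated NIPALS, and identical with or
without y-deflation (covered by a test against an independent
Krylov-subspace PLS1 oracle and a library reference).

## Selection statistics

**VIP.** Variable importance on the projection,
VIP_j = sqrt(p Σ_a ssy_a w_aj² / Σ_a ssy_a) with
ssy_a = q_a² t_a't_a, normalized so Σ_j VIP_j² = p.

**Permutation FDR.** The null distribution of VIP is obtained by
refitting after permuting y (B replicates at the same fixed A as the
observed fit, so the null stays comparable and the cost is linear in B).
The estimator is the pooled tail ratio
FDR(v) = min(1, V(v)/R(v)) with R(v) the observed count of VIP ≥ v and
V(v) the per-replicate average null count, followed by cumulative-min
monotonization so FDR never increases with VIP. The exact estimator
behind the published analysis is not printed anywhere we could find;
this pooled form is the standard reading of "FDR evaluated from the
empirical distribution" (as in SAM-type procedures) and should be
understood as a documented reconstruction. Its null calibration is
verified by simulation (pure-noise studies yield ≈ 0 % of genes below
FDR 0.05).

**Monte-Carlo reliability.** Coefficient vectors are recollected over
subsets drawn without replacement, size floor(n/2), each subset seeded
independently from a master seed. A gene's reliability is
mean_b(b_j^(b)) / sd_b(b_j^(b)) (sample sd, n−1 denominator) — a
signal-to-noise summary that is large only when the coefficient is both
large and stable under subsampling. This formula is likewise a
reconstruction of the cited Monte-Carlo variable-selection approach.
If the spread is numerically zero (< 1e-12) the gene receives the
sentinel ±1e12 and therefore passes any finite cutoff; the event is
logged.

**Cutoff scan.** Candidate cutoffs are the `grid_size` (default 100)
quantiles of |reliability| plus exactly 0. For each cutoff the model is
refit on the genes strictly above it (comparison is strict ">") and
scored by RMSECV; the lowest-RMSECV cutoff wins, with ties broken toward
the larger cutoff (the sparser model).

## Cross-validation

RMSECV uses a seeded uniform random partition into nearly equal folds
(default 4); no stratification, since the response is continuous. The
partition is drawn after a canonical sample sort (lexicographic on y
then the X columns), so the value is invariant to input row order.
A = 0 is allowed and means fold-training-mean prediction.

The number of components A\* is the smallest A whose relative RMSECV
improvement to A+1 falls below `rel_tol` (default 0.01 — an operational
version of "the descending trend loses strength"), capped at the
curve's argmin; `rel_tol = 0` returns the argmin exactly. If deflation
exhausts the covariance before `A_max` (exactly low-rank data) the curve
simply ends there.

## Stage order

By default A\* is chosen on all genes, then VIP/FDR at A\*, then
reliability on candidates only, then the cutoff scan. An alternative
`order="paper"` mode runs the FDR screen first at the largest feasible
provisional A and picks A\* afterwards on the candidates, mirroring a
narrative in which candidates are reported before the component count;
VIP needs a fixed A either way, so both orders are legitimate readings
and both are exposed.

## Scaling and centering

X columns are autoscaled to unit sd (ddof = 1) by default — VIP is
conventionally defined on autoscaled predictors — and y is centered
only. Scaling is switchable (`scale=False`), and the oracle-equivalence
and VIP-normalization properties hold either way. Coefficients are
always reported on the original gene scale.

## Preprocessing

Quantile normalization maps every column onto the across-column mean of
order statistics; within-column ties receive the mean of the reference
values at the tied ranks (a choice; idempotence holds exactly for
tie-free data). Median polish is Tukey's algorithm, rows first, defaults
tol = 0.01 and max_iter = 10 (conventional RMA-style settings); the
additive decomposition reconstructs the input exactly at every
iteration. Background correction of raw probe intensities is out of
scope: inputs are assumed to be probe-level log2 values, and
normalization is optional because public series matrices are often
already normalized.

## Enrichment and network

The enrichment background is annotated ∩ measured genes, and n counts
selected genes inside that background. P-values are exact hypergeometric
upper tails via scipy's log-space survival function (stable to
N ≈ 1e5), checked against brute-force enumeration for all N ≤ 12. Raw
p-values are primary; Benjamini–Hochberg values are an optional column.
No ontology-DAG ancestor propagation is performed — the annotation is a
flat gene→term table supplied by the user.

The interaction network is the induced undirected subgraph of the pair
list on the selected genes: duplicate orientations collapse, self-loops
drop (logged). Degree is the interaction count; hubs are degree
strictly > 10 by default. Interactions are treated as undirected because
curated interaction records carry directionality inconsistently and the
degree definition counts them symmetrically. Exports (SIF, GraphML,
TSV) are lexicographically ordered, hence byte-deterministic.

## Synthetic data

The generator emulates the structure the analysis assumes: phenotype
uniform over a configurable range (default 0–100, an index-like scale;
a bimodal mode mimics a mixed patient/control cohort), informative genes
x_ij = baseline_j + β_j z_i + Σ_f λ_jf u_if + ε_ij with z the
standardized phenotype, optional array-specific batch factors u, and
Gaussian noise; null genes carry baseline, batch, and noise only.
Defaults describe a reduced-scale cohort: 120 arrays, 1,000 genes, 30
informative at effect 1.5 per phenotype sd against unit noise, no batch
factors. Effects get random signs (up- and down-regulation). What the
generator does **not** emulate: probe-level intensity distributions,
heavy-tailed or heteroscedastic noise, gene–gene correlation beyond the
batch factors, and annotation incompleteness — so passing tests
demonstrate the statistics behave as designed under the assumed model,
not that real studies of any particular disease will reach the same
sensitivity.

## Reproducibility and problem sizes

Every stochastic stage takes a seed; a pipeline master seed fans out to
per-stage seeds via a SeedSequence keyed on the stage name, so stages
are independently reproducible and two runs with one seed are
byte-identical. Tests and the acceptance script run at reduced scale —
hundreds to a thousand genes, 40–120 samples, 50–200 permutations —
which the simulations show is ample to exercise every property; the
full-scale configuration (≈ 22,000 probes × 221 arrays, 1,000
permutations) is computationally feasible with the same code.

## Known limitations

- The FDR estimator and reliability formula are reconstructions (see
  above); other readings would shift the funnel counts.
- The elbow rule depends on `rel_tol`; very flat RMSECV curves can make
  A\* sensitive to it (the full curve is always written out for
  inspection).
- The permutation null fixes A; re-selecting A per replicate would
  widen the null slightly at much higher cost.
- Probe→gene collapsing is left to the user (an optional max-mean rule
  is provided); enrichment results depend on that mapping and on the
  annotation release.
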