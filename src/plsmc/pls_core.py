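"""PLS1 regression by NIPALS, VIP scores, and cross-validated RMSECV.

The response is a single continuous phenotype, so the NIPALS inner loop
converges in one pass and the fit reduces to the direct PLS1 recursion:
for each component a,

    w_a = X'y / ||X'y||        (unit-norm weight)
    t_a = X w_a                (score)
    p_a = X't_a / t_a't_a      (x-loading)
    q_a = y't_a / t_a't_a      (y-loading)
    X <- X - t_a p_a',  y <- y - q_a t_a

on centered (and by default column-autoscaled) X with centered y.
Regression coefficients on the scaled space are b = W (P'W)^-1 q, mapped
back through the centering/scaling so prediction works on the original
gene scale.

VIP aggregates squared weights across components, weighted by each
component's explained response variance ssy_a = q_a^2 t_a't_a:

    VIP_j = sqrt( p * sum_a ssy_a w_aj^2 / sum_a ssy_a )

and satisfies sum_j VIP_j^2 = p.

RMSECV is the out-of-fold root mean squared prediction error under a
seeded random partition into nearly equal folds; it drives both the
choice of the number of latent components and, downstream, the
reliability cutoff scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class PLSFitError(ValueError):
    """Raised when a PLS1 fit is infeasible on the given data."""


@dataclass
class PLSModel:
    """Fitted PLS1 decomposition.

    ``b`` is the regression-coefficient vector on the original
    (unscaled, uncentered) gene scale; ``intercept`` completes the affine
    prediction ``yhat = intercept + Xnew @ b``.
    """

    A: int
    W: np.ndarray          # p x A, unit-norm columns
    T: np.ndarray          # n x A, mutually orthogonal scores
    P: np.ndarray          # p x A x-loadings
    q: np.ndarray          # length-A y-loadings
    b: np.ndarray          # length-p coefficients, original scale
    intercept: float
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: float
    ssy: np.ndarray        # length-A explained y-variance per component

    @property
    def n_features(self) -> int:
        return self.W.shape[0]


def fit_pls1(
    X: np.ndarray, y: np.ndarray, A: int, scale: bool = True
) -> PLSModel:
    """Fit an ``A``-component PLS1 model of ``y`` on ``X`` (n x p).

    X columns are centered and, when ``scale`` is on, autoscaled to unit
    standard deviation (ddof=1); y is centered only.  Deterministic: no
    randomness is involved.

    Raises
    ------
    PLSFitError
        If ``A`` exceeds min(n-1, p), y is constant, a column has zero
        variance under autoscaling, or the deflated covariance X'y
        vanishes before ``A`` components are extracted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise PLSFitError("X and y have different sample counts")
    if not 1 <= A <= min(n - 1, p):
        raise PLSFitError(f"A={A} must be in [1, min(n-1, p)={min(n - 1, p)}]")
    x_center = X.mean(axis=0)
    if scale:
        x_scale = X.std(axis=0, ddof=1)
        if np.any(x_scale == 0):
            raise PLSFitError("zero-variance column under autoscaling; "
                              "drop degenerate genes first")
    else:
        x_scale = np.ones(p)
    y_center = float(y.mean())
    if np.allclose(y, y_center):
        raise PLSFitError("constant response: PLS1 is undefined")

    Xd = (X - x_center) / x_scale
    yd = y - y_center
    y_norm0 = np.linalg.norm(yd)

    W = np.empty((p, A))
    T = np.empty((n, A))
    P = np.empty((p, A))
    q = np.empty(A)
    ssy = np.empty(A)
    for a in range(A):
        cov = Xd.T @ yd
        cov_norm = np.linalg.norm(cov)
        if cov_norm <= 1e-12 * max(1.0, y_norm0):
            raise PLSFitError(
                f"deflated X'y vanished at component {a + 1}; use A <= {a}"
            )
        w = cov / cov_norm
        t = Xd @ w
        tt = float(t @ t)
        pa = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        W[:, a], T[:, a], P[:, a], q[a] = w, t, pa, qa
        ssy[a] = qa * qa * tt
        Xd = Xd - np.outer(t, pa)
        yd = yd - qa * t

    try:
        b_scaled = W @ np.linalg.solve(P.T @ W, q)
    except np.linalg.LinAlgError as exc:
        raise PLSFitError("singular P'W; reduce A") from exc
    b = b_scaled / x_scale
    intercept = y_center - float(x_center @ b)
    return PLSModel(A, W, T, P, q, b, intercept,
                    x_center, x_scale, y_center, ssy)


def predict(model: PLSModel, Xnew: np.ndarray) -> np.ndarray:
    """Predict the response for ``Xnew`` (m x p, model's gene order)."""
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    if Xnew.shape[1] != model.n_features:
        raise ValueError(
            f"Xnew has {Xnew.shape[1]} columns, model expects "
            f"{model.n_features}"
        )
    return model.intercept + Xnew @ model.b


def predict_via_scores(model: PLSModel, Xnew: np.ndarray) -> np.ndarray:
    """Prediction through score projection T = Xs W(P'W)^-1, q.

    Algebraically identical to :func:`predict`; kept as an internal
    consistency route.
    """
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    Xs = (Xnew - model.x_center) / model.x_scale
    R = model.W @ np.linalg.inv(model.P.T @ model.W)
    return model.y_center + (Xs @ R) @ model.q


def vip(model: PLSModel) -> np.ndarray:
    """Variable importance on the projection for every gene.

    Satisfies sum_j VIP_j^2 = p for any fitted model.
    """
    total = model.ssy.sum()
    if total <= 0:
        raise ValueError("model explains no response variance")
    p = model.n_features
    # W columns are unit-norm by construction
    weighted = (model.W ** 2) @ model.ssy
    return np.sqrt(p * weighted / total)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _canonical_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Sample ordering independent of input row order (y primary key,
    then X columns), so seeded folds do not depend on file row order."""
    keys = tuple(X[:, j] for j in range(X.shape[1] - 1, -1, -1)) + (y,)
    return np.lexsort(keys)


def make_folds(
    X: np.ndarray, y: np.ndarray, folds: int, seed: int
) -> list[np.ndarray]:
    """Seeded random partition into ``folds`` nearly equal blocks,
    applied after a canonical sample sort."""
    n = len(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < 2 * folds:
        raise ValueError(f"need >= {2 * folds} samples for {folds} folds")
    canon = _canonical_order(np.asarray(X, float), np.asarray(y, float))
    rng = np.random.default_rng(seed)
    perm = canon[rng.permutation(n)]
    return [np.sort(block) for block in np.array_split(perm, folds)]


def rmsecv(
    X: np.ndarray,
    y: np.ndarray,
    A: int,
    folds: int = 4,
    seed: int = 0,
    scale: bool = True,
) -> float:
    """Root mean square error of cross-validation at ``A`` components.

    ``A = 0`` means each fold is predicted by its training mean.
    Deterministic given the seed, which controls the fold partition.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    parts = make_folds(X, y, folds, seed)
    sq = np.empty(n)
    for test_idx in parts:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        Xtr, ytr = X[train_mask], y[train_mask]
        if A == 0:
            yhat = np.full(len(test_idx), ytr.mean())
        else:
            model = fit_pls1(Xtr, ytr, A, scale=scale)
            yhat = predict(model, X[test_idx])
        sq[test_idx] = (y[test_idx] - yhat) ** 2
    return float(np.sqrt(sq.mean()))


def max_feasible_components(n_train: int, p: int) -> int:
    return min(n_train - 1, p)


def choose_n_components(
    X: np.ndarray,
    y: np.ndarray,
    A_max: int,
    folds: int = 4,
    seed: int = 0,
    rel_tol: float = 0.01,
    scale: bool = True,
) -> tuple[int, np.ndarray]:
    """Pick the number of latent components by the RMSECV elbow.

    The RMSECV curve typically descends as components are added and then
    flattens; the chosen A* is the smallest A whose relative improvement
    to A+1 falls below ``rel_tol``, capped at the argmin of the curve
    (``rel_tol = 0`` therefore returns the argmin).  Returns
    ``(A_star, curve)`` where ``curve[a-1]`` is the RMSECV at a
    components.
    """
    if A_max < 1:
        raise ValueError("A_max must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    fold_sizes = [len(f) for f in make_folds(X, y, folds, seed)]
    feasible = min(max_feasible_components(n - max(fold_sizes), p), A_max)
    if feasible < 1:
        raise ValueError("no feasible component count under this fold design")
    vals = []
    for a in range(1, feasible + 1):
        try:
            vals.append(rmsecv(X, y, a, folds, seed, scale=scale))
        except PLSFitError:
            # deflation exhausted the covariance (e.g. exact low-rank data);
            # the curve simply ends here
            break
    if not vals:
        raise ValueError("no feasible component count on this data")
    curve = np.array(vals)
    argmin_a = int(np.argmin(curve)) + 1
    if rel_tol <= 0:
        return argmin_a, curve
    a_star = len(curve)
    for a in range(1, len(curve)):
        prev = curve[a - 1]
        improvement = (prev - curve[a]) / prev if prev > 0 else 0.0
        if improvement < rel_tol:
            a_star = a
            break
    return min(a_star, argmin_a), curve
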