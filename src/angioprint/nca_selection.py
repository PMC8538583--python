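"""Diagonal neighborhood component analysis (NCA) for feature selection.

NCA learns one non-negative weight per feature by maximizing the expected
leave-one-out nearest-neighbor accuracy under a soft (stochastic) neighbor
assignment.  With weighted L1 distance

    d_w(x_i, x_j) = sum_r w_r^2 |x_ir - x_jr|,

reference-point probabilities

    p_ij = exp(-d_w(x_i, x_j) / sigma) / sum_{l != i} exp(-d_w(x_i, x_l) / sigma),
    p_ii = 0,

and per-sample correct-classification probability
p_i = sum_{j : y_j = y_i} p_ij, the regularized objective is

    F(w) = (1/n) sum_i p_i - lambda * sum_r w_r^2.

F is maximized by per-sample stochastic gradient ascent (one pass over the
samples per epoch, shuffled, with a piecewise-constant decaying step size).
Squared weights rank feature relevance; selection keeps the top
ceil(n_features / 6) columns, which is 413 of 2478 for the full pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

DEFAULT_SIGMA = 1.0
DEFAULT_EPOCHS = 20
DEFAULT_LEARNING_RATE = 0.1
#: halve the step size this often (epochs)
LR_HALVING_PERIOD = 5
DEFAULT_SELECT_FRACTION = 1.0 / 6.0


@dataclass
class FeatureWeights:
    """Learned per-feature NCA weights; relevance of feature r is w[r]**2."""

    w: np.ndarray
    objective_trace: np.ndarray
    lam: float
    sigma: float
    epochs: int
    learning_rate: float
    seed: int

    @property
    def relevance(self) -> np.ndarray:
        return self.w**2


@dataclass
class SelectedFeatures:
    """The k most relevant feature columns (0-based indices)."""

    indices: np.ndarray
    ranking: np.ndarray
    k: int = field(init=False)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.ranking = np.asarray(self.ranking, dtype=np.int64)
        self.k = len(self.indices)


def _validate(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a 2-D matrix with at least 2 samples")
    if len(y) != X.shape[0]:
        raise ValueError("y must have one label per sample")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    if len(np.unique(y)) < 2:
        raise ValueError("NCA requires at least 2 classes")
    return X, y


def _soft_neighbor_probs(
    dists: np.ndarray, i: int, sigma: float
) -> np.ndarray:
    """p_i. over one row of distances, excluding self, numerically stable."""
    z = -dists / sigma
    z[i] = -np.inf
    z -= z.max()
    p = np.exp(z)
    total = p.sum()
    if total <= 0.0:  # all distances overflowed: fall back to uniform
        p = np.ones_like(p)
        p[i] = 0.0
        total = p.sum()
    return p / total


def nca_objective_and_grad(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    lam: float,
    sigma: float = DEFAULT_SIGMA,
) -> tuple[float, np.ndarray]:
    """Full-batch objective F(w) and its analytic gradient dF/dw."""
    X, y = _validate(X, y)
    w = np.asarray(w, dtype=np.float64)
    n, d = X.shape
    w2 = w**2
    obj = 0.0
    grad = np.zeros(d)
    for i in range(n):
        diffs = np.abs(X - X[i])  # n x d
        dists = diffs @ w2
        p = _soft_neighbor_probs(dists, i, sigma)
        same = (y == y[i]) & (np.arange(n) != i)
        p_i = p[same].sum()
        obj += p_i
        # d p_i / d w_r = (2 w_r / sigma) (p_i sum_l p_il D_ilr - sum_{j in class} p_ij D_ijr)
        grad += (2.0 * w / sigma) * (p_i * (p @ diffs) - (p[same] @ diffs[same]))
    obj = obj / n - lam * np.sum(w2)
    grad = grad / n - 2.0 * lam * w
    return obj, grad


def _objective_only(
    X: np.ndarray, y: np.ndarray, w2: np.ndarray, lam: float, sigma: float
) -> float:
    """F(w) without the gradient, chunked over samples."""
    n = X.shape[0]
    total = 0.0
    for i in range(n):
        dists = np.abs(X - X[i]) @ w2
        p = _soft_neighbor_probs(dists, i, sigma)
        total += p[(y == y[i]) & (np.arange(n) != i)].sum()
    return total / n - lam * np.sum(w2)


def nca_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float | None = None,
    sigma: float = DEFAULT_SIGMA,
    epochs: int = DEFAULT_EPOCHS,
    learning_rate: float = DEFAULT_LEARNING_RATE,
    seed: int = 0,
) -> FeatureWeights:
    """Learn per-feature NCA weights by stochastic gradient ascent.

    One update per sample per epoch in shuffled order; the step size halves
    every ``LR_HALVING_PERIOD`` epochs.  ``lam`` defaults to 1/n_samples.
    Weights start at 1 and are reported as absolute values (the model only
    sees them squared).  The exact objective is recorded after every epoch.
    Deterministic given ``seed``.
    """
    X, y = _validate(X, y)
    n, d = X.shape
    if lam is None:
        lam = 1.0 / n
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")

    # float32 working copy: the SGD pass is memory-bound on large matrices
    Xf = np.asarray(X, dtype=np.float32)
    classes, yi = np.unique(y, return_inverse=True)
    rng = np.random.default_rng(seed)
    w = np.ones(d, dtype=np.float64)
    idx = np.arange(n)
    trace = np.empty(epochs, dtype=np.float64)

    for epoch in range(epochs):
        lr = learning_rate / 2.0 ** (epoch // LR_HALVING_PERIOD)
        for i in rng.permutation(n):
            diffs = np.abs(Xf - Xf[i])  # n x d, float32
            dists = diffs @ w.astype(np.float32) ** 2
            p = _soft_neighbor_probs(dists.astype(np.float64), i, sigma)
            same = (yi == yi[i]) & (idx != i)
            p_i = p[same].sum()
            grad = (2.0 * w / sigma) * (
                p_i * (p.astype(np.float32) @ diffs)
                - (p[same].astype(np.float32) @ diffs[same])
            )
            w += lr * (grad - 2.0 * lam * w)
        trace[epoch] = _objective_only(X, y, w**2, lam, sigma)

    return FeatureWeights(
        w=np.abs(w),
        objective_trace=trace,
        lam=lam,
        sigma=sigma,
        epochs=epochs,
        learning_rate=learning_rate,
        seed=seed,
    )


def select_top_k(weights: FeatureWeights, k: int) -> SelectedFeatures:
    """Keep the k features of highest relevance w**2, ties to the lower index.

    Returned indices are sorted ascending; ``ranking`` lists all features by
    descending relevance.
    """
    d = len(weights.w)
    if not 1 <= k <= d:
        raise ValueError(f"k must be in [1, {d}], got {k}")
    relevance = weights.relevance
    # stable sort on negated relevance: equal values keep ascending index order
    ranking = np.argsort(-relevance, kind="stable")
    return SelectedFeatures(indices=np.sort(ranking[:k]), ranking=ranking)


def default_k(n_features: int, fraction: float = DEFAULT_SELECT_FRACTION) -> int:
    """ceil(n_features * fraction): 413 when n_features = 2478."""
    return math.ceil(n_features * fraction)


def apply_selection(fm, sel: SelectedFeatures):
    """Column-subset a feature matrix, preserving row order and provenance."""
    if len(sel.indices) and (sel.indices.min() < 0 or sel.indices.max() >= fm.n_features):
        raise ValueError(
            f"selection indices out of range for a {fm.n_features}-column matrix"
        )
    return replace(
        fm,
        values=fm.values[:, sel.indices].copy(),
        labels=fm.labels.copy(),
        column_provenance=[fm.column_provenance[i] for i in sel.indices],
    )
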