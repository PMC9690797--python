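"""Linear neighborhood similarity (LNS) via simplex-constrained quadratic programs.

Each entity is reconstructed as a convex combination of its K nearest
neighbors: with G the Gram matrix of the centered neighbor differences,
G[j,k] = (x_i - x_ij) . (x_i - x_ik), the weights minimize

    w' (G + lam I) w   subject to   sum(w) = 1,  w >= 0,

a ridge-regularized locally-linear reconstruction restricted to the
probability simplex.  Placing each entity's weights into its row yields a
sparse, row-stochastic weight matrix (Wl over lncRNAs, Wd over diseases) that
gives even isolated entities a usable neighborhood for the random walk.
The weight matrix is deliberately asymmetric: row i answers "how is entity i
rebuilt from its neighbors", as in label-propagation methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .matrices import SimilarityMatrix

__all__ = ["LnsProblem", "LnsWeights", "build_gram", "solve_weights", "lns_matrix"]

log = logging.getLogger(__name__)


class LnsSolverError(RuntimeError):
    """QP solver failed to converge for one entity's reconstruction."""

    def __init__(self, entity_index: int, message: str) -> None:
        super().__init__(f"LNS solver failed for entity {entity_index}: {message}")
        self.entity_index = entity_index


@dataclass(frozen=True)
class LnsProblem:
    """One LNS instance: features, neighbor count, ridge, and neighbor ranking.

    ``features`` holds one feature vector per entity (n x m); neighbors are
    picked per entity as the k largest entries of ``neighbor_similarity``
    (n x n), excluding self, ties broken by ascending index.
    """

    features: np.ndarray
    k: int
    lam: float = 1.0
    neighbor_similarity: np.ndarray | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        object.__setattr__(self, "features", X)
        n = X.shape[0]
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if not (0 < self.k < n):
            raise ValueError(f"k must satisfy 0 < k < n={n}")
        if self.neighbor_similarity is not None:
            S = np.asarray(self.neighbor_similarity, dtype=float)
            if S.shape != (n, n):
                raise ValueError("neighbor_similarity must be n x n")
            object.__setattr__(self, "neighbor_similarity", S)


@dataclass(frozen=True)
class LnsWeights:
    """Row-stochastic reconstruction weights; at most k nonzeros per row, zero diagonal."""

    W: np.ndarray
    labels: tuple[str, ...] | None = None

    def as_similarity(self, labels, kind: str = "lns") -> SimilarityMatrix:
        return SimilarityMatrix(self.W, tuple(labels), kind=kind)


def build_gram(xi: np.ndarray, neighbors: np.ndarray) -> np.ndarray:
    """Gram matrix of neighbor offsets: G[j,k] = (xi - xj) . (xi - xk)."""
    diffs = np.asarray(xi, float)[None, :] - np.asarray(neighbors, float)
    return diffs @ diffs.T


def solve_weights(G: np.ndarray, lam: float, entity_index: int = -1) -> tuple[np.ndarray, float]:
    """Minimize w'(G + lam I)w on the probability simplex.

    Returns (weights, objective).  The unconstrained-KKT solution
    (G + lam I)^{-1} 1, normalized to sum 1, is optimal whenever it is
    nonnegative and is returned exactly in that case; otherwise the QP is
    solved numerically (SLSQP) from the uniform start.
    """
    G = np.asarray(G, dtype=float)
    k = G.shape[0]
    if lam <= 0:
        raise ValueError("lam must be > 0")
    A = G + lam * np.eye(k)
    if k == 1:
        return np.array([1.0]), float(A[0, 0])

    def obj(w: np.ndarray) -> float:
        return float(w @ A @ w)

    # interior KKT closed form: stationary point of w'Aw - nu(1'w - 1)
    try:
        w_kkt = np.linalg.solve(A, np.ones(k))
        s = w_kkt.sum()
        if s > 0:
            w_kkt = w_kkt / s
            if np.all(w_kkt >= -1e-12):
                w_kkt = np.clip(w_kkt, 0.0, None)
                w_kkt /= w_kkt.sum()
                return w_kkt, obj(w_kkt)
    except np.linalg.LinAlgError:
        pass

    w0 = np.full(k, 1.0 / k)
    res = minimize(
        obj,
        w0,
        jac=lambda w: 2.0 * (A @ w),
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0, "jac": lambda w: np.ones(k)}],
        options={"ftol": 1e-14, "maxiter": 500},
    )
    if not res.success and res.status != 8:  # 8: positive directional derivative (flat optimum)
        raise LnsSolverError(entity_index, res.message)
    w = np.clip(res.x, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise LnsSolverError(entity_index, "solver returned a zero weight vector")
    w = w / total
    return w, obj(w)


def lns_matrix(p: LnsProblem) -> LnsWeights:
    """Solve one simplex QP per entity and assemble the n x n weight matrix.

    Neighbors come from ``neighbor_similarity`` when given (largest entries,
    self excluded, ties by ascending index) and from Euclidean feature
    distance otherwise.  Weights below 1e-12 are clipped and each row is
    renormalized, so rows sum to 1 exactly.
    """
    X = p.features
    n = X.shape[0]
    if p.neighbor_similarity is not None:
        rank_score = p.neighbor_similarity.copy()
    else:
        d = X[:, None, :] - X[None, :, :]
        rank_score = -np.sqrt(np.sum(d * d, axis=2))
    np.fill_diagonal(rank_score, -np.inf)

    W = np.zeros((n, n))
    for i in range(n):
        order = np.argsort(-rank_score[i], kind="stable")[: p.k]
        G = build_gram(X[i], X[order])
        try:
            w, objective = solve_weights(G, p.lam, entity_index=i)
        except LnsSolverError:
            raise
        # optimality sanity check: never worse than uniform weights
        uniform = np.full(p.k, 1.0 / p.k)
        A = G + p.lam * np.eye(p.k)
        if objective > float(uniform @ A @ uniform) + 1e-8:
            raise LnsSolverError(i, "objective exceeds the uniform-weight bound")
        w = np.where(w < 1e-12, 0.0, w)
        w = w / w.sum()
        W[i, order] = w
    return LnsWeights(W)
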