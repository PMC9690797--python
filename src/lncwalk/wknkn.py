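"""Weighted K-nearest-known-neighbor (WKNKN) preprocessing of the association matrix.

Known association matrices are extremely sparse, and a random walk started
from a sparse matrix has little signal to diffuse.  WKNKN replaces each zero
entry with an interaction likelihood estimated from the K most similar
*known* neighbors: for a disease dj, the K diseases most similar to it
(excluding itself) are ranked by descending fused similarity, and their
association profiles are averaged with weights eta^(r-1) * FD(d_r, dj) — a
geometric decay down the ranking times the similarity itself — normalized by
the plain sum of the K similarities.  The same is done row-wise for lncRNAs,
and a zero cell becomes the mean of its disease-side and lncRNA-side
estimates.  Known 1-entries are never modified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matrices import AssociationMatrix, SimilarityMatrix, require_same_labels

__all__ = ["WknknParams", "wknkn"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WknknParams:
    """Neighbor count K >= 1 and decay factor eta in (0,1]."""

    K: int = 7
    eta: float = 1.0
    #: include the decay in the normalizer too (Z = sum eta^(r-1) * sim)
    normalize_with_decay: bool = False

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not (0.0 < self.eta <= 1.0):
            raise ValueError("eta must lie in (0,1]")


def _neighbor_estimate(
    profiles: np.ndarray, S: np.ndarray, K: int, eta: float, with_decay: bool
) -> np.ndarray:
    """Estimated profile for each of n entities from its K nearest neighbors.

    ``profiles`` is n x m (one association profile per entity), ``S`` the n x n
    similarity used for ranking and weighting.  Returns an n x m estimate.
    """
    n = S.shape[0]
    est = np.zeros_like(profiles, dtype=float)
    decay = eta ** np.arange(K)
    for j in range(n):
        sims = S[:, j].copy()
        sims[j] = -np.inf  # self excluded from its own neighbor list
        # descending similarity, ties broken by ascending entity index
        order = np.argsort(-sims, kind="stable")[:K]
        w_sim = S[order, j]
        Z = float(np.sum(decay * w_sim)) if with_decay else float(np.sum(w_sim))
        if Z == 0.0:
            log.warning("all neighbor similarities zero for entity %d; contribution set to 0", j)
            continue
        est[j] = (decay * w_sim) @ profiles[order] / Z
    return est


def wknkn(
    Y: AssociationMatrix,
    FD: SimilarityMatrix,
    FL: SimilarityMatrix,
    p: WknknParams,
) -> AssociationMatrix:
    """Fill zero cells of Y with neighbor-based interaction likelihoods.

    FD ranks/weights disease neighbors (column side), FL lncRNA neighbors
    (row side).  Both are max-normalized internally so the filled values are
    probabilities in [0,1] even when the fusion weights do not sum to 1.
    Entries with Y=1 are returned unchanged; output >= input elementwise.
    """
    require_same_labels(Y.dis_labels, FD.labels, "disease")
    require_same_labels(Y.lnc_labels, FL.labels, "lncRNA")
    if p.K >= min(Y.n_lnc, Y.n_dis):
        raise ValueError(
            f"K={p.K} must be smaller than min(n_lnc, n_dis)={min(Y.n_lnc, Y.n_dis)}"
        )

    def _maxnorm(S: np.ndarray) -> np.ndarray:
        m = S.max()
        return S / m if m > 0 else S

    FDn = _maxnorm(FD.values)
    FLn = _maxnorm(FL.values)
    Yv = Y.values

    # disease side: estimate each column from its K nearest disease columns
    Yd = _neighbor_estimate(Yv.T, FDn, p.K, p.eta, p.normalize_with_decay).T
    # lncRNA side: estimate each row from its K nearest lncRNA rows
    Yl = _neighbor_estimate(Yv, FLn, p.K, p.eta, p.normalize_with_decay)

    filled = 0.5 * (Yd + Yl)
    out = np.where(Yv == 1.0, 1.0, np.maximum(Yv, np.clip(filled, 0.0, 1.0)))
    return Y.with_values(out)
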