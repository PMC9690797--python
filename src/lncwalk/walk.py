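"""Unbalanced bi-random walk over the disease and lncRNA similarity networks.

Two restart random walks run simultaneously: one diffuses the current
prediction matrix P (lncRNAs x diseases) through the column-normalized
disease network (P @ MD), the other through the column-normalized lncRNA
network (ML @ P).  Each step mixes the diffused mass with a restart matrix at
weight alpha.  The walks are *unbalanced*: the disease walk runs for up to s1
steps and the lncRNA walk for up to s2 steps, reflecting that the two
networks have different topology; while both are active their updates are
averaged.  The walk runs for exactly max(s1, s2) iterations — the caps are
step counts, not convergence tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lns import LnsWeights
from .matrices import AssociationMatrix, PipelineConfig, SimilarityMatrix

__all__ = [
    "NormalizedNetwork",
    "column_normalize",
    "walk_step_disease",
    "walk_step_lnc",
    "unbalanced_birandom_walk",
]


@dataclass(frozen=True)
class NormalizedNetwork:
    """Column-normalized nonnegative network: every column sums to 1 or is all zero."""

    M: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        object.__setattr__(self, "M", M)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("network matrix must be square")
        if M.min() < 0:
            raise ValueError("network matrix must be nonnegative")
        sums = M.sum(axis=0)
        ok = np.isclose(sums, 1.0, atol=1e-9) | (sums == 0.0)
        if not np.all(ok):
            raise ValueError("every column must sum to 1 or be entirely zero")

    @property
    def n(self) -> int:
        return self.M.shape[0]


def column_normalize(W: LnsWeights | SimilarityMatrix | np.ndarray) -> NormalizedNetwork:
    """Divide each nonzero column by its sum; zero columns stay zero."""
    labels: tuple[str, ...] | None = None
    if isinstance(W, LnsWeights):
        vals, labels = W.W, W.labels
    elif isinstance(W, SimilarityMatrix):
        vals, labels = W.values, W.labels
    else:
        vals = np.asarray(W, dtype=float)
    if vals.min() < 0:
        raise ValueError("cannot normalize a matrix with negative entries")
    sums = vals.sum(axis=0)
    out = np.divide(vals, sums, out=np.zeros_like(vals, dtype=float), where=sums != 0)
    return NormalizedNetwork(out, labels)


def _check_dims(P: np.ndarray, net: NormalizedNetwork, side: str) -> None:
    if side == "disease" and P.shape[1] != net.n:
        raise ValueError(f"P has {P.shape[1]} columns but disease network has {net.n} nodes")
    if side == "lnc" and P.shape[0] != net.n:
        raise ValueError(f"P has {P.shape[0]} rows but lncRNA network has {net.n} nodes")


def walk_step_disease(P: np.ndarray, MD: NormalizedNetwork, Y0: np.ndarray, alpha: float) -> np.ndarray:
    """One diffusion step through the disease network: (1-alpha) P @ MD + alpha Y0."""
    P = np.asarray(P, float)
    _check_dims(P, MD, "disease")
    return (1.0 - alpha) * (P @ MD.M) + alpha * np.asarray(Y0, float)


def walk_step_lnc(P: np.ndarray, ML: NormalizedNetwork, Y0: np.ndarray, alpha: float) -> np.ndarray:
    """One diffusion step through the lncRNA network: (1-alpha) ML @ P + alpha Y0."""
    P = np.asarray(P, float)
    _check_dims(P, ML, "lnc")
    return (1.0 - alpha) * (ML.M @ P) + alpha * np.asarray(Y0, float)


def unbalanced_birandom_walk(
    Y_init: AssociationMatrix,
    MD: NormalizedNetwork,
    ML: NormalizedNetwork,
    cfg: PipelineConfig,
) -> AssociationMatrix:
    """Run the two capped restart walks and return the final score matrix F.

    P(0) is Y_init scaled to unit total mass; by default the restart matrix is
    that same normalized P(0), so alpha=1 leaves P fixed at the start and the
    scale of the iterates stays coherent (``restart_unnormalized`` restores a
    raw-matrix restart).  For iterations p = 1..max(s1, s2): the disease step
    contributes while p <= s1, the lncRNA step while p <= s2, and the active
    updates are averaged.
    """
    if cfg.s1 + cfg.s2 < 1:
        raise ValueError("at least one walk step is required (s1 + s2 >= 1)")
    Yv = Y_init.values
    total = Yv.sum()
    if total == 0:
        raise ValueError("association matrix is all zero; walk has no mass to diffuse")
    _check_dims(Yv, MD, "disease")
    _check_dims(Yv, ML, "lnc")

    P = Yv / total
    Y0 = Yv if cfg.restart_unnormalized else P.copy()
    for p in range(1, max(cfg.s1, cfg.s2) + 1):
        rD = rL = 0
        DP = LP = None
        if p <= cfg.s1:
            DP = walk_step_disease(P, MD, Y0, cfg.alpha)
            rD = 1
        if p <= cfg.s2:
            LP = walk_step_lnc(P, ML, Y0, cfg.alpha)
            rL = 1
        acc = np.zeros_like(P)
        if rD:
            acc += DP
        if rL:
            acc += LP
        P = acc / (rD + rL)
    return Y_init.with_values(np.clip(P, 0.0, 1.0))
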