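"""Gaussian interaction-profile (GIP) kernels, logistic rescaling, and fusion.

The GIP kernel scores two entities by a Gaussian of the squared Euclidean
distance between their binary association profiles (column of Y for a
disease, row for an lncRNA).  The bandwidth is normalized by the mean squared
profile norm, which makes the kernel scale-free in the number of entities.
The logistic transform 1/(1+exp(c*K + x)) then spreads the kernel values:
with the conventional offset x = ln(9999) a kernel value of 0 maps to 1e-4,
and a negative slope c makes the map order-preserving.  Finally, semantic or
functional similarity is fused linearly with the transformed kernel using raw
weights f1, f2 (no renormalization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .matrices import AssociationMatrix, SimilarityMatrix, require_same_labels

__all__ = [
    "GipParams",
    "LogisticParams",
    "gip_bandwidths",
    "gip_disease",
    "gip_lnc",
    "logistic_transform",
    "fuse",
]

_EXP_CLIP = 709.0  # largest exponent representable in float64


@dataclass(frozen=True)
class GipParams:
    """GIP kernel bandwidths: gamma_d over disease profiles, gamma_l over lncRNA profiles."""

    gamma_d: float
    gamma_l: float
    mu: int  # number of diseases
    nu: int  # number of lncRNAs

    def __post_init__(self) -> None:
        for name in ("gamma_d", "gamma_l"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")


@dataclass(frozen=True)
class LogisticParams:
    """Elementwise logistic map 1/(1+exp(c*K + x))."""

    c: float
    x: float = float(np.log(9999.0))

    def __post_init__(self) -> None:
        if not (np.isfinite(self.c) and np.isfinite(self.x)):
            raise ValueError("logistic parameters must be finite")


def gip_bandwidths(Y: AssociationMatrix, convention: str = "normalized") -> GipParams:
    """Bandwidths from mean squared profile norms.

    ``normalized`` (default): gamma_d = nd / sum_j ||Y(:,dj)||^2, i.e. the
    reciprocal of the mean squared disease-profile norm, and likewise
    gamma_l = nl / sum_i ||Y(li,:)||^2.  ``literal`` selects the plain mean
    squared norm instead of its reciprocal.
    """
    Yv = Y.values
    col_sq = float(np.sum(Yv * Yv))  # sum of squared entries = both profile sums
    if col_sq == 0.0:
        raise ValueError("all-zero association matrix: GIP bandwidth undefined")
    mu, nu = Y.n_dis, Y.n_lnc
    if convention == "normalized":
        gd, gl = mu / col_sq, nu / col_sq
    elif convention == "literal":
        gd, gl = col_sq / mu, col_sq / nu
    else:
        raise ValueError("convention must be 'normalized' or 'literal'")
    return GipParams(gamma_d=gd, gamma_l=gl, mu=mu, nu=nu)


def _gip(profiles: np.ndarray, gamma: float) -> np.ndarray:
    d2 = squareform(pdist(profiles, metric="sqeuclidean"))
    K = np.exp(-gamma * d2)
    np.fill_diagonal(K, 1.0)
    return K


def gip_disease(Y: AssociationMatrix, p: GipParams) -> SimilarityMatrix:
    """GIP kernel over diseases: KD(i,j) = exp(-gamma_d ||Y(:,di)-Y(:,dj)||^2)."""
    return SimilarityMatrix(_gip(Y.values.T, p.gamma_d), Y.dis_labels, kind="gip")


def gip_lnc(Y: AssociationMatrix, p: GipParams) -> SimilarityMatrix:
    """GIP kernel over lncRNAs: KL(i,j) = exp(-gamma_l ||Y(li,:)-Y(lj,:)||^2)."""
    return SimilarityMatrix(_gip(Y.values, p.gamma_l), Y.lnc_labels, kind="gip")


def logistic_transform(K: SimilarityMatrix, p: LogisticParams) -> SimilarityMatrix:
    """Elementwise L = 1/(1+exp(c*K + x)), exponent clipped to avoid overflow."""
    z = np.clip(p.c * K.values + p.x, -_EXP_CLIP, _EXP_CLIP)
    L = 1.0 / (1.0 + np.exp(z))
    return SimilarityMatrix(L, K.labels, kind="logistic")


def fuse(S_a: SimilarityMatrix, S_b: SimilarityMatrix, f1: float, f2: float) -> SimilarityMatrix:
    """Linear fusion F = f1*S_a + f2*S_b with raw (unnormalized) weights."""
    if f1 < 0 or f2 < 0 or (f1 == 0 and f2 == 0):
        raise ValueError("fusion weights must be >= 0 and not both 0")
    if S_a.values.shape != S_b.values.shape:
        raise ValueError(f"shape mismatch: {S_a.values.shape} vs {S_b.values.shape}")
    require_same_labels(S_a.labels, S_b.labels, "fusion")
    return SimilarityMatrix(f1 * S_a.values + f2 * S_b.values, S_a.labels, kind="fused")
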