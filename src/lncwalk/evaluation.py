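"""Cross-validation over known associations, AUC scoring, and ranked reports.

Known 1-cells are masked in turn (leave-one-out) or in shuffled fifths
(k-fold, optionally repeated); the entire pipeline is recomputed from each
masked matrix, and the held-out cells' scores are compared against the scores
of all pairs that are 0 in the *full* matrix.  The AUC is the Mann-Whitney
probability that a held-out known association outranks an unknown pair, with
ties counted half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import pipeline
from .dag import DiseaseDAG, disease_semantic_matrix
from .matrices import AssociationMatrix, LabelError, PipelineConfig, SimilarityMatrix

__all__ = ["CvScheme", "CvResult", "auc_score", "run_cv", "top_k_report"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CvScheme:
    """Cross-validation layout: LOOCV or repeated k-fold with a seeded shuffle."""

    mode: str = "loocv"
    folds: int = 5
    repeats: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in {"loocv", "kfold"}:
            raise ValueError("mode must be 'loocv' or 'kfold'")
        if self.mode == "kfold" and self.folds < 2:
            raise ValueError("k-fold cross-validation needs folds >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass(frozen=True)
class CvResult:
    """Mean/sd of per-repeat AUCs (sd is 0 for a single repeat)."""

    auc_mean: float
    auc_sd: float
    per_repeat: tuple[float, ...]

    def to_dict(self) -> dict:
        return {
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "per_repeat": list(self.per_repeat),
        }


def auc_score(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """Mann-Whitney AUC: P(pos > neg) + 0.5 P(pos == neg), via midranks."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


PredictFn = Callable[[AssociationMatrix, SimilarityMatrix, PipelineConfig], np.ndarray]


def _default_predict(Y: AssociationMatrix, Sdis: SimilarityMatrix, cfg: PipelineConfig) -> np.ndarray:
    return pipeline.predict(Y, Sdis, cfg).F.values


def run_cv(
    Y: AssociationMatrix,
    dags: Sequence[DiseaseDAG] | SimilarityMatrix,
    cfg: PipelineConfig | None = None,
    scheme: CvScheme | None = None,
    predict_fn: PredictFn | None = None,
) -> CvResult:
    """Cross-validate the pipeline on a binary association matrix.

    ``dags`` may be the per-disease DAG list (the semantic matrix is computed
    once — it does not depend on the association matrix) or a precomputed
    semantic :class:`SimilarityMatrix`.  ``predict_fn(Y_train, Sdis, cfg)``
    replaces the full pipeline when given (e.g. a baseline or a test stub).

    Within a repeat, each fold's held-out positives are scored against all
    unknown pairs using that fold's prediction matrix; the per-fold AUCs are
    pooled weighted by held-out count, which equals the mean over test
    positives of the fraction of unknown pairs they outrank.
    """
    cfg = cfg or PipelineConfig()
    scheme = scheme or CvScheme()
    predict_fn = predict_fn or _default_predict
    if isinstance(dags, SimilarityMatrix):
        Sdis = dags
    else:
        Sdis = disease_semantic_matrix(list(dags), labels=list(Y.dis_labels))

    Yv = Y.values
    if not np.array_equal(Yv, Yv.astype(bool).astype(float)):
        raise ValueError("cross-validation requires a binary association matrix")
    pos_cells = np.argwhere(Yv == 1.0)
    neg_mask = Yv == 0.0
    n_pos = len(pos_cells)
    if n_pos == 0:
        raise ValueError("no known associations to cross-validate")
    folds = n_pos if scheme.mode == "loocv" else scheme.folds
    if folds > n_pos:
        raise ValueError(f"{folds} folds but only {n_pos} known associations")
    repeats = 1 if scheme.mode == "loocv" else scheme.repeats

    rng = np.random.default_rng(scheme.seed)
    per_repeat: list[float] = []
    for _ in range(repeats):
        order = rng.permutation(n_pos) if scheme.mode == "kfold" else np.arange(n_pos)
        fold_ids = np.array_split(order, folds)
        auc_sum = 0.0
        for fold in fold_ids:
            if fold.size == 0:
                continue
            Y_train = Yv.copy()
            held = pos_cells[fold]
            Y_train[held[:, 0], held[:, 1]] = 0.0
            if np.any(Y_train.sum(axis=1) == 0) or np.any(Y_train.sum(axis=0) == 0):
                log.info("fold leaves an isolated lncRNA/disease; isolated-node handling applies")
            F = predict_fn(Y.with_values(Y_train), Sdis, cfg)
            fold_auc = auc_score(F[held[:, 0], held[:, 1]], F[neg_mask])
            auc_sum += fold.size * fold_auc
        per_repeat.append(auc_sum / n_pos)

    arr = np.asarray(per_repeat)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return CvResult(auc_mean=float(arr.mean()), auc_sd=sd, per_repeat=tuple(per_repeat))


def top_k_report(
    F: AssociationMatrix, Y_known: AssociationMatrix, disease: str, k: int
) -> pd.DataFrame:
    """Top-k lncRNAs for one disease by descending predicted score.

    Each row carries the rank, lncRNA label, score, and whether the pair is
    already a known association.  Ties are broken by ascending lncRNA index.
    """
    if disease not in F.dis_labels:
        raise LabelError(f"unknown disease label: {disease!r}")
    if k > F.n_lnc:
        raise ValueError(f"k={k} exceeds the number of lncRNAs ({F.n_lnc})")
    j = F.dis_labels.index(disease)
    scores = F.values[:, j]
    order = np.argsort(-scores, kind="stable")[:k]
    known = Y_known.values[:, j] == 1.0
    return pd.DataFrame(
        {
            "rank": np.arange(1, k + 1),
            "lncRNA": [F.lnc_labels[i] for i in order],
            "score": scores[order],
            "known": known[order],
        }
    )
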