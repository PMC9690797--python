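"""End-to-end prediction: similarities -> fusion -> WKNKN -> LNS -> walk.

`predict` wires the stages in their canonical order.  Disease semantic
similarity is an input (it depends only on the term DAGs, not on the
association matrix) so cross-validation can reuse it across folds; everything
downstream is recomputed from the (possibly masked) association matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import dag as dag_mod
from . import kernels, lns, walk, wknkn
from .matrices import AssociationMatrix, PipelineConfig, SimilarityMatrix

__all__ = ["PipelineResult", "predict", "baseline_predict", "compute_similarities"]


@dataclass
class PipelineResult:
    """Final scores plus the per-stage intermediates for inspection/export."""

    F: AssociationMatrix
    intermediates: dict = field(default_factory=dict)


def compute_similarities(
    Y: AssociationMatrix, Sdis: SimilarityMatrix, cfg: PipelineConfig
) -> dict:
    """All similarity matrices up to fusion, keyed by stage name."""
    Sl = dag_mod.lnc_functional_similarity(Y, Sdis)
    gp = kernels.gip_bandwidths(Y, cfg.bandwidth_convention)
    KD = kernels.gip_disease(Y, gp)
    KL = kernels.gip_lnc(Y, gp)
    lp = kernels.LogisticParams(c=cfg.c, x=cfg.x)
    LD = kernels.logistic_transform(KD, lp)
    LL = kernels.logistic_transform(KL, lp)
    FD = kernels.fuse(Sdis, LD, cfg.f1, cfg.f2)
    FL = kernels.fuse(Sl, LL, cfg.f1, cfg.f2)
    return {"Sl": Sl, "KD": KD, "KL": KL, "LD": LD, "LL": LL, "FD": FD, "FL": FL}


def predict(
    Y: AssociationMatrix, Sdis: SimilarityMatrix, cfg: PipelineConfig | None = None
) -> PipelineResult:
    """Run the full pipeline on a binary association matrix.

    Stages: lncRNA functional similarity from ``Sdis``; GIP kernels from the
    raw binary matrix; logistic rescaling; linear fusion (FD, FL); WKNKN fill
    of zero cells; per-entity LNS weight matrices (features = WKNKN profiles,
    neighbors ranked by fused similarity); column normalization; and the
    unbalanced bi-random walk from the WKNKN matrix.
    """
    cfg = cfg or PipelineConfig()
    sims = compute_similarities(Y, Sdis, cfg)
    FD, FL = sims["FD"], sims["FL"]

    Yt = wknkn.wknkn(
        Y, FD, FL, wknkn.WknknParams(cfg.K, cfg.eta, cfg.normalize_with_decay)
    )

    nl, nd = Y.n_lnc, Y.n_dis
    kl = min(cfg.kl, nl - 1)
    kd = min(cfg.kd, nd - 1)
    if cfg.lns_features == "profile":
        feat_l, feat_d = Yt.values, Yt.values.T
    else:
        feat_l, feat_d = FL.values, FD.values
    metric_l = FL.values if cfg.lns_neighbor_metric == "fused" else None
    metric_d = FD.values if cfg.lns_neighbor_metric == "fused" else None

    Wl = lns.lns_matrix(lns.LnsProblem(feat_l, kl, cfg.lam, metric_l)).W
    Wd = lns.lns_matrix(lns.LnsProblem(feat_d, kd, cfg.lam, metric_d)).W
    if cfg.symmetrize_lns:
        Wl = 0.5 * (Wl + Wl.T)
        Wd = 0.5 * (Wd + Wd.T)

    ML = walk.column_normalize(Wl)
    MD = walk.column_normalize(Wd)
    F = walk.unbalanced_birandom_walk(Yt, MD, ML, cfg)
    sims.update({"Y_wknkn": Yt, "Wl": Wl, "Wd": Wd, "F": F})
    return PipelineResult(F=F, intermediates=sims)


def baseline_predict(Y: AssociationMatrix, cfg: PipelineConfig | None = None) -> PipelineResult:
    """Degenerate reference: the same walk on raw GIP networks.

    Skips semantic/functional similarity, the logistic transform, fusion,
    WKNKN and LNS: the networks are the column-normalized raw GIP kernels and
    the walk starts from the raw binary matrix.  Serves as the floor any
    useful configuration of the full pipeline must beat.
    """
    cfg = cfg or PipelineConfig()
    gp = kernels.gip_bandwidths(Y, cfg.bandwidth_convention)
    MD = walk.column_normalize(kernels.gip_disease(Y, gp))
    ML = walk.column_normalize(kernels.gip_lnc(Y, gp))
    F = walk.unbalanced_birandom_walk(Y, MD, ML, cfg)
    return PipelineResult(F=F, intermediates={"F": F})
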