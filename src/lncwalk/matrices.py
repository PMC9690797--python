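"""Labeled matrix containers and TSV I/O shared by every pipeline stage.

Two containers cover the whole pipeline: :class:`AssociationMatrix` holds the
bipartite lncRNA-disease adjacency (binary on input, probabilities after
neighbor preprocessing) and :class:`SimilarityMatrix` holds any square
similarity over one entity set.  Both carry ordered string labels and validate
themselves on construction, so label agreement can be checked before any
binary operation instead of failing silently on misaligned indices.

All matrices are exchanged as labeled TSV (UTF-8, tab separator, ``.``
decimal): first row is the column labels, first column the row labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "PipelineConfig",
    "MatrixFormatError",
    "LabelError",
    "read_association_matrix",
    "read_similarity_matrix",
    "write_matrix",
]

#: similarity kinds required to be symmetric (row-wise LNS weights are not)
SYMMETRIC_KINDS = frozenset({"semantic", "functional", "gip", "logistic", "fused"})


class MatrixFormatError(ValueError):
    """A matrix file or in-memory matrix violates the expected format."""


class LabelError(MatrixFormatError):
    """Duplicate, missing, or disagreeing entity labels."""


def _check_labels(labels: Sequence[str], what: str) -> tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise LabelError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)
    return labels


@dataclass(frozen=True)
class AssociationMatrix:
    """Bipartite association matrix: lncRNAs on rows, diseases on columns.

    Values are binary {0,1} for a raw adjacency and real probabilities in
    [0,1] after WKNKN preprocessing or after the walk.  Row i is the
    interaction profile of lncRNA i; column j the profile of disease j.
    """

    values: np.ndarray
    lnc_labels: tuple[str, ...]
    dis_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.size == 0:
            raise MatrixFormatError("association matrix must be non-empty and 2-D")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "lnc_labels", _check_labels(self.lnc_labels, "lncRNA"))
        object.__setattr__(self, "dis_labels", _check_labels(self.dis_labels, "disease"))
        if vals.shape != (len(self.lnc_labels), len(self.dis_labels)):
            raise MatrixFormatError(
                f"shape {vals.shape} does not match labels "
                f"({len(self.lnc_labels)} lncRNAs x {len(self.dis_labels)} diseases)"
            )
        if not np.all(np.isfinite(vals)):
            raise MatrixFormatError("association matrix contains non-finite values")
        if vals.min() < 0.0 or vals.max() > 1.0:
            bad = np.unravel_index(int(np.argmax((vals < 0) | (vals > 1))), vals.shape)
            raise MatrixFormatError(
                f"association value out of [0,1] at row {bad[0]}, col {bad[1]}: "
                f"{vals[bad]}"
            )

    @property
    def n_lnc(self) -> int:
        return len(self.lnc_labels)

    @property
    def n_dis(self) -> int:
        return len(self.dis_labels)

    def with_values(self, values: np.ndarray) -> "AssociationMatrix":
        """Same labels, new values (revalidated)."""
        return AssociationMatrix(np.asarray(values, float), self.lnc_labels, self.dis_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.lnc_labels), columns=list(self.dis_labels))


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square nonnegative similarity over one entity set (lncRNAs or diseases)."""

    values: np.ndarray
    labels: tuple[str, ...]
    kind: str = "fused"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1] or vals.size == 0:
            raise MatrixFormatError("similarity matrix must be square and non-empty")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "labels", _check_labels(self.labels, "entity"))
        if vals.shape[0] != len(self.labels):
            raise MatrixFormatError("similarity shape does not match label count")
        if not np.all(np.isfinite(vals)):
            raise MatrixFormatError("similarity matrix contains non-finite values")
        if vals.min() < 0.0:
            raise MatrixFormatError("similarity matrix contains negative values")
        if self.kind in SYMMETRIC_KINDS and not np.allclose(vals, vals.T, atol=1e-10):
            raise MatrixFormatError(f"{self.kind} similarity must be symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise LabelError(f"unknown entity label: {label!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


def require_same_labels(a: Sequence[str], b: Sequence[str], what: str) -> None:
    """Raise :class:`LabelError` unless the two ordered label sets agree."""
    if tuple(a) != tuple(b):
        raise LabelError(f"{what} labels disagree between operands")


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline tunables.

    Defaults are the LOOCV-tuned operating point: contribution factor
    ``delta=0.5``, logistic slope ``c=-21`` with offset ``x=ln(9999)``, fusion
    weights ``f1=2, f2=10``, WKNKN neighbor count ``K=7`` with decay
    ``eta=1``, LNS neighbor counts ``kl=40`` (lncRNAs) / ``kd=60`` (diseases)
    with ridge ``lam=1``, restart weight ``alpha=0.9`` and walk step caps
    ``s1=3`` (disease network) / ``s2=1`` (lncRNA network).
    """

    delta: float = 0.5
    c: float = -21.0
    x: float = math.log(9999.0)
    f1: float = 2.0
    f2: float = 10.0
    K: int = 7
    eta: float = 1.0
    kl: int = 40
    kd: int = 60
    lam: float = 1.0
    alpha: float = 0.9
    s1: int = 3
    s2: int = 1
    seed: int = 0
    # conventions left open by the formulas; defaults documented in methods.md
    bandwidth_convention: str = "normalized"  # or "literal"
    normalize_with_decay: bool = False
    lns_features: str = "profile"  # or "similarity"
    lns_neighbor_metric: str = "fused"  # or "euclidean"
    symmetrize_lns: bool = False
    restart_unnormalized: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError("delta must lie in [0,1]")
        if self.f1 < 0 or self.f2 < 0 or (self.f1 == 0 and self.f2 == 0):
            raise ValueError("fusion weights must be >= 0 and not both 0")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not (0.0 < self.eta <= 1.0):
            raise ValueError("eta must lie in (0,1]")
        if self.kl < 1 or self.kd < 1:
            raise ValueError("kl and kd must be >= 1")
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0,1]")
        if self.s1 < 0 or self.s2 < 0 or not isinstance(self.s1, int) or not isinstance(self.s2, int):
            raise ValueError("s1 and s2 must be nonnegative integers")
        if self.s1 + self.s2 < 1:
            raise ValueError("at least one walk step is required (s1 + s2 >= 1)")
        if self.bandwidth_convention not in {"normalized", "literal"}:
            raise ValueError("bandwidth_convention must be 'normalized' or 'literal'")
        if self.lns_features not in {"profile", "similarity"}:
            raise ValueError("lns_features must be 'profile' or 'similarity'")
        if self.lns_neighbor_metric not in {"fused", "euclidean"}:
            raise ValueError("lns_neighbor_metric must be 'fused' or 'euclidean'")

    def with_overrides(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# TSV I/O


def _read_frame(path: str | Path, fmt: str) -> pd.DataFrame:
    sep = {"tsv": "\t", "csv": ","}.get(fmt)
    if sep is None:
        raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'csv'")
    # check the raw header ourselves: pandas silently renames duplicate columns
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    _check_labels(header, "column")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    frame = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for i, row in enumerate(df.itertuples(index=False)):
        for j, cell in enumerate(row):
            try:
                frame.iloc[i, j] = float(cell)
            except (TypeError, ValueError):
                raise MatrixFormatError(
                    f"non-numeric cell at data row {i + 1}, column {j + 1}: {cell!r}"
                ) from None
    return frame


def read_association_matrix(path: str | Path, format: str = "tsv") -> AssociationMatrix:
    """Read a labeled association matrix (rows = lncRNAs, columns = diseases)."""
    df = _read_frame(path, format)
    return AssociationMatrix(df.to_numpy(float), tuple(df.index), tuple(df.columns))


def read_similarity_matrix(path: str | Path, kind: str = "fused", format: str = "tsv") -> SimilarityMatrix:
    """Read a labeled square similarity matrix; row and column labels must agree."""
    df = _read_frame(path, format)
    if tuple(df.index) != tuple(df.columns):
        raise LabelError("similarity matrix row and column labels differ")
    return SimilarityMatrix(df.to_numpy(float), tuple(df.index), kind)


def _check_writable_labels(labels: Sequence[str]) -> None:
    for lab in labels:
        if any(ch in lab for ch in "\t\n\r,"):
            raise LabelError(f"label contains a separator character and cannot be written: {lab!r}")


def write_matrix(m: AssociationMatrix | SimilarityMatrix, path: str | Path) -> None:
    """Write a labeled matrix as TSV at full float precision (17 significant digits)."""
    if m.values.size == 0:
        raise MatrixFormatError("refusing to write an empty matrix")
    if isinstance(m, AssociationMatrix):
        rows, cols = m.lnc_labels, m.dis_labels
    else:
        rows, cols = m.labels, m.labels
    _check_writable_labels(rows)
    _check_writable_labels(cols)
    df = pd.DataFrame(m.values, index=list(rows), columns=list(cols))
    df.to_csv(path, sep="\t", float_format="%.17g")
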