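"""Disease semantic similarity from term DAGs, and lncRNA functional similarity.

Each disease is represented by the directed acyclic graph of its ancestors in
a MeSH-style term hierarchy (edges run child -> parent).  Every term in the
DAG contributes to the disease's semantics with a weight that decays by a
factor ``delta`` per hop away from the focal term: the focal term contributes
1 and any other term contributes ``delta`` times the largest contribution
among its children inside the DAG.  The semantic value of a disease is the sum
of these contributions, and the semantic similarity of two diseases is the
contribution mass they place on shared terms, normalized by their combined
semantic values — two diseases are similar when their ancestries overlap close
to the focal terms.

lncRNA functional similarity is lifted from disease similarity: two lncRNAs
are similar when each disease associated with one has a close counterpart
among the diseases associated with the other (best-match average).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .matrices import (
    AssociationMatrix,
    LabelError,
    SimilarityMatrix,
    require_same_labels,
)

__all__ = [
    "DiseaseDAG",
    "ContributionMap",
    "compute_contributions",
    "semantic_value",
    "semantic_similarity",
    "disease_semantic_matrix",
    "set_to_disease_similarity",
    "lnc_functional_similarity",
    "read_ontology",
    "read_term_mapping",
    "dags_from_ontology",
]


@dataclass(frozen=True)
class DiseaseDAG:
    """Ancestor DAG of one disease: the focal term plus all its ancestors.

    ``edges`` are directed child -> parent pairs among ``nodes``; every node is
    the focal term or reachable from it by repeatedly following parents.
    """

    disease_id: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    delta: float = 0.5
    #: display label for similarity matrices; defaults to the focal node id.
    #: Distinct from disease_id when several diseases map into one ontology:
    #: nodes stay term ids so shared ancestors intersect correctly.
    name: str | None = None

    def __post_init__(self) -> None:
        if self.name is None:
            object.__setattr__(self, "name", self.disease_id)
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in self.edges))
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError("delta must lie in [0,1]")
        if self.disease_id not in self.nodes:
            raise ValueError(f"focal node {self.disease_id!r} not in node set")
        for c, p in self.edges:
            if c not in self.nodes or p not in self.nodes:
                raise ValueError(f"edge ({c!r},{p!r}) references a node outside the DAG")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError(f"term graph of {self.disease_id!r} contains a cycle")
        reachable = {self.disease_id} | nx.descendants(g, self.disease_id)
        unreachable = self.nodes - reachable
        if unreachable:
            raise ValueError(
                f"nodes unreachable from focal node {self.disease_id!r}: {sorted(unreachable)}"
            )

    def graph(self) -> nx.DiGraph:
        """Directed graph with child -> parent edges over all nodes."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class ContributionMap:
    """Per-term semantic contributions of one disease's DAG (focal term = 1)."""

    disease_id: str
    contributions: Mapping[str, float]

    def __post_init__(self) -> None:
        contrib = dict(self.contributions)
        object.__setattr__(self, "contributions", contrib)
        if not contrib:
            raise ValueError("contribution map is empty")
        if contrib.get(self.disease_id) != 1.0:
            raise ValueError("focal node contribution must be exactly 1.0")
        for term, v in contrib.items():
            if not (0.0 < v <= 1.0):
                raise ValueError(f"contribution of {term!r} out of (0,1]: {v}")


def compute_contributions(dag: DiseaseDAG) -> ContributionMap:
    """Decay-per-hop contributions of every term in a disease's ancestor DAG.

    Processed in topological order (all children of a term before the term
    itself), so each non-focal term sees the final contributions of its
    children when taking the max.
    """
    g = dag.graph()
    contrib: dict[str, float] = {}
    for node in nx.topological_sort(g):
        if node == dag.disease_id:
            contrib[node] = 1.0
        else:
            children = [c for c in g.predecessors(node)]
            # reachability was validated, so children is non-empty here
            contrib[node] = dag.delta * max(contrib[c] for c in children)
    return ContributionMap(dag.disease_id, contrib)


def semantic_value(cm: ContributionMap) -> float:
    """Semantic value of a disease: the sum of all term contributions (>= 1)."""
    return float(sum(cm.contributions.values()))


def semantic_similarity(cm_i: ContributionMap, cm_j: ContributionMap) -> float:
    """Overlap of two contribution maps, normalized to [0,1] and symmetric.

    Sums, over terms present in both DAGs, the contribution each disease gives
    that term, divided by the sum of the two semantic values.  Disjoint DAGs
    score 0; identical DAGs score 1.
    """
    shared = set(cm_i.contributions) & set(cm_j.contributions)
    num = sum(cm_i.contributions[t] + cm_j.contributions[t] for t in shared)
    return float(num / (semantic_value(cm_i) + semantic_value(cm_j)))


def disease_semantic_matrix(dags: Sequence[DiseaseDAG], labels: Sequence[str] | None = None) -> SimilarityMatrix:
    """Pairwise semantic similarity over a list of per-disease DAGs.

    ``labels`` fixes the output order (default: DAG order); a label without a
    DAG is an error naming the disease.
    """
    by_id = {d.name: d for d in dags}
    if labels is None:
        labels = [d.name for d in dags]
    deltas = {d.delta for d in dags}
    if len(deltas) > 1:
        raise ValueError(f"all DAGs must share one delta, got {sorted(deltas)}")
    maps = {}
    for lab in labels:
        if lab not in by_id:
            raise LabelError(f"no DAG provided for disease {lab!r}")
        maps[lab] = compute_contributions(by_id[lab])
    n = len(labels)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = semantic_similarity(maps[labels[i]], maps[labels[j]])
    return SimilarityMatrix(S, tuple(labels), kind="semantic")


def set_to_disease_similarity(d: str, S: Iterable[str], Sdis: SimilarityMatrix) -> float:
    """Best-match similarity between disease ``d`` and a non-empty disease set."""
    members = list(S)
    if not members:
        raise ValueError("disease set is empty")
    i = Sdis.index_of(d)
    return float(max(Sdis.values[i, Sdis.index_of(m)] for m in members))


def lnc_functional_similarity(Y: AssociationMatrix, Sdis: SimilarityMatrix) -> SimilarityMatrix:
    """Functional similarity of lncRNAs from their associated disease sets.

    For lncRNAs with disease sets Dis1 (size m) and Dis2 (size n), the score
    is the mean best-match similarity across both directions:
    (sum_i max_j Sdis(d1i, Dis2) + sum_j max_i Sdis(d2j, Dis1)) / (m + n).

    An lncRNA with no associations has an undefined disease set; by
    convention its self-similarity is 1 and its similarity to every other
    lncRNA is 0, so isolated rows do not poison the matrix.
    """
    require_same_labels(Y.dis_labels, Sdis.labels, "disease")
    Yv = Y.values
    nl = Y.n_lnc
    dis_sets = [np.flatnonzero(Yv[i] > 0) for i in range(nl)]
    S = np.eye(nl)
    Sd = Sdis.values
    for i in range(nl):
        a = dis_sets[i]
        if a.size == 0:
            continue  # row/col stay 0, diagonal stays 1
        for j in range(i + 1, nl):
            b = dis_sets[j]
            if b.size == 0:
                continue
            cross = Sd[np.ix_(a, b)]
            val = (cross.max(axis=1).sum() + cross.max(axis=0).sum()) / (a.size + b.size)
            S[i, j] = S[j, i] = val
    return SimilarityMatrix(S, Y.lnc_labels, kind="functional")


# ---------------------------------------------------------------------------
# Ontology plumbing: one global child->parent edge list, per-disease closures.


def read_ontology(path: str | Path) -> list[tuple[str, str]]:
    """Read a term hierarchy edge list TSV with columns child_id, parent_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.strip() for c in df.columns]
    if cols[:2] != ["child_id", "parent_id"]:
        raise ValueError(f"ontology file must have columns child_id, parent_id; got {cols}")
    return [(str(c), str(p)) for c, p in zip(df.iloc[:, 0], df.iloc[:, 1])]


def read_term_mapping(path: str | Path) -> dict[str, str]:
    """Read a disease_label -> term_id mapping TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.strip() for c in df.columns]
    if cols[:2] != ["disease_label", "term_id"]:
        raise ValueError(f"mapping file must have columns disease_label, term_id; got {cols}")
    mapping: dict[str, str] = {}
    for lab, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if lab in mapping:
            raise LabelError(f"duplicate disease label in mapping: {lab!r}")
        mapping[str(lab)] = str(term)
    return mapping


def dags_from_ontology(
    edges: Sequence[tuple[str, str]],
    mapping: Mapping[str, str],
    delta: float = 0.5,
) -> list[DiseaseDAG]:
    """Per-disease ancestor DAGs extracted from one global ontology edge list.

    The DAG of a disease is the closure of its mapped term under the
    child -> parent relation: the term itself, all its ancestors, and all
    hierarchy edges among them.  Nodes keep their term ids (so shared
    ancestors of different diseases intersect); the disease label travels in
    the DAG's ``name`` and labels downstream similarity matrices.
    """
    g = nx.DiGraph()
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("ontology edge list contains a cycle")
    dags = []
    for disease, term in mapping.items():
        if term not in g:
            raise ValueError(f"term {term!r} for disease {disease!r} not in ontology")
        ancestors = {term} | nx.descendants(g, term)
        sub = [(c, p) for c, p in edges if c in ancestors and p in ancestors]
        dags.append(
            DiseaseDAG(
                disease_id=term,
                nodes=frozenset(ancestors),
                edges=frozenset(sub),
                delta=delta,
                name=disease,
            )
        )
    return dags
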