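"""Semantic contributions, disease similarity, and lncRNA functional similarity."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncwalk import (
    AssociationMatrix,
    DiseaseDAG,
    SimilarityMatrix,
    compute_contributions,
    disease_semantic_matrix,
    lnc_functional_similarity,
    semantic_similarity,
    semantic_value,
    set_to_disease_similarity,
)
from lncwalk.dag import dags_from_ontology
from lncwalk.matrices import LabelError


def bfs_hop_oracle(dag: DiseaseDAG) -> dict[str, float]:
    """Independent oracle: contribution = delta ** (min hops focal -> node)."""
    g = nx.DiGraph()
    g.add_nodes_from(dag.nodes)
    g.add_edges_from(dag.edges)
    hops = nx.single_source_shortest_path_length(g, dag.disease_id)
    return {n: dag.delta**h for n, h in hops.items()}


def random_dag(rng: np.random.Generator, n_nodes: int, delta: float = 0.5) -> DiseaseDAG:
    """Random ancestor DAG: each non-focal node gets >=1 child among earlier nodes."""
    names = [f"t{i}" for i in range(n_nodes)]
    edges = set()
    for i in range(1, n_nodes):
        n_children = 1 + rng.integers(0, min(i, 3))
        for c in rng.choice(i, size=n_children, replace=False):
            edges.add((names[int(c)], names[i]))
    return DiseaseDAG(names[0], set(names), edges, delta)


class TestContributions:
    def test_single_edge_chain(self):
        dag = DiseaseDAG("Di", {"Di", "p"}, {("Di", "p")}, 0.5)
        assert compute_contributions(dag).contributions == {"Di": 1.0, "p": 0.5}

    def test_textbook_four_node_dag(self, dsn_dag):
        cm = compute_contributions(dsn_dag)
        assert cm.contributions == {
            "Digestive System Neoplasms": 1.0,
            "Digestive System Diseases": 0.5,
            "Neoplasms by Site": 0.5,
            "Neoplasms": 0.25,
        }

    def test_diamond_takes_shortest_path(self):
        # "top" reachable via 2 hops (through a) and 3 hops (through b->c)
        dag = DiseaseDAG(
            "f",
            {"f", "a", "b", "c", "top"},
            {("f", "a"), ("f", "b"), ("b", "c"), ("a", "top"), ("c", "top")},
            0.5,
        )
        cm = compute_contributions(dag)
        assert cm.contributions["top"] == max(0.5**2, 0.5**3) == 0.25

    def test_matches_bfs_hop_oracle_on_random_dags(self, rng):
        for _ in range(25):
            dag = random_dag(rng, int(rng.integers(2, 12)))
            assert compute_contributions(dag).contributions == pytest.approx(bfs_hop_oracle(dag))

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            DiseaseDAG("a", {"a", "b"}, {("a", "b"), ("b", "a")})

    def test_unreachable_node_rejected(self):
        with pytest.raises(ValueError, match="unreachable"):
            DiseaseDAG("a", {"a", "b", "orphan"}, {("a", "b")})


class TestSemanticValue:
    def test_textbook_values(self, dsn_dag, bgn_dag):
        assert semantic_value(compute_contributions(dsn_dag)) == 2.25
        assert semantic_value(compute_contributions(bgn_dag)) == 2.625

    def test_single_node_dag(self):
        assert semantic_value(compute_contributions(DiseaseDAG("x", {"x"}, set()))) == 1.0


class TestSemanticSimilarity:
    def test_textbook_pair(self, dsn_dag, bgn_dag):
        sim = semantic_similarity(compute_contributions(dsn_dag), compute_contributions(bgn_dag))
        assert round(sim, 4) == 0.6923

    def test_identical_diseases_score_one(self, bgn_dag):
        cm = compute_contributions(bgn_dag)
        assert semantic_similarity(cm, cm) == 1.0

    def test_disjoint_dags_score_zero(self):
        a = compute_contributions(DiseaseDAG("a", {"a", "p"}, {("a", "p")}))
        b = compute_contributions(DiseaseDAG("b", {"b", "q"}, {("b", "q")}))
        assert semantic_similarity(a, b) == 0.0

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_symmetric_and_bounded_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        # overlapping node pools so intersections are common
        a = random_dag(rng, int(rng.integers(2, 10)))
        b = random_dag(rng, int(rng.integers(2, 10)))
        ca, cb = compute_contributions(a), compute_contributions(b)
        s_ab, s_ba = semantic_similarity(ca, cb), semantic_similarity(cb, ca)
        assert s_ab == s_ba
        assert 0.0 <= s_ab <= 1.0

    def test_adding_shared_ancestor_never_decreases_similarity(self):
        a0 = DiseaseDAG("a", {"a", "r"}, {("a", "r")})
        b0 = DiseaseDAG("b", {"b", "r"}, {("b", "r")})
        base = semantic_similarity(compute_contributions(a0), compute_contributions(b0))
        a1 = DiseaseDAG("a", {"a", "r", "s"}, {("a", "r"), ("r", "s")})
        b1 = DiseaseDAG("b", {"b", "r", "s"}, {("b", "r"), ("r", "s")})
        grown = semantic_similarity(compute_contributions(a1), compute_contributions(b1))
        assert grown >= base


class TestSemanticMatrix:
    def test_identical_dags_give_all_ones(self):
        a = DiseaseDAG("t", {"t", "p"}, {("t", "p")}, name="dA")
        b = DiseaseDAG("t", {"t", "p"}, {("t", "p")}, name="dB")
        S = disease_semantic_matrix([a, b])
        np.testing.assert_allclose(S.values, np.ones((2, 2)))

    def test_textbook_pair_off_diagonal(self, dsn_dag, bgn_dag):
        S = disease_semantic_matrix([dsn_dag, bgn_dag])
        assert round(S.values[0, 1], 4) == 0.6923
        np.testing.assert_allclose(np.diag(S.values), 1.0)

    def test_matrix_equals_pairwise_calls(self, rng):
        dags = [random_dag(rng, int(rng.integers(2, 8))) for _ in range(5)]
        dags = [
            DiseaseDAG(d.disease_id, d.nodes, d.edges, d.delta, name=f"dis{i}")
            for i, d in enumerate(dags)
        ]
        S = disease_semantic_matrix(dags)
        cms = [compute_contributions(d) for d in dags]
        for i in range(5):
            for j in range(5):
                expect = 1.0 if i == j else semantic_similarity(cms[i], cms[j])
                assert S.values[i, j] == pytest.approx(expect)

    def test_missing_dag_named_in_error(self, dsn_dag):
        with pytest.raises(LabelError, match="ghost"):
            disease_semantic_matrix([dsn_dag], labels=["ghost"])


class TestSetToDiseaseSimilarity:
    @pytest.fixture()
    def sdis(self):
        v = np.array([[1.0, 0.2, 0.7, 0.4], [0.2, 1, 0.1, 0.3], [0.7, 0.1, 1, 0.5], [0.4, 0.3, 0.5, 1]])
        return SimilarityMatrix(v, ("a", "b", "c", "d"), kind="semantic")

    def test_member_of_own_set_scores_one(self, sdis):
        assert set_to_disease_similarity("a", {"a", "b"}, sdis) == 1.0

    def test_singleton_set(self, sdis):
        assert set_to_disease_similarity("a", {"c"}, sdis) == 0.7

    def test_max_over_three(self, sdis):
        assert set_to_disease_similarity("a", {"b", "c", "d"}, sdis) == 0.7

    def test_empty_set_rejected(self, sdis):
        with pytest.raises(ValueError, match="empty"):
            set_to_disease_similarity("a", set(), sdis)


class TestFunctionalSimilarity:
    def sdis3(self, s_ab=0.6, s_ac=0.2, s_bc=0.3):
        v = np.array([[1.0, s_ab, s_ac], [s_ab, 1.0, s_bc], [s_ac, s_bc, 1.0]])
        return SimilarityMatrix(v, ("dA", "dB", "dC"), kind="semantic")

    def test_identical_disease_sets_score_one(self):
        Y = AssociationMatrix(np.array([[1.0, 0, 1], [1, 0, 1]]), ("l1", "l2"), ("dA", "dB", "dC"))
        S = lnc_functional_similarity(Y, self.sdis3())
        assert S.values[0, 1] == pytest.approx(1.0)

    def test_hand_worked_best_match_average(self):
        # Dis1={dA}, Dis2={dB,dC}: (max(0.6,0.2) + 0.6 + 0.2) / 3
        Y = AssociationMatrix(np.array([[1.0, 0, 0], [0, 1, 1]]), ("l1", "l2"), ("dA", "dB", "dC"))
        S = lnc_functional_similarity(Y, self.sdis3())
        assert S.values[0, 1] == pytest.approx((0.6 + 0.6 + 0.2) / 3)

    def test_unrelated_disease_sets_score_zero(self):
        Y = AssociationMatrix(np.array([[1.0, 0, 0], [0, 0, 1]]), ("l1", "l2"), ("dA", "dB", "dC"))
        S = lnc_functional_similarity(Y, self.sdis3(s_ab=0.0, s_ac=0.0, s_bc=0.0))
        assert S.values[0, 1] == 0.0

    def test_isolated_lncrna_self_one_others_zero(self):
        Y = AssociationMatrix(np.array([[1.0, 0, 0], [0, 0, 0]]), ("l1", "l2"), ("dA", "dB", "dC"))
        S = lnc_functional_similarity(Y, self.sdis3())
        assert S.values[1, 1] == 1.0
        assert S.values[0, 1] == 0.0


class TestOntologyExtraction:
    def test_closure_intersects_on_term_ids(self):
        # two diseases whose focal terms share the chain c -> b -> a
        edges = [("b", "a"), ("c", "b"), ("x", "c"), ("y", "b")]
        dags = dags_from_ontology(edges, {"dX": "x", "dY": "y"}, delta=0.5)
        S = disease_semantic_matrix(dags, labels=["dX", "dY"])
        # shared ancestors of x (b,a via c) and y (b,a): strictly positive
        assert 0.0 < S.values[0, 1] < 1.0

    def test_same_term_diseases_are_identical(self):
        edges = [("b", "a")]
        dags = dags_from_ontology(edges, {"d1": "b", "d2": "b"})
        S = disease_semantic_matrix(dags, labels=["d1", "d2"])
        assert S.values[0, 1] == 1.0
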