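"""Shared fixtures: the textbook DAG pair and a small synthetic dataset."""

import numpy as np
import pytest

from lncwalk import DiseaseDAG, SyntheticSpec, disease_semantic_matrix, make_dataset


@pytest.fixture(scope="session")
def dsn_dag() -> DiseaseDAG:
    """Digestive System Neoplasms: two direct parents, both children of one root."""
    return DiseaseDAG(
        disease_id="Digestive System Neoplasms",
        nodes={
            "Digestive System Neoplasms",
            "Digestive System Diseases",
            "Neoplasms by Site",
            "Neoplasms",
        },
        edges={
            ("Digestive System Neoplasms", "Digestive System Diseases"),
            ("Digestive System Neoplasms", "Neoplasms by Site"),
            ("Digestive System Diseases", "Neoplasms"),
            ("Neoplasms by Site", "Neoplasms"),
        },
        delta=0.5,
    )


@pytest.fixture(scope="session")
def bgn_dag() -> DiseaseDAG:
    """Breast Gastrointestinal Neoplasms: a deeper DAG overlapping the one above."""
    return DiseaseDAG(
        disease_id="Breast Gastrointestinal Neoplasms",
        nodes={
            "Breast Gastrointestinal Neoplasms",
            "Gastrointestinal Diseases",
            "Digestive System Diseases",
            "Digestive System Neoplasms",
            "Neoplasms by Site",
            "Neoplasms",
        },
        edges={
            ("Breast Gastrointestinal Neoplasms", "Gastrointestinal Diseases"),
            ("Breast Gastrointestinal Neoplasms", "Digestive System Neoplasms"),
            ("Gastrointestinal Diseases", "Digestive System Diseases"),
            ("Digestive System Neoplasms", "Digestive System Diseases"),
            ("Digestive System Neoplasms", "Neoplasms by Site"),
            ("Digestive System Diseases", "Neoplasms"),
            ("Neoplasms by Site", "Neoplasms"),
        },
        delta=0.5,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Seeded 14x9 two-block dataset: (Y, dags, Sdis). Small enough for fast CV."""
    spec = SyntheticSpec(n_lnc=14, n_dis=9, n_blocks=2, dag_branching=2, seed=7)
    Y, dags, _, _ = make_dataset(spec)
    Sdis = disease_semantic_matrix(dags, labels=list(Y.dis_labels))
    return Y, dags, Sdis


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
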