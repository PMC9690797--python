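"""Disease semantic similarity from two overlapping term DAGs.

Builds the classic digestive-neoplasm example: one disease whose DAG has
four terms and a second, deeper disease whose DAG shares all four of them.
Prints the per-term contributions, the semantic values, and the pairwise
similarity.
"""

from lncwalk import DiseaseDAG, compute_contributions, semantic_similarity, semantic_value

dsn = DiseaseDAG(
    disease_id="Digestive System Neoplasms",
    nodes={"Digestive System Neoplasms", "Digestive System Diseases", "Neoplasms by Site", "Neoplasms"},
    edges={
        ("Digestive System Neoplasms", "Digestive System Diseases"),
        ("Digestive System Neoplasms", "Neoplasms by Site"),
        ("Digestive System Diseases", "Neoplasms"),
        ("Neoplasms by Site", "Neoplasms"),
    },
    delta=0.5,
)
bgn = DiseaseDAG(
    disease_id="Breast Gastrointestinal Neoplasms",
    nodes={
        "Breast Gastrointestinal Neoplasms", "Gastrointestinal Diseases",
        "Digestive System Diseases", "Digestive System Neoplasms",
        "Neoplasms by Site", "Neoplasms",
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

for dag in (dsn, bgn):
    cm = compute_contributions(dag)
    print(f"{dag.disease_id}:")
    for term, c in sorted(cm.contributions.items(), key=lambda kv: -kv[1]):
        print(f"  {c:5.3f}  {term}")
    print(f"  semantic value = {semantic_value(cm)}")

sim = semantic_similarity(compute_contributions(dsn), compute_contributions(bgn))
print(f"\nsemantic similarity = {sim:.4f}")
print("(shared ancestor mass over combined semantic value: 1 means identical DAGs)")
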