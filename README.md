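# lncwalk

Link prediction on bipartite lncRNA–disease association networks.

Experimentally confirmed lncRNA–disease associations (LDAs) are scarce: a
typical curated matrix has a few hundred 1-entries over tens of thousands of
candidate pairs. `lncwalk` ranks the unknown pairs by combining several
similarity views of both entity sets and diffusing the known associations
through them. It is a library first — import it from Python — with a thin
`lncwalk` CLI and narrative scripts under `examples/` for each capability.

## Method

Given a binary association matrix **Y** ∈ {0,1}^(nl×nd) (rows = lncRNAs,
columns = diseases) and a MeSH-style term hierarchy:

1. **Disease semantic similarity** S_dis. Each disease is an ancestor DAG in
   the hierarchy. A term's contribution decays by factor δ per hop from the
   focal term (D(d) = δ·max over children of d); the similarity of two
   diseases is the contribution mass on shared terms divided by the sum of
   their semantic values D_sum = Σ_d D(d).
2. **lncRNA functional similarity** S_l: best-match average of S_dis across
   the two lncRNAs' associated disease sets.
3. **GIP kernel + logistic rescaling.** K(i,j) = exp(−γ‖y_i − y_j‖²) over
   association profiles, bandwidth γ normalized by the mean squared profile
   norm, then L = 1/(1+exp(cK + x)) with x = ln(9999) so an empty overlap
   maps to 1e-4.
4. **Fusion**: FD = f1·S_dis + f2·LD and FL = f1·S_l + f2·LL.
5. **WKNKN**: zero cells of Y are filled with decayed, similarity-weighted
   averages of the K nearest known neighbors' profiles (disease side and
   lncRNA side, averaged).
6. **Linear neighborhood similarity (LNS)**: each entity is reconstructed
   from its k nearest neighbors by minimizing w'(G+λI)w on the probability
   simplex (a small QP per entity), giving row-stochastic weight matrices
   W_l, W_d that repair isolated nodes.
7. **Unbalanced bi-random walk**: restart walks on the column-normalized
   W_d and W_l run simultaneously with different step caps s1, s2
   (P ← (1−α)·P·MD + α·P0 on the disease side, mirrored on the lncRNA side,
   averaged while both are active). The final P is the score matrix **F**.

Evaluation is by LOOCV or repeated 5-fold CV: held-out associations are
scored against all unknown pairs, summarized as a Mann–Whitney AUC.

## Worked example

`examples/semantic_similarity.py` builds two overlapping disease DAGs and
prints:

```
Digestive System Neoplasms:
  1.000  Digestive System Neoplasms
  0.500  Neoplasms by Site
  0.500  Digestive System Diseases
  0.250  Neoplasms
  semantic value = 2.25
...
semantic similarity = 0.6923
```

The semantic value 2.25 is the total ancestor contribution of the four-term
DAG (1 + 0.5 + 0.5 + 0.25); 0.6923 is the fraction of the two diseases'
combined semantic mass that sits on shared terms — they overlap strongly
because one DAG contains the other.

`examples/cross_validate.py` runs repeated 5-fold CV on a 20×15 synthetic
planted-block dataset and prints:

```
full pipeline AUC = 0.8799 (+/- 0.0498)
raw-GIP baseline  = 0.7500 (+/- 0.0768)
```

i.e. a held-out association outranks a random unknown pair 88% of the time,
and the fused-similarity machinery clearly beats a bare GIP walk.
`examples/predict_associations.py` shows the per-disease top-k ranking with
known associations flagged.

## Command line

```sh
lncwalk simulate --out-dir fixture             # synthetic Y + ontology + mapping
lncwalk predict  --assoc fixture/Y.tsv --ontology fixture/ontology.tsv \
                 --mapping fixture/mapping.tsv --out-dir run
lncwalk evaluate --assoc fixture/Y.tsv --ontology fixture/ontology.tsv \
                 --mapping fixture/mapping.tsv --mode kfold --repeats 10
lncwalk similarity ... --which semantic --out sdis.tsv
```

All matrices are labeled TSV; every run writes a `manifest.json` with the
resolved configuration, input digests and seed.

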