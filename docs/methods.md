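# Methods

## Data model

The association matrix Y has lncRNAs on rows and diseases on columns; a cell
is 1 when the association is experimentally supported, 0 when unknown (not
negative — the method's task is precisely to rank those zeros). All matrices
carry ordered string labels, and every binary operation checks label
agreement before computing. One matrix-orientation remark for readers of the
walk equations: the products P·MD and ML·P only type-check when the
prediction matrix P is nl×nd (lncRNAs × diseases); the package uses that
orientation throughout.

## Disease semantic similarity

Each disease maps to a term in a child→parent ontology; its DAG is the
ancestor closure of that term. Contributions follow the standard
decay-per-hop recursion with factor δ (default 0.5): the focal term
contributes 1, every other term δ times the best of its children. Because
the max propagates along shortest paths, the contribution of a term equals
δ^h with h the minimum hop count from the focal term — the test suite uses a
BFS on exactly this identity as an independent oracle. Similarity is shared
contribution mass normalized by combined semantic value, which is symmetric,
lies in [0,1], and is 1 exactly for identical DAGs.

DAGs extracted from one global ontology keep term ids as node names (the
disease label travels separately); two diseases mapped to the same term are
then correctly identical, and a focal term appearing as another disease's
ancestor is correctly counted as shared.

Functional similarity of lncRNAs is the best-match average of disease
similarities across the two associated disease sets. An lncRNA with no
associations has an undefined disease set; the package defines its
self-similarity as 1 and its similarity to others as 0 so the denominator
m+n=0 case never arises and isolated rows stay inert. The fused GIP term
still gives such nodes usable structure.

## GIP kernel and logistic rescaling

The kernel bandwidth is the reciprocal mean squared profile norm
(γ_d = nd / Σ_j ‖Y(:,d_j)‖², likewise γ_l over rows), the convention that
makes the kernel scale-free in the entity counts; a `bandwidth_convention`
switch selects the plain mean squared norm instead for comparability with
implementations that read the formula the other way. The kernel is computed
from the raw binary matrix, before WKNKN, matching the stage order of the
algorithm. The logistic map 1/(1+exp(cK+x)) uses x = ln(9999) — chosen so
K = 0 maps to exactly 1e-4 — and a negative slope c so the map is
order-preserving; exponents are clipped at ±709 so extreme parameters cannot
overflow. Fusion uses raw weights (default f1 = 2, f2 = 10) without
renormalization; downstream stages that need probabilities normalize
themselves.

## WKNKN preprocessing

For each disease, the K most similar other diseases (by fused similarity,
ties broken by ascending index; self excluded) contribute their association
profiles with weights η^(r−1)·sim(r), normalized by the plain sum of the K
similarities — implemented literally as printed in the source formulation,
where the decay appears in the numerator only. With the default η = 1 this
is an exact similarity-weighted mean; a `normalize_with_decay` flag selects
the fully decayed normalizer. The disease-side and lncRNA-side estimates are
averaged into each zero cell; 1-cells are never touched, so the output
dominates the input elementwise. Fused similarities are max-normalized
inside this stage only, keeping filled values interpretable as probabilities
in [0,1] even though f1+f2 ≠ 1. An entity whose neighbor similarities are
all zero contributes nothing (logged) rather than raising.

## Linear neighborhood similarity

Each entity's feature vector is its WKNKN-filled association profile (row
for lncRNAs, column for diseases) — the stage ordering implies LNS sees the
preprocessed matrix — and neighbors are ranked by fused similarity so the
neighborhood definition is consistent with the rest of the pipeline
(`lns_features` / `lns_neighbor_metric` switch both choices). The per-entity
QP minimizes w'(G+λI)w on the simplex with λ = 1. The solver first evaluates
the equality-constrained KKT closed form (G+λI)^{-1}·1 normalized to sum 1,
which is the exact optimum whenever nonnegative; otherwise SLSQP runs from
the uniform start with ftol 1e-14. Every row is verified against the
uniform-weight objective bound, weights below 1e-12 are clipped and the row
renormalized, so W is row-stochastic to 1e-8. W is used asymmetric, as in
label propagation; `symmetrize_lns` averages it with its transpose when a
symmetric network is wanted. Neighbor counts kl, kd are capped at n−1 at
desk scale.

## Unbalanced bi-random walk

Both networks are column-normalized with zero columns left zero (isolated
nodes simply do not forward mass). P(0) is the WKNKN matrix scaled to unit
total mass, and the restart matrix defaults to that same P(0): restarting to
the normalized matrix keeps the iterate scale coherent and makes α = 1 a
fixed point (`restart_unnormalized` restores a raw-matrix restart). The walk
runs exactly max(s1, s2) iterations — the caps are step counts, not
convergence tolerances — computing the disease-side update while p ≤ s1 and
the lncRNA-side update while p ≤ s2 and averaging the active ones. Defaults
s1 = 3, s2 = 1 reflect that the disease network (semantic + kernel) is the
richer of the two.

## Defaults

| parameter | default | meaning |
|---|---|---|
| δ | 0.5 | semantic contribution decay per hop |
| c, x | −21, ln 9999 | logistic slope / offset |
| f1, f2 | 2, 10 | fusion weights (semantic/functional vs logistic kernel) |
| K, η | 7, 1 | WKNKN neighbor count and decay |
| kl, kd | 40, 60 | LNS neighbor counts (capped at n−1) |
| λ | 1 | LNS ridge |
| α | 0.9 | restart weight |
| s1, s2 | 3, 1 | walk step caps (disease / lncRNA network) |

These are the jointly tuned LOOCV operating point for a curated
115-lncRNA × 178-disease association matrix; on much smaller matrices the
neighbor counts saturate at n−1 and the remaining parameters transfer
unchanged.

## Evaluation

`auc_score` is the Mann–Whitney statistic computed from midranks (ties count
half); the test suite cross-checks it against exhaustive pair counting and
against scikit-learn's ROC-AUC, which are never used as the implementation.
In cross-validation the negatives are all pairs that are 0 in the full
matrix, fixed across folds; each fold's held-out positives are scored with
that fold's prediction matrix and per-fold AUCs are pooled weighted by
held-out count — equivalent to asking, for every test association, what
fraction of unknown pairs it outranks. Disease semantic similarity is not
recomputed per fold (it depends only on the ontology); everything downstream
of the association matrix is. Repeated 5-fold CV reports mean ± sd over
repeats.

## Synthetic data

The generator plants co-association blocks: lncRNAs and diseases are
partitioned into n_blocks groups, each disease block maps onto one subtree
of a synthetic term tree (so within-block diseases share deep ancestors),
and cells are Bernoulli with density_in inside matched blocks and
density_out elsewhere. This realizes exactly the assumption the walk
exploits — similar diseases associate with similar lncRNAs — so held-out
recovery on these fixtures tests the machinery, not the assumption.

Default size is 30 × 24 with 3 blocks, density_out 0.02, and density_in
0.70. The in-block density is calibrated analytically: in-block zero cells
count as unknown pairs during evaluation, so a perfect block oracle's AUC is
capped at roughly 1 − r/2 where r is the in-block share of zeros. At
density_in 0.30 that ceiling is ≈ 0.79 — no method can look good — while
0.70 puts it at ≈ 0.9, the regime curated LDA benchmarks occupy. What these
fixtures do **not** emulate: scale-free degree distributions, annotation
bias (well-studied lncRNAs accumulate associations), inter-block similarity
gradients, or noisy ontology placement; a high AUC here demonstrates the
pipeline recovers planted structure, not that it will score the same on real
curated data.

## Problem sizes and numerical choices

The default test-suite and example workloads are desk-scale (matrices up to
30 × 24, LOOCV over ≈160 positives, ≈100 QP oracle instances), chosen so
the complete check-suite runs in about a minute while still exercising every
stage jointly. Determinism: every stochastic routine takes an explicit seed,
the pipeline itself is deterministic, and tie-breaks (neighbor ranking,
top-k reports) are by ascending index. Degenerate inputs have defined
behavior throughout: all-zero rows are allowed (isolated-node conventions),
an all-zero matrix is rejected where a computation is undefined (GIP
bandwidth, the walk), and empty matrices are rejected at I/O.

## Known limitations

- The semantic measure is the decay-per-hop family only; information-content
  measures (Resnik and relatives) are out of scope.
- WKNKN and LNS neighbor counts interact at small n (both saturate near
  n−1), so parameter sensitivity studies need n well above the neighbor
  counts to be meaningful.
- The walk has no convergence criterion by design; very large step caps with
  α near 0 can drift the score scale (scores should be read as rankings).
- Real MeSH descriptor files are not parsed; the ontology must arrive as a
  child→parent edge list plus a disease→term mapping.
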