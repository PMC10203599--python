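# Methods

## Model

`lmdti` predicts drug–target interactions (DTIs) by binary classification
of drug–target pairs with features extracted from a weighted heterogeneous
network. The network *G(V, E)* has four node kinds — drugs (D), protein
targets (T), lncRNAs (L) and miRNAs (M) — and two edge classes:

* **interaction edges** from six bipartite layers (D–T, D–L, D–M, L–T,
  M–T, L–M), always weight 1.0;
* **similarity edges** among drugs and among targets, weighted by the
  similarity value in (0, 1].

The model assumes the input similarities are already normalised to [0, 1]
with unit self-similarity, and that all eight layers describe symmetric
relations, so the graph is undirected. Similarity edges below a
configurable threshold (`network.sim_threshold`, default 0: keep every
non-zero similarity) are dropped before the merge. The default of 0 keeps
maximal information; the threshold exists because sparse similarity graphs
are sometimes preferred at scale.

### Pair features

**node2vec.** Second-order random walks with return parameter *p* and
in-out parameter *q*: standing at node *v* having arrived from *u*, the
unnormalised probability of stepping to neighbour *x* is
*w(v,x)·α(u,x)* with α = 1/p if *x = u*, 1 if *x* is adjacent to *u*, and
1/q otherwise; the first step of a walk is first-order. `num_walks` walks
of `walk_length` nodes start from every node; isolated nodes yield
length-1 walks so every node receives a vector. The corpus trains a
skip-gram model with negative sampling (SGNS): sequential stochastic
gradient descent, one update per (centre, context) pair, negatives drawn
from the unigram distribution raised to 3/4, dot products clipped to ±8
inside the sigmoid, learning rate decaying linearly from `alpha` (0.025)
to `alpha/1000`. The SGNS trainer is implemented in-package (numpy with a
jit-compiled inner loop) and is deterministic given the seed because
training is strictly sequential and single-threaded.

Defaults: p = q = 1, d = 64, 10 walks per node, walk length 30, window 5,
5 epochs, 5 negatives. The published search grid over these knobs is
exposed by `hyperparameter_grid` (1600 configurations; walk lengths
10–40 for small networks, 60–120 for large ones) with mean validation
AUPR as the intended selection objective.

**Path scores (PSM).** Path scoring is restricted to the drug/target
sub-network — the similarity matrices Sd (n×n) and St (m×m) with zero
diagonal plus the binary interaction matrix A (n×m) — both for runtime
and because drug–target paths through ncRNA nodes are not part of the
score definition. A path scores the product of its edge weights; paths
are simple (no node may appear twice, endpoints included) and 2–3 edges
long, which admits exactly six kind templates P1: D–D–T, P2: D–T–T,
P3: D–D–D–T, P4: D–D–T–T, P5: D–T–D–T, P6: D–T–T–T. Per template the Sum
and Max over all matching paths between (dᵢ, tⱼ) give the 12 PSM features.

Sum scores are computed by chained matrix products (P1 = Sd·A,
P2 = A·St, P3 = Sd²·A, P4 = Sd·A·St, P5 = A·Aᵀ·A, P6 = A·St²). Because the
similarity diagonals are zero, the only node repeats a raw product can
count are *endpoint revisits at interior positions*, possible for P3
(first drug), P5 (either endpoint) and P6 (last target); these are
cancelled by inclusion–exclusion (e.g. Sum P5 = A Aᵀ A − A∘colsum(A²) −
A∘rowsum(A²) + A∘A²). Max scores use max-product semiring chaining with
the same exclusions, realised by zeroing the diagonal of intermediate
semiring products; for P5 the excluded index depends on the scored
column, which breaks associativity, so a per-column top-two masking
recovers the exact masked maximum in O(m·n²). Correctness of both routes
is defined by agreement (< 1e-9) with exhaustive depth-first enumeration
of simple paths, checked over randomised instances in the test suite and
the acceptance script.

`exclude_direct` (default true for training/evaluation features) removes
the pair's own edge (dᵢ, tⱼ) before scoring that pair, so a known
interaction is never scored through itself; for de-novo ranking of
unobserved pairs it is switched off. Under the strict simple-path rule
the direct edge cannot lie on any admissible 2–3-edge path between its
own endpoints (the target would have to appear twice), so both settings
provably coincide; the flag is kept for interface clarity and both
settings are exercised against the brute-force reference.

### Classification and labels

Known DTIs are positives (label 1); negatives (label 0) are drawn
uniformly without replacement from the zero cells of A, by default at a
1:1 ratio (the ratio is configurable; nothing in the method fixes it).
The default classifier is XGBoost with 500 trees, depth 6, learning rate
0.1, subsample 0.8, L2 = 1.0, single-threaded for determinism; random
forest and AdaBoost are available behind the same interface. Feature
merging defaults to concatenation [f(d); f(t); PSM₁₂]; a Hadamard variant
[f(d)∘f(t); PSM₁₂] is provided.

### Evaluation protocol

Labelled pairs are split, stratified by label, into 11 near-equal parts.
Parts 1–10 form a 10-fold cross-validation (train 9, test 1); part 11 is
an independent holdout scored by a model refit on parts 1–10. Metrics:
AUC (rank-based, midrank ties), AUPR as step-interpolated average
precision (chosen over trapezoidal PR interpolation as the less
optimistic convention), ER = 1 − AUPR, and ΔER = (ER₂ − ER₁)/ER₂. Fold
means and the holdout are reported separately.

**Embedding scope.** Training embeddings on the entire graph — including
the interactions a fold will be tested on — lets test-edge information
shape the feature space. Both protocols are implemented:
`embed_scope="per_fold"` (library default) re-generates walks, embeddings
and path scores for every fold with that fold's positive test edges
removed from the graph and from A; `embed_scope="full"` computes them
once on the complete graph, which matches the protocol the original tool
describes. The run log records which scope was used.

## Synthetic data

The generator emulates the *shape* of the benchmark inputs, not any real
dataset: drugs, targets and ncRNAs are assigned to k clusters
round-robin; a DTI edge is Bernoulli(p_within = 0.3) within a cluster and
Bernoulli(p_between = 0.02) across; similarities are 0.2 + 0.5·[same
cluster] + N(0, 0.1), clipped, symmetrised, unit diagonal; ncRNA layers
attach with density 0.05, boosted 4× within the ncRNA's latent cluster so
the satellite layers carry cluster signal (this is what makes the
integrating-vs-original network ablation measurable on synthetic data).
Defaults: 60 drugs, 50 targets, 20 lncRNAs, 20 miRNAs, 4 clusters —
small enough that the full pipeline cross-validates in well under a
minute per run, large enough for ~270 positives.

What passing tests on this generator do and do not show: edges are
conditionally independent given cluster membership, so *any* feature
computed without a pair's own edge carries at most cluster-level
information about that pair. Recovery of the planted structure therefore
demonstrates that embeddings and path scores extract the block signal,
but says nothing about degree heterogeneity, similarity spectra, or the
much lower positive rates of real interaction data. Under the leak-free
per-fold protocol the Bayes-optimal cross-validated AUPR on the default
configuration is roughly 0.75–0.80 (within-cluster pairs can be ranked
above between-cluster pairs, but positives and sampled negatives inside a
cluster are statistically identical); the full-graph protocol scores
higher (~0.87) precisely because embeddings see the test edges. The
planted-recovery acceptance check is therefore run under the full-graph
protocol, i.e. the original tool's own evaluation setup.

## Numerical choices and degenerate inputs

* Similarity matrices must be symmetric within 1e-6 with entries within
  1e-6 of [0, 1] and unit diagonal; sub-tolerance violations are clipped,
  anything larger is an error. Empty (0×0) matrices are valid.
* SNF: full kernel P by row normalisation with half the mass off-diagonal
  (P(i,i) = ½), sparse kernel S over the K nearest neighbours
  (K = 20, capped at n−1), t = 20 parallel updates
  P⁽ᵛ⁾ ← S⁽ᵛ⁾·mean(P⁽ᵘ⁾, u≠v)·S⁽ᵛ⁾ᵀ with symmetrisation each step, final
  average of the P⁽ᵛ⁾, then unit diagonal and min–max rescaling of the
  off-diagonals to [0, 1]. Inputs are used directly as affinities (they
  are already similarities); t = 0 degenerates to the mean of the
  normalised kernels. Isolated rows keep all mass on the diagonal.
  A single input matrix is passed through unchanged by every fusion
  method.
* Prediction tables sort by descending score with lexicographic
  (drug, target) tie-breaks, so output files are bit-stable.
* All randomness flows from one master seed; stage seeds (embedding,
  classifier, negative sampling) are derived arithmetically from it.
* Duplicate edges in input files are deduplicated with a logged warning;
  malformed lines fail with the line number.

## Known limitations

* The SGNS trainer is sequential by design (determinism over speed);
  embedding graphs beyond ~10⁴ nodes would want the asynchronous
  multi-worker formulation this package deliberately avoids.
* Meta-path scoring materialises dense n×m score matrices and an n×n×m
  intermediate for the P5 Max; fine for benchmark-scale networks,
  not for 10⁵-node graphs.
* No identifier namespace validation or cross-database conversion; inputs
  must already share one identifier space.
* The grid-search driver enumerates configurations but leaves the outer
  search loop to the caller.
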