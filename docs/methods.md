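# Methods

## Model and assumptions

`lncdlink` treats lncRNA–disease association prediction as link prediction
on a typed two-layer network. The working assumptions are:

* **Guilt by association.** lncRNAs associated with semantically similar
  diseases are functionally similar, and similar lncRNAs associate with
  similar diseases. This is what makes the fused similarity blocks SL/SD
  informative about missing links.
* **Ontology coherence.** Disease similarity is meaningful through shared
  ontology ancestors, with influence decaying geometrically per level
  (factor Δ). A disease absent from the ontology contributes only trivial
  self-similarity; the Gaussian interaction-profile (GIP) kernel then
  carries the signal.
* **Known associations are true; unknown pairs are a mixture.** The
  unknown-pair pool contains both true negatives and undiscovered positives,
  which is why negatives are *selected* (K-means cluster-proportional
  sampling) rather than taken uniformly, and why ranking quality (AUC,
  rank enrichment of held-out positives) is the primary readout.

## Stage-by-stage notes

### Semantic contributions (decay over the ancestor DAG)

The contribution of ancestor `u` to disease `i` is defined recursively —
the disease contributes 1 and each ancestor Δ times the maximum over the
nodes one hop closer to the disease. Evaluated by dynamic programming in
topological order of the child→parent DAG, this equals
`Δ^(shortest hop distance from i to u)`; the test suite checks it against
brute-force enumeration of all descending paths. Inputs with cycles are
rejected outright. Δ defaults to 0.5 (dimensionless, in (0,1)): halving per
level keeps grandparents relevant but distant ancestors negligible.

### Functional similarity edge cases

An lncRNA with an empty disease set would make the best-match average
0/0. Its functional similarity is defined as 0 off-diagonal (logged as a
warning), so the fusion rule substitutes the GIP kernel there; the fused
matrix's diagonal is forced to 1. The fusion zero-test is *structural*
(exact comparison with 0.0): a functional similarity entry is zero exactly
when the two disease sets share no semantic overlap, so no numeric
tolerance is appropriate.

### GIP kernel

Bandwidth δ = δ′ / (mean squared profile norm), δ′ = 1 (dimensionless).
An all-zero association matrix leaves δ undefined and is rejected. Pairwise
squared distances are computed by the norm expansion and symmetrised
explicitly to keep the matrix symmetric to the 1e-10 tolerance the
containers enforce.

### Network sparsification and the metagraph

The similarity blocks are dense, but the walk model is uniform over
neighbours, i.e. edges are unweighted. Each node therefore keeps walkable
same-type edges only to its `top_k` (default 10) most similar neighbours
with strictly positive similarity, symmetrised by union (ties broken by
node index, so assembly is deterministic). Association edges are used
exactly as given.

The default metagraph is the four-node diamond `L1→D1`, `D1→L2`, `D1→D2`,
`D2→L2` (source `L1`, target `L2`): the union of the lncRNA–disease–lncRNA
and lncRNA–disease–disease–lncRNA metapaths. The branch at `D1` is the point
of using a meta*graph* — at a disease node the walk may either return to the
lncRNA layer or first move within the disease layer. On reaching the target
the schema restarts at the source, so walks are long alternations rather
than single schema instances. Users can supply any acyclic typed schema via
a small text format (`node`/`edge`/`source`/`target` lines).

Each step samples uniformly among the admissible edge *types* (those with
at least one realisation at the current node), then uniformly among the
neighbours of the chosen type; the walk ends when no type is admissible or
at the length cap L (default 80, with 10 walks per source-type node —
conventional sizes for walk-based embedding of networks with a few hundred
nodes). If a schema position offered the same edge type toward two schema
destinations, the destination is drawn uniformly; the node-level transition
law is unaffected.

### Heterogeneous skip-gram

Every ordered pair within a window of b = 5 positions is a training
example. The objective is the standard sampled softmax except that the
U = 5 negatives are drawn from nodes *of the context node's type*
(unigram^0.75 noise within type by default; uniform available). Training is
SGD with learning rate decaying linearly 0.025 → 1e-4 over all updates,
5 epochs, Ψ initialised uniform(−0.5/d, 0.5/d), Φ at zero, d = 64. The
inner loop is a numba kernel; a single-pair numpy reference path carries
identical arithmetic and is finite-difference-checked. All sampling flows
from one seeded generator and pairs are visited in corpus order, so
training is reproducible bit for bit. The per-epoch mean pre-update loss is
recorded; with the decaying rate it is non-increasing across epochs up to
the noise of fresh negative draws.

### K-means negative selection

Lloyd's algorithm with initial centers drawn from the points, run to
assignment fixpoint or 300 iterations, best objective of 10 restarts. An
emptied cluster is re-seeded deterministically from the point farthest from
its centroid. k = 10 clusters over all unknown pairs. Negatives are
allocated proportionally to cluster size with largest-remainder rounding
(ties to the lower cluster id; quotas capped by cluster size with overflow
pushed to clusters with room) and drawn uniformly without replacement
within a cluster — preserving the cluster mass of the unknown pool, which
is the point of clustering in the first place. Equal-per-cluster allocation
is available as a config alternative. Whether negatives should instead be
taken near or far from centroids is genuinely open; uniform-within-cluster
is the assumption-light choice.

### Classifier cascade

Labels are {0,1} externally and mapped to {−1,+1} inside the boosting
stage. The initial score `½·log(pos/neg)` is half the conventional
log-odds; it is kept as stated (the factor only rescales the starting point
and the trees absorb it). CART split search is exhaustive
variance-reduction on residuals with deterministic tie-breaking (lowest
feature index, then lowest threshold; thresholds are midpoints between
consecutive distinct values). Defaults: T = 100 trees, depth ≤ 3,
shrinkage α = 0.1, ≥ 5 samples per leaf.

Leaf values use the single-Newton-step form `Σr / Σ|r|(2−|r|)` rather than
exact per-leaf minimisation of the log-loss. The exact argmin is unbounded
on leaves whose residuals all share a sign (any well-fit tree produces
such leaves), so one damped step is the *stable* choice, not merely a fast
one; it never overshoots. Quantitatively, the step is within 0.15 of the
exact minimiser only where the optimal step is itself small (|c*| ≲ 0.15,
the late-boosting regime) — on sign-pure or strongly skewed leaves it
deliberately undershoots. With shrinkage this costs rounds, not accuracy;
the training-loss monotonicity test covers the property that matters.

The logistic head sees only the leaf codes (dimension Σ_t N_t + intercept),
trained by full-batch gradient descent with step size 1/L, L the spectral
bound of the design matrix (power iteration) over 4m plus the L2 strength
(1e-4, needed because leaf codes are often separable). Descent is therefore
monotone; it stops at gradient norm < 1e-6 or 3000 steps.

Classifier input per pair is the **Hadamard product** of the two node
embeddings. The alternative, concatenation, was measured substantially
worse here (planted world, identical everything else: mean CV AUC 0.825 vs
0.915): axis-aligned tree splits cannot express the inner-product affinity
the skip-gram optimises, while the elementwise product exposes it
coordinate by coordinate. `pair_features: concat` switches back.

### Evaluation

Stratified k-fold (default 10) is a shuffle-within-class round-robin deal,
which keeps both overall fold sizes and per-class counts within one of each
other. Metrics use a 0.5 decision threshold; a metric with a zero
denominator is reported as NaN with a warning. AUC is the trapezoidal sweep
(identical to Mann–Whitney pair counting with ties at one half — asserted
exactly in tests); the mean ROC is vertically averaged on a common
false-positive-rate grid. By default embeddings and negative selection are
computed once on the full network and only the labelled pairs are split:
that matches the pipeline's stage order, but test positives then influence
their own fold's features through the network. `strict_cv: true` recomputes
similarities, embeddings and features per fold with the fold's positives
masked; it is ~10× slower and measurably harder, and is the mode to use
when absolute leakage-freedom matters more than comparability.

## The synthetic world

The generator plants B communities (default 4) over 112 lncRNAs × 150
diseases (the shape of the smallest real catalogue release), samples
associations at p_in = 0.3 within and p_out = 0.02 across communities, and
removes 20% of the sampled links as recoverable ground truth *before* any
stage sees the matrix. The ontology forest gives each community one root,
two mid-level and three low-level terms; each disease attaches to 0–3 terms,
80% of draws staying in-community (depth ≤ 4), so semantic similarity
acquires the same block structure as the associations.

What it emulates: the community/block correlation between association
profiles and ontology neighbourhoods that every stage of the method relies
on. What it does not: power-law degree distributions, the deep and uneven
topology of real disease ontologies, annotation biases (well-studied
diseases have more links), or label noise. Passing the end-to-end tests
therefore demonstrates that the machinery recovers structure it is designed
for at realistic scale — not a clinical performance claim on real
catalogues, whose headline numbers also depend on curation choices outside
this package.

## Numerical conventions

* Similarity containers enforce symmetry to 1e-10, entries in [0,1] (with
  clipping only of sub-tolerance float overshoot) and unit diagonals where
  the role requires them.
* All randomness flows from one master seed through fixed-index
  `SeedSequence` stage sub-seeds (`world`, `walks`, `embedding`, `kmeans`,
  `negatives`, `cv`), each < 2³¹; reruns are byte-identical, and the
  resolved configuration plus the derived seeds are written next to every
  output directory.
* Model persistence is JSON of the tree arrays, initial score, shrinkage
  and head weights; Python's float round-trip guarantees bit-exact reload.
* Degenerate inputs fail loudly: cyclic ontologies, all-zero association
  matrices, single-class training labels, oversized negative requests and
  unknown config keys are all rejected with specific messages.

## Limitations

* The walk model is unweighted; similarity magnitudes influence only the
  top-k edge selection, not transition probabilities.
* Skip-gram training is single-threaded SGD; adequate for networks of a
  few hundred nodes, not engineered for 10⁵-node graphs.
* The default CV protocol shares embeddings across folds (see above).
* Negative "truth" does not exist in this domain; reported accuracy-type
  metrics are relative to the selected negative set, and ranking metrics
  should be preferred when comparing methods.
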