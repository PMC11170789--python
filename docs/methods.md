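# Methods

## Problem

Given two undirected multilayer networks `G1` and `G2` with the same
number of layers, score how similar each node of `G1` is to each node of
`G2` **on the same layer**. Layers hold heterogeneous entity types
(e.g. genes on one layer, diseases on another), so cross-layer
comparisons are meaningless by construction and are never produced: a
gene is not comparable to a disease, whatever their wiring. The output
is a layer-blocked similarity matrix with entries in [0, 1], from which
downstream tasks (network alignment, counterpart classification) are
derived.

A multilayer network is `G_M = (V_M, E_M)` with the edge set split into
intralayer edges `E_a` (both endpoints on one layer) and interlayer
edges `E_b = E_M \ E_a` (endpoints on two distinct layers). Input is a
set of tuples `(u, v, l)` — an edge list where `l` is either a layer
label or a layer-pair designation. Node identity is `(name, layer)`:
the same name on two layers denotes two distinct nodes.

## Pipeline

1. **Preprocessing** (`preprocess`). The network is split into per-layer
   subgraph views; every interlayer edge is attached to the views of
   *both* endpoint layers so that no information is lost in the split.
   Each node receives a purely topological initial feature vector
   (below), and the whole network is assembled into a dense batch: a
   feature matrix plus a directed edge index with both orientations of
   every undirected edge, rows sorted by (layer position, node name) for
   reproducibility.

2. **GIN embedding** (`gin`). A Graph Isomorphism Network computes one
   embedding per node by iterated aggregation

       h_v^(k) = MLP_k( (1 + eps_k) * h_v^(k-1) + sum_{u in N(v)} h_u^(k-1) )

   where each MLP is linear–ReLU–linear and `eps_k` is a per-step
   scalar (0 by default). The stack is `conv1` (input width to hidden),
   one intermediate step per layer of the multilayer network (`convs`),
   and `conv2` (hidden to output); the embedding of a node is the output
   of the final step, so the number of aggregation iterations is
   `K = 2 + n_layers`. Both networks are embedded with the *same*
   parameters — that is what makes the embeddings comparable across
   networks.

3. **Similarity** (`simscore`). Same-layer cross-network node pairs are
   scored with the weighted (Ruzicka) Jaccard coefficient
   `sum_i min(a_i, b_i) / sum_i max(a_i, b_i)`, the only Jaccard form on
   real vectors that reduces to the classical intersection-over-union on
   binary vectors. Layer correspondence is positional (layer i of the
   source pairs with layer i of the target); label-based pairing is
   available by option.

4. **Alignment and evaluation** (`alignval`). A node mapping is read off
   the similarity matrix per layer, by maximum-weight bipartite matching
   (Hungarian algorithm, the default) or greedily; ties break by
   (source name, target name). Node Correctness (NC) is the fraction of
   mapped nodes whose image equals the known counterpart. The
   classification view labels a pair positive iff it is a true
   counterpart pair and predicts positive iff its similarity is at least
   0.95; accuracy, AUC (tie-corrected rank statistic), sensitivity,
   specificity, precision and F1 follow.

## No training

No loss function is attached to the GIN: it is used as a *seeded,
randomly initialized* structural feature extractor. With continuous
random weights, nodes whose neighbourhoods the 1-WL colour refinement
can distinguish at depth K receive distinct embeddings (and
WL-indistinguishable nodes provably receive identical ones), so the
architecture's discriminative power for isomorphism-style distinctions
does not depend on task training. Externally trained parameters can be
loaded through the JSON parameter round-trip in `gin`.

## Initial features

Only topology is used, so the construction must be name-free and
comparable across networks. With `d` channels (default 64):

* slot 0: own degree divided by the network's maximum degree;
* slots 1..d-1: histogram of the node's neighbour degrees over `d-1`
  logarithmically spaced bins covering `[1, max_degree]`;
* the row is L2-normalized; all-zero rows (isolated nodes) stay zero.

Degrees are taken in the flattened network (intralayer plus interlayer
edges), so interlayer-attached nodes carry their cross-layer context.
Two nodes with equal degree and equal neighbour-degree multisets get
identical rows, which is exactly the granularity the first WL iteration
sees. Any alternative featurizer can be plugged in by constructing a
`FeatureMatrix` directly. Biological node attributes could in principle
serve as initial features; this package deliberately uses topology only.

## Numerical design choices

These matter because the model is untrained; each was selected by
measuring alignment quality on the synthetic benchmark during
development.

* **Orthogonal weight init.** MLP weight matrices are (semi-)orthogonal
  (SVD of a Gaussian draw from a Philox counter-based stream keyed by
  the seed; biases 0). Compositions of generic random matrices with
  ReLU progressively collapse representations toward a dominant
  direction, which blurs exactly the per-node distinctions the
  similarity step needs; orthogonal maps are norm-preserving and keep
  the stack's output discriminative. Under the benchmark's
  noise-degradation protocol this raised mean NC at 5% noise from ~0.17
  to ~0.21 relative to scaled-uniform init.
* **Inter-step row normalization.** Sum aggregation on dense graphs
  multiplies magnitudes by roughly the mean degree per step; states are
  L2-normalized row-wise between steps (the final output is left
  untouched). Equal rows stay equal, so WL-equivalence properties are
  unaffected.
* **Signed decomposition before scoring.** The weighted Jaccard is
  defined on non-negative vectors; embeddings are roughly zero-centred,
  and simply clipping negatives discards half the signal. Each
  embedding is decomposed as `[max(x,0), max(-x,0)]` before scoring.
  On non-negative vectors this is the identity (up to zero padding), and
  the reduction to set Jaccard on binary vectors is preserved. Together
  with the two choices above, mean NC at 5% noise under the degradation
  protocol is ~0.24.
* **Both-zero convention.** Two all-zero rectified vectors score 1.0:
  they belong to structurally identical (isolated) nodes. Configurable
  via `empty_value`.
* **Zero-denominator KPIs** are reported as 0 with a warning rather than
  NaN; AUC is omitted (with a warning) when labels are degenerate.
* **Interlayer edges between non-consecutive layers** are accepted with
  a logged warning rather than rejected; layer adjacency is positional.

## Synthetic benchmark

The generator (`benchgen`) emulates the kind of heterogeneous two-layer
disease–gene networks the method targets, at desk scale:

* **Layers**: extended preferential attachment (Albert–Barabási) with
  `n = 50` nodes, `m = 2` attachment edges, extra-edge probability
  `p = 0.5`, rewiring probability `q = 0.4` (requires `p + q < 1`).
  This parameter set avoids high-density clusters while keeping degree
  structure close to real biological interaction networks. The
  `networkx` implementation of the process is used directly. At
  `p = q = 0` the process degenerates to plain preferential attachment
  with exactly `m(n-m)` edges, which the tests use as a closed-form
  anchor.
* **Interlayer wiring**: `z`% of `n` (default 10%, i.e. 5 edges for
  `n = 50`) uniformly random distinct cross-layer pairs between each
  consecutive layer pair.
* **Noise**: a noisy copy shuffles a fraction (5–25%) of *all* edges:
  each selected edge is deleted and replaced by a uniformly random new
  edge of the same class (same layer, or same layer pair), avoiding
  self-loops, duplicates and the original edge set — so edge counts,
  the intra/inter split and the node set are all conserved and exactly
  the selected edges differ. The ground-truth node mapping between a
  network and its noisy copy is therefore the identity.
* **Suite**: 10 base networks with one noisy copy at each of 5 noise
  levels — 50 evaluation samples over 60 distinct networks, a pure
  function of the seed.

What the generator does **not** emulate: real degree-distribution
heterogeneity across layers (both layers are drawn from the same
process), community structure, biological edge semantics, and the much
larger node counts of real disease–gene maps. Passing benchmarks here
demonstrates correctness and qualitative noise behaviour of the
pipeline, not field performance on real data.

## Evaluation scales

The bundled evaluation (tests and `scripts/acceptance.py`) runs the
noise-degradation protocol at 5 base networks × 5 noise levels (with 3
model/generation seeds in the test suite), at the default generator
parameters. An untrained extractor on these dense synthetic networks
reaches mean NC ≈ 0.21–0.27 at 5% noise — an order of magnitude above
the 1/n = 0.02 random-mapping expectation — decaying toward ≈ 0.06 at
25% noise, the qualitative signature expected of a topology-only
method. Counterpart similarities rarely clear the 0.95 classification
threshold at nonzero noise, so pooled sensitivity is typically 0 while
specificity and accuracy stay near 1 and AUC near 0.7: the threshold
view is most informative near-zero noise or with trained parameters.

## Known limitations

* No training objective: discriminative power is whatever random
  orthogonal projections preserve; a trained model would be strictly
  better calibrated, and the 0.95 threshold only becomes a sensitive
  classifier under one.
* WL-equivalent nodes are inherently indistinguishable; on highly
  symmetric graphs the alignment can only tie-break lexically.
* Edge lists cannot carry isolated nodes; in-memory construction can.
* Undirected, unweighted edges only.
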