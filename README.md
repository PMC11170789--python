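# mulsim

Cross-network node similarity for multilayer biological networks.

Biological systems are increasingly modelled as *multilayer* networks:
node sets partitioned into layers of distinct entity types (genes,
diseases, drugs), with intralayer edges inside each layer and interlayer
edges connecting layers. Comparing two such networks node-by-node — how
similar is gene *u* of network 1 to gene *w* of network 2? — underlies
network alignment, cross-cohort comparison and knowledge transfer, but
most node-similarity methods only work *within* one network. `mulsim`
scores node pairs **across** two different multilayer networks while
respecting the layered structure: heterogeneous entities are never
compared (a gene is not similar to a disease, whatever its wiring).

## Method

For `G_M = (V_M, E_M)` the edge set splits into intralayer edges `E_a`
and interlayer edges `E_b = E_M \ E_a`. Given `G1`, `G2` with the same
number of layers:

1. every node gets a topology-only initial feature vector `h_v^(0)`
   (own degree + neighbour-degree histogram, 64 channels by default);
2. a shared Graph Isomorphism Network computes embeddings by iterating

   `h_v^(k) = MLP_k((1 + ε_k)·h_v^(k-1) + Σ_{u∈N(v)} h_u^(k-1))`,

   with a linear–ReLU–linear MLP per step and one intermediate step per
   network layer; the final step's output is the node embedding;
3. same-layer cross-network pairs are scored with the weighted Jaccard
   coefficient `Σ min(a_i,b_i) / Σ max(a_i,b_i) ∈ [0, 1]`.

On top of the similarity matrix the package provides maximum-weight
bipartite matching (node mapping), Node Correctness against a known
ground truth, threshold classification KPIs, and a synthetic multilayer
benchmark generator (extended preferential-attachment layers, random
interlayer wiring, class-preserving edge-shuffling noise with identity
ground truth). See `docs/methods.md` for assumptions, parameter
choices and limitations.

## Worked example

```python
import numpy as np
from mulsim import benchgen
from mulsim.alignval import node_correctness
from mulsim.estimators import PairwiseNodeSimilarity

rng = np.random.default_rng(0)
net = benchgen.gen_multilayer(benchgen.GenParams(), rng)   # 2 layers, 50 nodes each
sample = benchgen.perturb(net, 0.05, rng)                  # shuffle 5% of edges

est = PairwiseNodeSimilarity(random_state=0).fit((net, sample.target))
block = est.similarity_.block_for("L1")
print("block shape:", block.values.shape)
print("sim(n0@L1, n0@L1) =", round(block.values[0, 0], 3))
print("row max =", round(block.values[0].max(), 3))
print("node correctness at 5% noise:",
      node_correctness(est.predict(), sample.truth))
```

prints

```
block shape: (50, 50)
sim(n0@L1, n0@L1) = 0.547
row max = 0.549
node correctness at 5% noise: 0.19
```

Each layer yields a 50×50 block of similarities in [0, 1]. Node `n0`'s
true counterpart scores 0.547, essentially at its row maximum — the
noisy copy moved a competing node marginally above it. Matching the
whole block recovers 19% of true counterparts at 5% noise, roughly ten
times the 1/50 = 0.02 expectation of a random mapping; with an exact
copy (noise 0) recovery is 100%.

The same pipeline is available from the shell:

```sh
mulsim generate --num-base 2 --noise 5,10 --out suite/
mulsim similarity --source suite/base00.tsv --target suite/base00_noise05.tsv --out run/
mulsim align --matrix run/similarity.tsv --method matching --out mapping.tsv
mulsim evaluate --suite suite/ --out eval/
```

Networks are 3-column TSV edge lists `u v layer` (interlayer rows use
`layer1-layer2`); similarities are TSV with a
`source target layer similarity` header.

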