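"""Synthetic multilayer benchmark generator with ground-truth mappings.

Each layer is grown by the extended preferential-attachment process of
Albert & Barabási: at every step, with probability ``p`` m new edges are
added between existing nodes, with probability ``q`` m existing edges are
rewired, and otherwise a new node attaches preferentially with m edges
(requires p + q < 1).  The parameter set n=50, m=2, p=0.5, q=0.4 is used
as the default: it avoids high-density clusters while keeping the degree
structure close to real biological interaction networks.  Consecutive
layers are connected by ``z``% (of n) uniformly random interlayer edges.

Noisy copies are produced by "shuffling" a fixed fraction of all edges:
each selected edge (intralayer or interlayer alike) is deleted and
replaced by a new uniformly random edge of the same class — same layer
for intralayer edges, same layer pair for interlayer ones — avoiding
self-loops and duplicates, so edge counts and the intra/inter split are
conserved and the node set is unchanged.  Because the node set is shared,
the ground-truth mapping between a network and its noisy copy is the
identity.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .alignval import NodeMapping
from .netio import MultilayerNetwork, NodeRef

__all__ = [
    "GenParams",
    "BenchmarkSample",
    "gen_layer",
    "gen_multilayer",
    "perturb",
    "build_suite",
    "DEFAULT_NOISE_LEVELS",
]

DEFAULT_NOISE_LEVELS = (0.05, 0.10, 0.15, 0.20, 0.25)


@dataclass(frozen=True)
class GenParams:
    """Generator parameters; defaults are the benchmark's study conditions."""

    n_layers: int = 2
    n: int = 50          # nodes per layer
    m: int = 2           # attachment edges per new node
    p: float = 0.5       # probability of adding m extra edges per step
    q: float = 0.4       # probability of rewiring m edges per step
    z: float = 10.0      # interlayer edges per consecutive layer pair, % of n
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p + self.q >= 1.0:
            raise ValueError("extended preferential attachment requires p + q < 1")
        if not self.n > self.m >= 1:
            raise ValueError("need n > m >= 1")
        if self.z < 0:
            raise ValueError("z must be non-negative")
        if self.n_layers < 1:
            raise ValueError("need at least one layer")


@dataclass
class BenchmarkSample:
    """A source network, its noisy copy, and the identity ground truth."""

    source: MultilayerNetwork
    target: MultilayerNetwork
    truth: NodeMapping
    noise_level: float
    base_id: int = 0


def _rng_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def gen_layer(n: int, m: int, p: float, q: float, rng: np.random.Generator) -> nx.Graph:
    """One layer via the extended preferential-attachment process."""
    if p + q >= 1.0:
        raise ValueError("extended preferential attachment requires p + q < 1")
    # networkx consumes legacy RandomState seeds deterministically; derive one
    return nx.extended_barabasi_albert_graph(n, m, p, q, seed=_rng_seed(rng))


def gen_multilayer(params: GenParams, rng: np.random.Generator) -> MultilayerNetwork:
    """Independent layers plus z%·n random interlayer edges per adjacent pair."""
    n_inter = round(params.z / 100.0 * params.n)
    if n_inter > params.n * params.n:
        raise ValueError("requested more interlayer edges than distinct node pairs")
    layers = []
    for li in range(params.n_layers):
        g = gen_layer(params.n, params.m, params.p, params.q, rng)
        label = f"L{li + 1}"
        layers.append(
            (label, [f"n{v}" for v in g.nodes], [(f"n{u}", f"n{v}") for u, v in g.edges])
        )
    net = MultilayerNetwork()
    for label, nodes, edges in layers:
        net.add_layer(label)
        for name in nodes:
            net.add_node(name, label)
        for u, v in edges:
            net.add_intra_edge(u, v, label)
    for li in range(params.n_layers - 1):
        lab_a, lab_b = f"L{li + 1}", f"L{li + 2}"
        chosen: set[tuple[int, int]] = set()
        while len(chosen) < n_inter:
            a = int(rng.integers(params.n))
            b = int(rng.integers(params.n))
            chosen.add((a, b))
        for a, b in sorted(chosen):
            net.add_inter_edge(f"n{a}", lab_a, f"n{b}", lab_b)
    net.validate()
    return net


def _edge_class(net: MultilayerNetwork, edge) -> tuple[str, ...]:
    u, v = edge
    return (u.layer,) if u.layer == v.layer else tuple(sorted((u.layer, v.layer)))


def perturb(
    network: MultilayerNetwork, fraction: float, rng: np.random.Generator
) -> BenchmarkSample:
    """Noisy copy: delete-and-rewire ``floor(fraction·|E|)`` random edges.

    Replacements stay within the class of the deleted edge and avoid the
    entire original edge set plus earlier replacements, so exactly the
    selected edges differ between source and target.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    all_edges = sorted(network.all_edges())
    k = math.floor(fraction * len(all_edges))
    selected_idx = rng.choice(len(all_edges), size=k, replace=False) if k else []
    selected = {all_edges[int(i)] for i in selected_idx}
    original = set(all_edges)

    target = MultilayerNetwork()
    for layer in network.layer_order:
        target.add_layer(layer)
    for node in network.nodes:
        target.add_node(node.name, node.layer)
    for layer, edges in network.intra_edges.items():
        for u, v in edges - selected:
            target.add_intra_edge(u.name, v.name, layer)
    for u, v in network.inter_edges - selected:
        target.add_inter_edge(u.name, u.layer, v.name, v.layer)

    layer_members = {
        layer: sorted(n for n in network.nodes if n.layer == layer)
        for layer in network.layer_order
    }
    forbidden = set(original)
    for edge in sorted(selected):
        cls = _edge_class(network, edge)
        if len(cls) == 1:
            pool = layer_members[cls[0]]
            pools = (pool, pool)
            capacity = len(pool) * (len(pool) - 1) // 2
        else:
            pools = (layer_members[cls[0]], layer_members[cls[1]])
            capacity = len(pools[0]) * len(pools[1])
        placed = False
        for _ in range(200 * max(capacity, 1)):
            a = pools[0][int(rng.integers(len(pools[0])))]
            b = pools[1][int(rng.integers(len(pools[1])))]
            if a == b:
                continue
            cand = (a, b) if a <= b else (b, a)
            if cand in forbidden:
                continue
            forbidden.add(cand)
            if len(cls) == 1:
                target.add_intra_edge(a.name, b.name, cls[0])
            else:
                target.add_inter_edge(a.name, a.layer, b.name, b.layer)
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"replacement pool exhausted for edge class {cls} "
                f"(capacity {capacity}, forbidden {len(forbidden)})"
            )
    target.validate()
    truth = NodeMapping(pairs={node: node for node in sorted(network.nodes)})
    return BenchmarkSample(
        source=network,
        target=target,
        truth=truth,
        noise_level=fraction,
    )


def build_suite(
    num_base: int = 10,
    noise_levels=DEFAULT_NOISE_LEVELS,
    params: GenParams = GenParams(),
    seed: int = 0,
) -> list[BenchmarkSample]:
    """``num_base`` base networks, one noisy copy per level.

    The defaults (10 bases, 5 levels) yield 50 samples built from
    10 + 50 = 60 distinct networks, fully reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    samples: list[BenchmarkSample] = []
    for b in range(num_base):
        base = gen_multilayer(dataclasses.replace(params, seed=seed), rng)
        for level in sorted(noise_levels):
            sample = perturb(base, level, rng)
            sample.base_id = b
            samples.append(sample)
    return samples
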