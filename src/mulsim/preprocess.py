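"""Turn a multilayer network into a message-passing-ready batch.

Three steps: (1) split the network into per-layer views, duplicating each
interlayer edge into the views of both endpoint layers so no information
is lost; (2) assign every node a purely topological initial feature vector
(own degree plus a histogram of neighbour degrees), so that features are
comparable across two different networks without any shared node naming;
(3) assemble a dense feature matrix and a directed edge index (both
orientations per undirected edge) with deterministic row ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .netio import Edge, MultilayerNetwork, NodeRef

__all__ = [
    "LayerView",
    "FeatureMatrix",
    "GraphBatch",
    "split_layers",
    "initial_features",
    "build_batch",
    "prepare",
]

DEFAULT_CHANNELS = 64


@dataclass
class LayerView:
    """A single layer as a subgraph, with interlayer edges attached.

    ``attached_nodes`` are foreign nodes pulled in by interlayer edges:
    an interlayer edge between layers i and j appears in both views, so
    relationships across layers survive the split.
    """

    layer: str
    member_nodes: set[NodeRef]
    attached_nodes: set[NodeRef] = field(default_factory=set)
    edges: set[Edge] = field(default_factory=set)


def split_layers(network: MultilayerNetwork) -> list[LayerView]:
    """One view per layer, in layer order; interlayer edges duplicated."""
    views = {
        layer: LayerView(
            layer=layer,
            member_nodes={n for n in network.nodes if n.layer == layer},
            edges=set(network.intra_edges[layer]),
        )
        for layer in network.layer_order
    }
    for u, v in network.inter_edges:
        for here, there in ((u, v), (v, u)):
            view = views[here.layer]
            view.edges.add((u, v) if u <= v else (v, u))
            view.attached_nodes.add(there)
    return [views[layer] for layer in network.layer_order]


@dataclass
class FeatureMatrix:
    """Initial node features: ``values`` is ``len(node_order) x d``."""

    node_order: list[NodeRef]
    d: int
    values: np.ndarray

    def row(self, node: NodeRef) -> np.ndarray:
        return self.values[self.node_order.index(node)]


def _node_order(network: MultilayerNetwork) -> list[NodeRef]:
    """Stable ordering: (layer position, node name)."""
    pos = {layer: i for i, layer in enumerate(network.layer_order)}
    return sorted(network.nodes, key=lambda n: (pos[n.layer], n.name))


def initial_features(
    network: MultilayerNetwork, d: int = DEFAULT_CHANNELS
) -> FeatureMatrix:
    """Topology-only initial features with ``d`` channels.

    Slot 0 holds the node's own degree divided by the network maximum
    degree; slots ``1..d-1`` hold a histogram of its neighbours' degrees
    over ``d-1`` logarithmically spaced bins covering ``[1, max_degree]``.
    Rows are L2-normalized (all-zero rows — isolated nodes — stay zero).
    The construction depends only on local topology, never on node names,
    so features are comparable across networks.
    """
    if d < 2:
        raise ValueError(f"channel count must be >= 2, got {d}")
    order = _node_order(network)
    values = np.zeros((len(order), d), dtype=np.float64)
    if not order:
        return FeatureMatrix(order, d, values)

    deg = network.degree()
    adj = network.neighbours()
    max_deg = max(deg.values(), default=0)
    if max_deg == 0:  # edgeless network: all-zero features by convention
        return FeatureMatrix(order, d, values)

    # log-spaced bin edges over [1, max_deg]; n_bins = d-1
    edges = np.geomspace(1.0, max_deg + 1.0, num=d) if max_deg > 1 else None
    for i, node in enumerate(order):
        k = deg[node]
        if k == 0:
            continue
        values[i, 0] = k / max_deg
        for nb in adj[node]:
            nd = deg[nb]
            if edges is None:
                b = 0
            else:
                b = int(np.searchsorted(edges, nd, side="right")) - 1
                b = min(max(b, 0), d - 2)
            values[i, 1 + b] += 1.0
        norm = np.linalg.norm(values[i])
        if norm > 0:
            values[i] /= norm
    return FeatureMatrix(order, d, values)


@dataclass
class GraphBatch:
    """Dense arrays ready for message passing.

    ``edge_index`` is shaped ``(2, 2|E|)``: each undirected edge
    contributes both directed orientations.  ``inter_mask`` flags the
    columns that came from interlayer edges.  ``layer_partition`` maps
    each row to its native layer label.
    """

    node_order: list[NodeRef]
    node_index: dict[NodeRef, int]
    features: np.ndarray
    edge_index: np.ndarray
    inter_mask: np.ndarray
    layer_partition: list[str]

    @property
    def n_nodes(self) -> int:
        return len(self.node_order)

    def undirected_edges(self) -> set[Edge]:
        """Recover the multiset of undirected edges (for conservation checks)."""
        out: set[Edge] = set()
        for s, t in self.edge_index.T:
            u, v = self.node_order[s], self.node_order[t]
            out.add((u, v) if u <= v else (v, u))
        return out


def build_batch(network: MultilayerNetwork, features: FeatureMatrix) -> GraphBatch:
    """Assemble the directed edge index and feature array for one network."""
    order = _node_order(network)
    if set(features.node_order) != set(network.nodes):
        raise ValueError("feature matrix does not cover the network's node set")
    # re-index features into canonical order
    feat_pos = {n: i for i, n in enumerate(features.node_order)}
    values = features.values[[feat_pos[n] for n in order]]
    index = {n: i for i, n in enumerate(order)}

    src: list[int] = []
    dst: list[int] = []
    flags: list[bool] = []
    for layer in network.layer_order:
        for u, v in sorted(network.intra_edges[layer]):
            src += [index[u], index[v]]
            dst += [index[v], index[u]]
            flags += [False, False]
    for u, v in sorted(network.inter_edges):
        src += [index[u], index[v]]
        dst += [index[v], index[u]]
        flags += [True, True]

    edge_index = np.array([src, dst], dtype=np.int64).reshape(2, -1)
    return GraphBatch(
        node_order=order,
        node_index=index,
        features=values,
        edge_index=edge_index,
        inter_mask=np.array(flags, dtype=bool),
        layer_partition=[n.layer for n in order],
    )


def prepare(
    network: MultilayerNetwork, d: int = DEFAULT_CHANNELS
) -> GraphBatch:
    """Convenience: features + batch in one call."""
    return build_batch(network, initial_features(network, d))
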