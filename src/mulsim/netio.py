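"""Multilayer-network data model and edge-list / similarity-matrix I/O.

A multilayer network is a node set partitioned into ordered layers, with
undirected intralayer edges (both endpoints on the same layer) and
undirected interlayer edges (endpoints on two distinct layers).  The
on-disk carrier is a 3-column TSV dialect ``u<TAB>v<TAB>layer_spec`` where
``layer_spec`` is a bare layer label for intralayer edges and a
``L1-L2`` pair for interlayer edges.  A 4th ``edge_type`` column
(``intralayer``/``interlayer``) is accepted on read and ignored on the
intralayer/interlayer decision, which is always derived from
``layer_spec`` itself.

Because the carrier is a pure edge list, isolated nodes are not
representable on disk; read/write round-trips are exact for every
network whose nodes all have at least one incident edge.  In-memory
construction (:func:`from_layer_graphs`) has no such restriction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "NodeRef",
    "MultilayerNetwork",
    "MalformedEdgeError",
    "NetworkValidationError",
    "read_edge_list",
    "from_layer_graphs",
    "write_edge_list",
    "write_similarity",
    "read_similarity",
]


class MalformedEdgeError(ValueError):
    """A row of an edge-list file could not be parsed."""


class NetworkValidationError(ValueError):
    """A structural invariant of the multilayer model is violated."""


@dataclass(frozen=True, order=True)
class NodeRef:
    """A node identified by ``(name, layer)``.

    The same name on two different layers denotes two distinct nodes:
    heterogeneous layers hold different entity types (e.g. genes on one
    layer, diseases on another), so identity must be layer-qualified.
    """

    name: str
    layer: str


Edge = tuple[NodeRef, NodeRef]


def _canonical(u: NodeRef, v: NodeRef) -> Edge:
    """Canonical ordering of an undirected edge."""
    return (u, v) if u <= v else (v, u)


@dataclass
class MultilayerNetwork:
    """Ordered layers plus per-layer intralayer edge sets and interlayer edges.

    Invariants (enforced by :meth:`validate`):

    * every intralayer edge joins two nodes on the same layer;
    * every interlayer edge joins nodes on two distinct layers;
    * no self-loops; all edges are undirected (stored canonically);
    * every edge endpoint is a member of ``nodes``.
    """

    layer_order: list[str] = field(default_factory=list)
    nodes: set[NodeRef] = field(default_factory=set)
    intra_edges: dict[str, set[Edge]] = field(default_factory=dict)
    inter_edges: set[Edge] = field(default_factory=set)

    # -- construction helpers -------------------------------------------------

    def add_layer(self, layer: str) -> None:
        if layer not in self.intra_edges:
            self.layer_order.append(layer)
            self.intra_edges[layer] = set()

    def add_node(self, name: str, layer: str) -> NodeRef:
        if layer not in self.intra_edges:
            self.add_layer(layer)
        ref = NodeRef(name, layer)
        self.nodes.add(ref)
        return ref

    def add_intra_edge(self, u: str, v: str, layer: str) -> None:
        if u == v:
            raise NetworkValidationError(
                f"self-loop {u!r} on layer {layer!r} is not allowed"
            )
        a = self.add_node(u, layer)
        b = self.add_node(v, layer)
        self.intra_edges[layer].add(_canonical(a, b))

    def add_inter_edge(self, u: str, layer_u: str, v: str, layer_v: str) -> None:
        if layer_u == layer_v:
            raise NetworkValidationError(
                f"interlayer edge requires two distinct layers, got {layer_u!r}"
            )
        for lay in (layer_u, layer_v):
            if lay not in self.intra_edges:
                raise NetworkValidationError(
                    f"interlayer edge references unknown layer {lay!r}"
                )
        a = self.add_node(u, layer_u)
        b = self.add_node(v, layer_v)
        edge = _canonical(a, b)
        if not _adjacent(self.layer_order, layer_u, layer_v):
            logger.warning(
                "interlayer edge %s spans non-consecutive layers %r-%r",
                edge, layer_u, layer_v,
            )
        self.inter_edges.add(edge)

    # -- queries --------------------------------------------------------------

    @property
    def n_layers(self) -> int:
        return len(self.layer_order)

    def layer_nodes(self, layer: str) -> list[NodeRef]:
        """Nodes native to ``layer``, sorted by name."""
        return sorted(n for n in self.nodes if n.layer == layer)

    def all_edges(self) -> set[Edge]:
        """E_M = union of all intralayer sets and the interlayer set."""
        out: set[Edge] = set()
        for edges in self.intra_edges.values():
            out |= edges
        return out | self.inter_edges

    def n_edges(self) -> int:
        return sum(len(e) for e in self.intra_edges.values()) + len(self.inter_edges)

    def degree(self) -> dict[NodeRef, int]:
        """Degree of every node in the flattened (supra) graph."""
        deg = {n: 0 for n in self.nodes}
        for u, v in self.all_edges():
            deg[u] += 1
            deg[v] += 1
        return deg

    def neighbours(self) -> dict[NodeRef, set[NodeRef]]:
        adj: dict[NodeRef, set[NodeRef]] = {n: set() for n in self.nodes}
        for u, v in self.all_edges():
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def validate(self) -> None:
        for layer, edges in self.intra_edges.items():
            for u, v in edges:
                if u.layer != layer or v.layer != layer:
                    raise NetworkValidationError(
                        f"intralayer edge {(u, v)} not confined to layer {layer!r}"
                    )
                if u == v:
                    raise NetworkValidationError(f"self-loop {u}")
        for u, v in self.inter_edges:
            if u.layer == v.layer:
                raise NetworkValidationError(
                    f"interlayer edge {(u, v)} joins a single layer"
                )
        for u, v in self.all_edges():
            if u not in self.nodes or v not in self.nodes:
                raise NetworkValidationError(f"edge {(u, v)} endpoint not in node set")
        overlap = self.inter_edges & set().union(*self.intra_edges.values()) \
            if self.intra_edges else set()
        if overlap:
            raise NetworkValidationError(f"edges both intra and inter: {overlap}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultilayerNetwork):
            return NotImplemented
        return (
            self.layer_order == other.layer_order
            and self.nodes == other.nodes
            and self.intra_edges == other.intra_edges
            and self.inter_edges == other.inter_edges
        )


def _adjacent(order: Sequence[str], a: str, b: str) -> bool:
    try:
        return abs(order.index(a) - order.index(b)) == 1
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# edge-list dialect
# ---------------------------------------------------------------------------

def _split_layer_spec(spec: str) -> tuple[str, ...]:
    """A bare label is intralayer; ``L1-L2`` (two distinct labels) is interlayer."""
    if "-" in spec:
        parts = tuple(spec.split("-"))
        if len(parts) == 2 and parts[0] != parts[1] and all(parts):
            return parts
    return (spec,)


def read_edge_list(
    stream: IO[str] | Iterable[str],
    layer_order: Sequence[str] | None = None,
) -> MultilayerNetwork:
    """Parse the TSV edge-list dialect into a :class:`MultilayerNetwork`.

    Duplicate rows and reversed duplicates collapse to a single undirected
    edge.  ``layer_order`` defaults to first-appearance order of intralayer
    labels; interlayer labels must already be known when their row appears,
    unless an explicit ``layer_order`` declares them up front.
    """
    net = MultilayerNetwork()
    if layer_order is not None:
        for lay in layer_order:
            net.add_layer(lay)
    inter_rows: list[tuple[int, str, str, str, str]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) not in (3, 4):
            raise MalformedEdgeError(
                f"line {lineno}: expected 3 or 4 columns, got {len(fields)}"
            )
        u, v, spec = fields[0], fields[1], fields[2]
        layers = _split_layer_spec(spec)
        if len(layers) == 1:
            net.add_intra_edge(u, v, layers[0]) if u != v else _raise_self_loop(
                lineno, u, layers[0]
            )
        else:
            # defer so that intralayer rows can register layers first
            inter_rows.append((lineno, u, layers[0], v, layers[1]))
    for lineno, u, lu, v, lv in inter_rows:
        try:
            net.add_inter_edge(u, lu, v, lv)
        except NetworkValidationError as exc:
            raise NetworkValidationError(f"line {lineno}: {exc}") from exc
    net.validate()
    return net


def _raise_self_loop(lineno: int, u: str, layer: str) -> None:
    raise NetworkValidationError(
        f"line {lineno}: self-loop {u!r} on layer {layer!r}"
    )


def from_layer_graphs(
    layer_graphs: Sequence[tuple[str, Iterable[str], Iterable[tuple[str, str]]]],
    inter_edges: Iterable[tuple[tuple[str, str], tuple[str, str]]] = (),
) -> MultilayerNetwork:
    """Build a network from in-memory per-layer graphs, skipping file I/O.

    Parameters
    ----------
    layer_graphs
        Ordered ``(layer_label, nodes, edges)`` triples; each edge is an
        unordered ``(u, v)`` name pair on that layer.
    inter_edges
        Cross-layer pairs ``((u, layer_u), (v, layer_v))``.  Endpoints must
        exist on their claimed layers.
    """
    net = MultilayerNetwork()
    for layer, nodes, edges in layer_graphs:
        net.add_layer(layer)
        for name in nodes:
            net.add_node(name, layer)
        for u, v in edges:
            net.add_intra_edge(u, v, layer)
    known = set(net.nodes)
    for (u, lu), (v, lv) in inter_edges:
        for name, lay in ((u, lu), (v, lv)):
            if NodeRef(name, lay) not in known:
                raise NetworkValidationError(
                    f"interlayer endpoint {name!r} absent from layer {lay!r}"
                )
        net.add_inter_edge(u, lu, v, lv)
    net.validate()
    return net


def write_edge_list(network: MultilayerNetwork, stream: IO[str]) -> int:
    """Serialize to the TSV dialect; returns the number of data rows written."""
    count = 0
    for layer in network.layer_order:
        for u, v in sorted(network.intra_edges[layer]):
            stream.write(f"{u.name}\t{v.name}\t{layer}\n")
            count += 1
    for u, v in sorted(network.inter_edges):
        stream.write(f"{u.name}\t{v.name}\t{u.layer}-{v.layer}\n")
        count += 1
    return count


# ---------------------------------------------------------------------------
# similarity matrix I/O (TSV: source, target, layer, similarity)
# ---------------------------------------------------------------------------

_SIM_HEADER = "source\ttarget\tlayer\tsimilarity"


def write_similarity(matrix: "SimilarityMatrix", stream: IO[str]) -> int:
    """One row per scored same-layer pair, similarity at 6 decimal places."""
    import numpy as np

    stream.write(_SIM_HEADER + "\n")
    count = 0
    for block in matrix.blocks:
        if not np.all(np.isfinite(block.values)):
            raise ValueError("similarity values must be finite")
        for i, s in enumerate(block.source_order):
            for j, t in enumerate(block.target_order):
                stream.write(
                    f"{s.name}\t{t.name}\t{block.layer}\t{block.values[i, j]:.6f}\n"
                )
                count += 1
    return count


def read_similarity(stream: IO[str]) -> list[tuple[str, str, str, float]]:
    """Parse rows written by :func:`write_similarity` back into tuples."""
    rows: list[tuple[str, str, str, float]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line == _SIM_HEADER.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise MalformedEdgeError(f"line {lineno}: expected 4 columns")
        rows.append((parts[0], parts[1], parts[2], float(parts[3])))
    return rows
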