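import io

import numpy as np
import pytest

from mulsim import benchgen, netio


@pytest.fixture
def toy_two_layer() -> netio.MultilayerNetwork:
    """Two layers with intralayer edges on each and one interlayer edge."""
    return netio.from_layer_graphs(
        [
            ("L1", ["a", "b", "c"], [("a", "b"), ("b", "c")]),
            ("L2", ["x", "y", "z"], [("x", "y"), ("y", "z"), ("x", "z")]),
        ],
        inter_edges=[(("a", "L1"), ("x", "L2"))],
    )


@pytest.fixture
def bench_network() -> netio.MultilayerNetwork:
    """A 2-layer synthetic network at the benchmark's default parameters."""
    rng = np.random.default_rng(42)
    return benchgen.gen_multilayer(benchgen.GenParams(), rng)


def random_network(rng: np.random.Generator, n_layers: int = 2,
                   n: int = 8, p_edge: float = 0.4,
                   n_inter: int = 2) -> netio.MultilayerNetwork:
    """Small Erdos-Renyi-per-layer network for property tests."""
    layers = []
    for li in range(n_layers):
        nodes = [f"v{i}" for i in range(n)]
        edges = {
            (nodes[i], nodes[j])
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < p_edge
        }
        # edge-list carriers cannot represent isolated nodes; cover them
        covered = {x for e in edges for x in e}
        for i, node in enumerate(nodes):
            if node not in covered:
                edges.add((node, nodes[(i + 1) % n]))
        layers.append((f"L{li}", nodes, sorted(edges)))
    inter = []
    for li in range(n_layers - 1):
        for _ in range(n_inter):
            a, b = rng.integers(n), rng.integers(n)
            inter.append(((f"v{a}", f"L{li}"), (f"v{b}", f"L{li+1}")))
    return netio.from_layer_graphs(layers, inter_edges=inter)


def roundtrip(network: netio.MultilayerNetwork) -> netio.MultilayerNetwork:
    buf = io.StringIO()
    netio.write_edge_list(network, buf)
    buf.seek(0)
    return netio.read_edge_list(buf)
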