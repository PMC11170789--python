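"""GIN forward rule, stacking, determinism and equivariance."""

import io
import itertools

import numpy as np
import pytest

from mulsim import gin, netio, preprocess
from mulsim.gin import (
    GINLayerParams,
    MLPParams,
    embed,
    embed_pair,
    gin_layer_forward,
    init_model,
    mlp_forward,
)

from conftest import random_network


def scalar_mlp(w1=1.0, w2=1.0) -> MLPParams:
    return MLPParams(
        W1=np.array([[w1]]), b1=np.zeros(1), W2=np.array([[w2]]), b2=np.zeros(1)
    )


class TestMLPForward:
    @pytest.mark.parametrize("x,expected", [(-3.0, 0.0), (2.5, 2.5), (0.0, 0.0)])
    def test_scalar_identity_chain(self, x, expected):
        assert mlp_forward(scalar_mlp(), np.array([[x]]))[0, 0] == expected

    def test_hand_matrix_evaluation(self):
        params = MLPParams(
            W1=np.array([[1.0, -1.0]]),
            b1=np.zeros(2),
            W2=np.array([[1.0], [1.0]]),
            b2=np.zeros(1),
        )
        assert mlp_forward(params, np.array([[4.0]]))[0, 0] == 4.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="d_in"):
            mlp_forward(scalar_mlp(), np.ones((2, 3)))

    def test_inconsistent_params_rejected(self):
        with pytest.raises(ValueError, match="chain"):
            MLPParams(W1=np.ones((2, 3)), b1=np.zeros(3), W2=np.ones((4, 2)), b2=np.zeros(2))


def path_edge_index():
    # a-b-c as both orientations
    return np.array([[0, 1, 1, 2], [1, 0, 2, 1]])


class TestGINLayerForward:
    def test_path_hand_evaluation(self):
        """a-b-c with features (1,2,3), eps=0: (1+2, 2+1+3, 3+2) = (3,6,5)."""
        layer = GINLayerParams(mlp=scalar_mlp())
        out = gin_layer_forward(layer, np.array([[1.0], [2.0], [3.0]]), path_edge_index())
        assert np.allclose(out.ravel(), [3.0, 6.0, 5.0])

    def test_epsilon_scales_self_term(self):
        layer = GINLayerParams(mlp=scalar_mlp(), epsilon=0.5)
        out = gin_layer_forward(layer, np.array([[1.0], [2.0], [3.0]]), path_edge_index())
        assert out[0, 0] == pytest.approx(1.5 * 1 + 2)

    def test_isolated_negative_node_killed_by_relu(self):
        layer = GINLayerParams(mlp=scalar_mlp())
        out = gin_layer_forward(layer, np.array([[-1.0]]), np.empty((2, 0), dtype=int))
        assert out[0, 0] == 0.0

    def test_nonfinite_input_rejected(self):
        layer = GINLayerParams(mlp=scalar_mlp())
        with pytest.raises(ValueError, match="finite"):
            gin_layer_forward(layer, np.array([[np.nan]]), np.empty((2, 0), dtype=int))

    @pytest.mark.parametrize("case", range(20))
    def test_matches_per_node_brute_force(self, case):
        """Vectorized forward equals direct per-node evaluation of the rule."""
        rng = np.random.default_rng(case)
        n = int(rng.integers(2, 6))
        d = int(rng.integers(1, 4))
        X = rng.normal(size=(n, d))
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < 0.5]
        ei = (
            np.array([[i for i, j in pairs] + [j for i, j in pairs],
                      [j for i, j in pairs] + [i for i, j in pairs]])
            if pairs else np.empty((2, 0), dtype=int)
        )
        layer = GINLayerParams(
            mlp=MLPParams(
                W1=rng.normal(size=(d, 3)), b1=rng.normal(size=3),
                W2=rng.normal(size=(3, 2)), b2=rng.normal(size=2),
            ),
            epsilon=float(rng.normal() * 0.3),
        )
        got = gin_layer_forward(layer, X, ei)
        for v in range(n):
            nbrs = [b if a == v else a for a, b in pairs if v in (a, b)]
            agg = (1 + layer.epsilon) * X[v] + sum(
                (X[u] for u in nbrs), np.zeros(d)
            )
            expected = mlp_forward(layer.mlp, agg[None, :])[0]
            assert np.allclose(got[v], expected, atol=1e-10)


class TestInitModel:
    def test_bitwise_determinism(self):
        m1 = init_model(8, 8, 8, 2, seed=7)
        m2 = init_model(8, 8, 8, 2, seed=7)
        assert np.array_equal(m1.conv1.mlp.W1, m2.conv1.mlp.W1)
        assert np.array_equal(m1.conv2.mlp.W2, m2.conv2.mlp.W2)
        for a, b in zip(m1.convs, m2.convs):
            assert np.array_equal(a.mlp.W1, b.mlp.W1)

    def test_seeds_differ(self):
        assert not np.array_equal(
            init_model(8, 8, 8, 1, seed=1).conv1.mlp.W1,
            init_model(8, 8, 8, 1, seed=2).conv1.mlp.W1,
        )

    def test_stack_size_tracks_network_layers(self):
        model = init_model(8, 8, 8, n_intermediate=3, seed=0)
        assert len(model.convs) == 3
        assert model.n_steps == 5

    def test_epsilons_start_at_zero(self):
        model = init_model(4, 4, 4, 2, seed=0)
        assert model.conv1.epsilon == 0.0
        assert all(c.epsilon == 0.0 for c in model.convs)

    @pytest.mark.parametrize("bad", [dict(n_intermediate=0), dict(d_in=0)])
    def test_invalid_arguments_rejected(self, bad):
        kwargs = dict(d_in=4, d_hid=4, d_out=4, n_intermediate=1, seed=0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            init_model(**kwargs)


class TestEmbed:
    def test_complete_graph_symmetry(self):
        """All K4 nodes are equivalent, so all embedding rows coincide."""
        net = netio.from_layer_graphs(
            [("L1", list("abcd"), list(itertools.combinations("abcd", 2)))]
        )
        batch = preprocess.prepare(net, d=8)
        model = init_model(8, 8, 8, 1, seed=0)
        emb = embed(model, batch)
        assert np.allclose(emb, emb[0], atol=1e-9)

    def test_permutation_equivariance(self):
        """Renaming nodes permutes embedding rows without changing values."""
        rng = np.random.default_rng(11)
        net = random_network(rng, n_layers=1, n=6, n_inter=0)
        renamed = netio.MultilayerNetwork()
        renamed.add_layer("L0")
        mapping = {n: f"w{9 - int(n.name[1:])}" for n in net.nodes}
        for n in net.nodes:
            renamed.add_node(mapping[n], "L0")
        for u, v in net.intra_edges["L0"]:
            renamed.add_intra_edge(mapping[u], mapping[v], "L0")
        model = init_model(8, 8, 8, 1, seed=5)
        e1 = embed(model, preprocess.prepare(net, d=8))
        e2 = embed(model, preprocess.prepare(renamed, d=8))
        b1 = preprocess.prepare(net, d=8)
        b2 = preprocess.prepare(renamed, d=8)
        for i, n in enumerate(b1.node_order):
            j = b2.node_order.index(netio.NodeRef(mapping[n], "L0"))
            assert np.allclose(e1[i], e2[j], atol=1e-6)

    def test_isomorphic_graphs_equal_embedding_multisets(self):
        """Two isomorphic 6-node graphs yield the same multiset of rows."""
        edges1 = [("0", "1"), ("1", "2"), ("2", "3"), ("3", "4"), ("4", "5"), ("5", "0")]
        perm = {"0": "c", "1": "e", "2": "a", "3": "f", "4": "b", "5": "d"}
        edges2 = [(perm[u], perm[v]) for u, v in edges1]
        g1 = netio.from_layer_graphs([("L1", list(perm), edges1)])
        g2 = netio.from_layer_graphs([("L1", list(perm.values()), edges2)])
        model = init_model(8, 8, 8, 1, seed=3)
        e1 = embed(model, preprocess.prepare(g1, d=8))
        e2 = embed(model, preprocess.prepare(g2, d=8))
        s1 = np.array(sorted(map(tuple, np.round(e1, 9))))
        s2 = np.array(sorted(map(tuple, np.round(e2, 9))))
        assert np.allclose(s1, s2, atol=1e-6)

    def test_wl_indistinguishable_nodes_equal_embeddings(self):
        """Nodes the 1-WL refinement cannot separate get identical rows:
        in a 6-cycle every node is WL-equivalent at any depth."""
        edges = [(str(i), str((i + 1) % 6)) for i in range(6)]
        net = netio.from_layer_graphs([("L1", [str(i) for i in range(6)], edges)])
        model = init_model(8, 8, 8, 2, seed=1)
        emb = embed(model, preprocess.prepare(net, d=8))
        assert np.allclose(emb, emb[0], atol=1e-9)

    def test_dimension_mismatch_rejected(self, toy_two_layer):
        batch = preprocess.prepare(toy_two_layer, d=8)
        model = init_model(16, 16, 16, 2, seed=0)
        with pytest.raises(ValueError, match="d_in"):
            embed(model, batch)


class TestEmbedPair:
    def test_shared_parameters_no_crosstalk(self, toy_two_layer, bench_network):
        model = init_model(8, 8, 8, 2, seed=0)
        b1 = preprocess.prepare(toy_two_layer, d=8)
        b2 = preprocess.prepare(bench_network, d=8)
        e1, e2 = embed_pair(model, b1, b2)
        assert np.array_equal(e1, embed(model, b1))
        assert np.array_equal(e2, embed(model, b2))
        r1, r2 = embed_pair(model, b2, b1)
        assert np.array_equal(r1, e2) and np.array_equal(r2, e1)

    def test_identical_batches_identical_outputs(self, toy_two_layer):
        model = init_model(8, 8, 8, 2, seed=0)
        b = preprocess.prepare(toy_two_layer, d=8)
        e1, e2 = embed_pair(model, b, b)
        assert np.array_equal(e1, e2)


class TestPersistence:
    def test_json_roundtrip(self):
        model = init_model(4, 5, 3, 2, seed=9)
        buf = io.StringIO()
        gin.save_model(model, buf)
        buf.seek(0)
        loaded = gin.load_model(buf)
        assert np.allclose(loaded.conv1.mlp.W1, model.conv1.mlp.W1)
        assert np.allclose(loaded.conv2.mlp.b2, model.conv2.mlp.b2)
        assert loaded.n_steps == model.n_steps
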