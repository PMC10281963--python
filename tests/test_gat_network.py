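"""Graph attention network: architecture, forward, attention, gradients."""

import math

import numpy as np
import pytest

from ifaceqe.edge_features import EDGE_FEATURE_DIM
from ifaceqe.gat_network import (FEATURE_VERSION, GATConfig, GATParams,
                                 aggregate_quality, attention_weights,
                                 edge_score, edge_scores, layer_forward,
                                 load_checkpoint, loss_and_gradients,
                                 model_forward, network_forward,
                                 save_checkpoint)
from ifaceqe.interface_graph import InterfaceGraph
from ifaceqe.node_features import NODE_FEATURE_DIM


def _toy_graph(rng, n1=3, n2=3, edges=None, label=True):
    """A featurized bipartite graph with random features (no structures)."""
    if edges is None:
        edges = [(i, n1 + j) for i in range(n1) for j in range(n2)]
    n_nodes = n1 + n2
    nodes = [(0 if k < n1 else 1, None) for k in range(n_nodes)]
    g = InterfaceGraph(
        nodes=nodes, edges=edges,
        edge_distance=rng.uniform(2.5, 9.5, len(edges)),
        node_features=rng.normal(size=(n_nodes, NODE_FEATURE_DIM)),
        edge_features=rng.normal(size=(len(edges), EDGE_FEATURE_DIM)))
    if label:
        g.edge_label = rng.uniform(0.05, 0.95, len(edges))
    return g


class TestConfig:
    def test_hidden_dims(self):
        cfg = GATConfig()
        assert cfg.hidden_dims == [32, 16, 8, 4]

    def test_layer_input_dims_after_head_concatenation(self):
        cfg = GATConfig()
        assert cfg.node_dims == [17, 128, 64, 32]

    def test_parameter_shapes(self):
        params = GATParams(GATConfig())
        assert params.W[0].shape == (4, 32, 17 + 27)
        assert params.W[1].shape == (4, 16, 128 + 27)
        assert params.W[3].shape == (1, 4, 32 + 27)
        assert params.a[0].shape == (4, 64)
        assert params.a[3].shape == (1, 8)

    def test_seeded_init_is_deterministic(self):
        p1, p2 = GATParams(GATConfig(random_seed=3)), \
            GATParams(GATConfig(random_seed=3))
        for x, y in zip(p1.flat(), p2.flat()):
            assert np.array_equal(x, y)
        p3 = GATParams(GATConfig(random_seed=4))
        assert not np.array_equal(p1.W[0], p3.W[0])


class TestAttention:
    def test_rows_sum_to_one_every_layer(self, labeled_graph, params):
        H = labeled_graph.node_features
        for l in range(params.config.n_layers):
            alpha, dst = attention_weights(
                H, labeled_graph.edge_features, labeled_graph.edges, params, l)
            sums = np.zeros((labeled_graph.n_nodes, alpha.shape[1]))
            np.add.at(sums, dst, alpha)
            assert np.allclose(sums, 1.0, atol=1e-12)
            H = layer_forward(H, labeled_graph.edge_features,
                              labeled_graph.edges, params, l)

    def test_single_neighbour_gets_weight_one(self, rng, params):
        g = _toy_graph(rng, n1=1, n2=1, edges=[(0, 1)])
        alpha, _ = attention_weights(g.node_features, g.edge_features,
                                     g.edges, params, 0)
        assert np.allclose(alpha, 1.0)

    def test_identical_neighbours_share_weight_equally(self, rng, params):
        """Two neighbours presenting identical features get alpha = 0.5."""
        g = _toy_graph(rng, n1=1, n2=2, edges=[(0, 1), (0, 2)])
        g.node_features[2] = g.node_features[1]
        g.edge_features[1] = g.edge_features[0]
        alpha, dst = attention_weights(g.node_features, g.edge_features,
                                       g.edges, params, 0)
        assert np.allclose(alpha[dst == 0], 0.5, atol=1e-12)


class TestForward:
    def test_hand_computed_single_layer(self):
        """Forward of a 1-layer, 1-head, 2-dim network on a 2-node graph,
        recomputed with explicit scalar arithmetic."""
        cfg = GATConfig(n_layers=1, heads_per_layer=(1,), hidden_input=2,
                        node_dim=2, edge_dim=1)
        params = GATParams(cfg)
        params.W[0] = np.array([[[1.0, 0.0, 0.5],
                                 [0.0, -1.0, 0.25]]])
        params.a[0] = np.array([[0.3, -0.2, 0.1, 0.4]])
        X = np.array([[1.0, 2.0], [3.0, -1.0]])
        Ef = np.array([[2.0]])
        H, _ = network_forward(X, Ef, [(0, 1)], params)
        # message into node 0 from node 1: z = W [h_1 || e]
        z01 = np.array([3.0 + 1.0, 1.0 + 0.5])
        z10 = np.array([1.0 + 1.0, -2.0 + 0.5])
        # single neighbour each: alpha = 1, final layer is linear
        assert H[0] == pytest.approx(z01)
        assert H[1] == pytest.approx(z10)

    def test_output_shape_and_finite(self, labeled_graph, params):
        H, _ = network_forward(labeled_graph.node_features,
                               labeled_graph.edge_features,
                               labeled_graph.edges, params)
        assert H.shape == (labeled_graph.n_nodes, 4)
        assert np.isfinite(H).all()

    def test_final_layer_produces_negative_components(self, labeled_graph,
                                                      params):
        """The output layer is linear, so embeddings are signed."""
        H, _ = network_forward(labeled_graph.node_features,
                               labeled_graph.edge_features,
                               labeled_graph.edges, params)
        assert (H < 0).any()

    def test_node_relabeling_invariance(self, rng, params):
        """Scores are equivariant under a permutation of node indices."""
        g = _toy_graph(rng, n1=4, n2=3)
        s0 = edge_scores(network_forward(g.node_features, g.edge_features,
                                         g.edges, params)[0], g.edges)
        perm = rng.permutation(g.n_nodes)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(g.n_nodes)
        X2 = g.node_features[inv]
        order = rng.permutation(g.n_edges)   # also shuffle edge order
        edges2 = [(int(perm[i]), int(perm[j]))
                  for i, j in (g.edges[k] for k in order)]
        E2 = g.edge_features[order]
        s1 = edge_scores(network_forward(X2, E2, edges2, params)[0], edges2)
        assert np.allclose(s1, s0[order], atol=1e-10)

    def test_deterministic(self, labeled_graph, params):
        s1, q1 = model_forward(labeled_graph, params)
        s2, q2 = model_forward(labeled_graph, params)
        assert np.array_equal(s1, s2) and q1 == q2


class TestEdgeScoreAndAggregation:
    def test_logistic_values(self):
        emb = np.array([[0.0, 1.0, 2.0, 0.0],
                        [1.0, 0.0, 0.0, 3.0],     # dot with row 0: 0
                        [0.0, 3.0, 0.0, 1.0]])    # dot with row 0: 3
        assert edge_score(emb, (0, 1)) == pytest.approx(0.5)
        assert edge_score(emb, (0, 2)) == pytest.approx(
            1.0 / (1.0 + math.exp(-3.0)))
        assert edge_score(emb, (0, 2), raw_dot=True) == pytest.approx(3.0)

    def test_score_symmetry(self, labeled_graph, params):
        H, _ = network_forward(labeled_graph.node_features,
                               labeled_graph.edge_features,
                               labeled_graph.edges, params)
        for i, j in labeled_graph.edges[:10]:
            assert edge_score(H, (i, j)) == edge_score(H, (j, i))

    def test_aggregate_is_mean(self):
        assert aggregate_quality([0.2, 0.4, 0.9]) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            aggregate_quality([])

    def test_untrained_q_in_open_unit_interval(self, labeled_graph):
        for seed in range(5):
            _, q = model_forward(labeled_graph,
                                 GATParams(GATConfig(random_seed=seed)))
            assert 0.0 < q < 1.0


class TestGradients:
    def test_matches_numerical_differentiation(self, rng):
        """Central-difference check of every parameter block on a 6-node
        graph, relative error below 1e-4."""
        g = _toy_graph(rng, n1=3, n2=3,
                       edges=[(0, 3), (0, 4), (1, 3), (1, 5), (2, 4), (2, 5)])
        cfg = GATConfig(hidden_input=8, random_seed=2)  # dims 8, 4, 2, 1
        params = GATParams(cfg)
        _, grads = loss_and_gradients(g, params)
        eps = 1e-6
        for arr, garr in zip(params.flat(), grads.flat()):
            flat, gflat = arr.ravel(), garr.ravel()
            # probe a subset of coordinates in each block
            for k in rng.choice(flat.size, size=min(12, flat.size),
                                replace=False):
                orig = flat[k]
                flat[k] = orig + eps
                lp, _ = loss_and_gradients(g, params)
                flat[k] = orig - eps
                lm, _ = loss_and_gradients(g, params)
                flat[k] = orig
                num = (lp - lm) / (2 * eps)
                scale = max(abs(num), abs(gflat[k]), 1e-8)
                assert abs(gflat[k] - num) / scale < 1e-4

    def test_loss_value_matches_forward(self, labeled_graph, params):
        loss, _ = loss_and_gradients(labeled_graph, params)
        scores, _ = model_forward(labeled_graph, params)
        assert loss == pytest.approx(
            float(((scores - labeled_graph.edge_label) ** 2).sum()))

    def test_unlabeled_graph_errors(self, rng, params):
        g = _toy_graph(rng, label=False)
        with pytest.raises(ValueError, match="label"):
            loss_and_gradients(g, params)


class TestCheckpoint:
    def test_round_trip(self, params, labeled_graph, tmp_path):
        path = str(tmp_path / "model.npz")
        save_checkpoint(params, path)
        loaded = load_checkpoint(path)
        for x, y in zip(params.flat(), loaded.flat()):
            assert np.array_equal(x, y)
        _, q0 = model_forward(labeled_graph, params)
        _, q1 = model_forward(labeled_graph, loaded)
        assert q0 == q1

    def test_feature_version_mismatch_errors(self, params, tmp_path):
        path = str(tmp_path / "model.npz")
        save_checkpoint(params, path)
        data = dict(np.load(path))
        import json
        meta = json.loads(bytes(data["_meta"]).decode())
        meta["version"] = "node9-edge9-v0"
        data["_meta"] = np.frombuffer(json.dumps(meta).encode(),
                                      dtype=np.uint8)
        np.savez(path, **data)
        with pytest.raises(ValueError, match="version"):
            load_checkpoint(path)


def test_feature_version_tracks_dimensions():
    assert str(NODE_FEATURE_DIM) in FEATURE_VERSION
    assert str(EDGE_FEATURE_DIM) in FEATURE_VERSION
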