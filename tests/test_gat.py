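"""GAT layer, pooling, readout and classifier, checked against independent
brute-force computations of the attention and scoring rules."""

import math

import numpy as np
import pytest

import braingat as bg
from braingat.autodiff import Tensor, bce_with_logits
from braingat.connectivity import BrainGraph
from braingat.features import NodeFeatureMatrix
from braingat.gat import (AttentionCoefficients, GatLayerParams, ModelConfig,
                          GatClassifier, attention_coefficients, gat_forward,
                          init_gat_layer, node_attention_scores, readout,
                          save_checkpoint, load_checkpoint, topk_pool)


# -- independent oracles ---------------------------------------------------

def oracle_attention(H, neighbors, W, a):
    """Single-head softmax attention computed with plain Python loops:
    alpha_ij = exp(a . [W h_i || W h_j]) / sum_k exp(a . [W h_i || W h_k])."""
    alpha = {}
    for i, nbrs in neighbors.items():
        scores = {j: math.exp(float(a @ np.concatenate([W @ H[i], W @ H[j]])))
                  for j in nbrs}
        z = sum(scores.values())
        for j, s in scores.items():
            alpha[(i, j)] = s / z
    return alpha


def oracle_layer(H, neighbors, W_out, alpha):
    """h_i' = ReLU( sum_{j in N(i)} alpha_ij W h_j ), plain loops."""
    out = np.zeros((len(neighbors), W_out.shape[0]))
    for i, nbrs in neighbors.items():
        for j in nbrs:
            out[i] += alpha[(i, j)] * (W_out @ H[j])
    return np.maximum(out, 0.0)


def oracle_node_scores(alpha, n):
    """Sum of alpha over every directed pair incident to each node; a
    self-loop is a single pair."""
    s = np.zeros(n)
    for (i, j), a in alpha.items():
        s[i] += a
        if i != j:
            s[j] += a
    return s


def _edge_index(neighbors):
    tgt = [i for i, nbrs in neighbors.items() for _ in nbrs]
    src = [j for nbrs in neighbors.values() for j in nbrs]
    return np.asarray(tgt), np.asarray(src)


def _single_head_params(W, a, d_out, d_in):
    return GatLayerParams(W_heads=[Tensor(W, requires_grad=True)],
                          a_heads=[Tensor(a, requires_grad=True)],
                          W_shared=Tensor(W, requires_grad=True))


# -- attention -------------------------------------------------------------

class TestAttention:
    def test_single_neighbor_gets_all_attention(self):
        H = np.random.default_rng(0).normal(size=(2, 3))
        neighbors = {0: [1], 1: [0]}
        params = init_gat_layer(np.random.default_rng(1), 3, 4, 2)
        att = attention_coefficients(H, _edge_index(neighbors), params)
        np.testing.assert_allclose(att.alpha.data, 1.0)

    def test_zero_features_give_uniform_attention(self):
        H = np.zeros((4, 3))
        neighbors = {0: [0, 1, 2, 3], 1: [1, 0], 2: [2, 0], 3: [3, 0]}
        params = init_gat_layer(np.random.default_rng(2), 3, 4, 3)
        att = attention_coefficients(H, _edge_index(neighbors), params)
        for head in att.per_head:
            d = AttentionCoefficients(head, [head], att.edge_index).as_dict()
            for i, nbrs in neighbors.items():
                for j in nbrs:
                    assert d[(i, j)] == pytest.approx(1 / len(nbrs))

    def test_three_node_path_matches_hand_oracle(self):
        # path 0 - 1 - 2 with self-loops, one head, d_out = 2, fixed params
        H = np.array([[1.0, 0.5], [-0.3, 0.8], [0.2, -0.6]])
        W = np.array([[0.4, -0.2], [0.1, 0.3]])
        a = np.array([0.5, -0.4, 0.2, 0.3])
        neighbors = {0: [0, 1], 1: [1, 0, 2], 2: [2, 1]}
        params = _single_head_params(W, a, 2, 2)
        att = attention_coefficients(H, _edge_index(neighbors), params)
        expected = oracle_attention(H, neighbors, W, a)
        got = att.as_dict()
        for pair, val in expected.items():
            assert got[pair] == pytest.approx(val, abs=1e-6)

    def test_rows_sum_to_one_per_head_and_averaged(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            n = int(rng.integers(3, 10))
            neighbors = {i: [i] + [int(j) for j in rng.choice(n, rng.integers(1, n))]
                         for i in range(n)}
            neighbors = {i: sorted(set(v)) for i, v in neighbors.items()}
            H = rng.normal(size=(n, 4))
            params = init_gat_layer(rng, 4, 3, 4)
            att = attention_coefficients(H, _edge_index(neighbors), params)
            tgt, _ = att.edge_index
            for arr in [h.data for h in att.per_head] + [att.alpha.data]:
                sums = np.zeros(n)
                np.add.at(sums, tgt, arr)
                np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_isolated_node_without_self_loops_rejected(self):
        H = np.zeros((3, 2))
        params = init_gat_layer(np.random.default_rng(0), 2, 2, 1)
        with pytest.raises(ValueError, match="self-loops"):
            attention_coefficients(H, (np.array([0, 1]), np.array([1, 0])),
                                   params)


class TestGatForward:
    def test_identity_on_single_self_loop_node(self):
        H = np.array([[0.7, 1.2]])
        W = np.eye(2)
        params = _single_head_params(W, np.zeros(4), 2, 2)
        att = attention_coefficients(H, (np.array([0]), np.array([0])), params)
        out = gat_forward(H, att.edge_index, params, att)
        np.testing.assert_allclose(out.data, H)

    def test_uniform_attention_equal_features_symmetry(self):
        # complete graph with identical node features: all rows equal
        n = 5
        H = np.tile(np.array([0.3, -0.7, 1.1]), (n, 1))
        neighbors = {i: list(range(n)) for i in range(n)}
        params = init_gat_layer(np.random.default_rng(4), 3, 4, 2)
        att = attention_coefficients(H, _edge_index(neighbors), params)
        out = gat_forward(H, att.edge_index, params, att).data
        assert np.allclose(out, out[0][None, :], atol=1e-12)

    def test_three_node_path_output_matches_oracle(self):
        H = np.array([[1.0, 0.5], [-0.3, 0.8], [0.2, -0.6]])
        W = np.array([[0.4, -0.2], [0.1, 0.3]])
        a = np.array([0.5, -0.4, 0.2, 0.3])
        neighbors = {0: [0, 1], 1: [1, 0, 2], 2: [2, 1]}
        params = _single_head_params(W, a, 2, 2)
        att = attention_coefficients(H, _edge_index(neighbors), params)
        out = gat_forward(H, att.edge_index, params, att)
        expected = oracle_layer(H, neighbors, W,
                                oracle_attention(H, neighbors, W, a))
        np.testing.assert_allclose(out.data, expected, atol=1e-6)

    def test_zero_attention_vectors_reduce_to_mean_aggregation(self):
        rng = np.random.default_rng(5)
        n = 6
        neighbors = {i: sorted({i, *rng.choice(n, 3).tolist()}) for i in range(n)}
        H = rng.normal(size=(n, 4))
        W = rng.normal(size=(3, 4))
        params = GatLayerParams(
            W_heads=[Tensor(rng.normal(size=(3, 4))) for _ in range(4)],
            a_heads=[Tensor(np.zeros(6)) for _ in range(4)],
            W_shared=Tensor(W))
        att = attention_coefficients(H, _edge_index(neighbors), params)
        out = gat_forward(H, att.edge_index, params, att).data
        direct = np.maximum(np.stack(
            [np.mean([W @ H[j] for j in neighbors[i]], axis=0)
             for i in range(n)]), 0.0)
        np.testing.assert_allclose(out, direct, atol=1e-10)


class TestTopKPool:
    def test_keeps_ceil_ratio_nodes(self):
        # ratio 0.2 of 200 nodes -> exactly 40 survive
        rng = np.random.default_rng(6)
        n = 200
        neighbors = {i: sorted({i, *rng.choice(n, 4).tolist()}) for i in range(n)}
        H = rng.normal(size=(n, 16))
        params = init_gat_layer(rng, 16, 8, 2)
        att = attention_coefficients(H, _edge_index(neighbors), params)
        pool = topk_pool(H, att.edge_index, att, ratio=0.2)
        assert pool.selected_indices.size == 40 == math.ceil(0.2 * n)

    def test_star_hub_always_selected(self):
        # uniform attention on a star: the hub touches the most directed
        # pairs, so it outscores every leaf
        n = 6
        neighbors = {0: list(range(n))}
        for leaf in range(1, n):
            neighbors[leaf] = [leaf, 0]
        H = np.zeros((n, 3))              # zero features -> uniform attention
        params = init_gat_layer(np.random.default_rng(7), 3, 2, 2)
        att = attention_coefficients(H, _edge_index(neighbors), params)
        pool = topk_pool(H, att.edge_index, att, ratio=0.2)
        assert pool.selected_indices[0] == 0     # hub ranks first
        assert np.argmax(pool.node_scores) == 0

    @pytest.mark.parametrize("n", range(2, 9))
    def test_selection_matches_sort_oracle(self, n):
        # brute-force score-sort oracle over random graphs of every size <= 8
        rng = np.random.default_rng(n)
        for trial in range(20):
            neighbors = {i: sorted({i, *rng.choice(n, rng.integers(1, n + 1)).tolist()})
                         for i in range(n)}
            H = rng.normal(size=(n, 3))
            params = init_gat_layer(rng, 3, 3, int(rng.integers(1, 4)))
            att = attention_coefficients(H, _edge_index(neighbors), params)
            ratio = float(rng.uniform(0.2, 1.0))
            pool = topk_pool(H, att.edge_index, att, ratio=ratio)
            scores = oracle_node_scores(att.as_dict(), n)
            k = max(1, math.ceil(ratio * n))
            expected = sorted(range(n), key=lambda i: (-scores[i], i))[:k]
            assert pool.selected_indices.tolist() == expected
            np.testing.assert_allclose(pool.node_scores, scores, atol=1e-9)

    def test_induced_subgraph_and_original_indices(self):
        # 4-cycle plus self-loops; force selection of nodes {0, 2} via ties
        neighbors = {0: [0, 1, 3], 1: [1, 0, 2], 2: [2, 1, 3], 3: [3, 0, 2]}
        H = np.zeros((4, 2))
        params = init_gat_layer(np.random.default_rng(8), 2, 2, 1)
        att = attention_coefficients(H, _edge_index(neighbors), params)
        pool = topk_pool(H, att.edge_index, att, ratio=0.5)
        assert pool.selected_indices.tolist() == [0, 1]   # ties -> low index
        tgt, src = pool.sub_edge_index
        kept = set(zip(tgt.tolist(), src.tolist()))
        assert kept == {(0, 0), (1, 1), (0, 1), (1, 0)}

    def test_global_attention_diagnostic(self):
        neighbors = {0: [0, 1], 1: [1, 0]}
        H = np.zeros((2, 2))
        params = init_gat_layer(np.random.default_rng(9), 2, 2, 1)
        att = attention_coefficients(H, _edge_index(neighbors), params)
        pool = topk_pool(H, att.edge_index, att, ratio=1.0)
        assert pool.global_attention == pytest.approx(pool.node_scores.sum())
        assert pool.normalized_scores.sum() == pytest.approx(1.0)


class TestReadout:
    def test_single_node_duplicates_features(self):
        h = np.array([[1.0, -2.0, 3.0]])
        np.testing.assert_allclose(readout(h).data, [1, -2, 3, 1, -2, 3])

    def test_two_node_example(self):
        z = readout(np.array([[0.0, 2.0], [2.0, 0.0]]))
        np.testing.assert_allclose(z.data, [2.0, 2.0, 1.0, 1.0])

    def test_node_permutation_invariance(self):
        rng = np.random.default_rng(10)
        H = rng.normal(size=(10, 5))
        perm = rng.permutation(10)
        np.testing.assert_allclose(readout(H).data, readout(H[perm]).data)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            readout(np.zeros((0, 3)))


# -- classifier ------------------------------------------------------------

def _graph_from(values, edges, label=0, sid="g"):
    feats = NodeFeatureMatrix(values=values, subject_id=sid)
    return BrainGraph(node_features=feats, edges=np.asarray(edges),
                      label=label, subject_id=sid)


@pytest.fixture()
def random_graph():
    rng = np.random.default_rng(11)
    n = 12
    edges = np.array([[i, j] for i in range(n) for j in range(i + 1, n)
                      if rng.random() < 0.3])
    return _graph_from(rng.normal(size=(n, 16)), edges)


class TestClassifier:
    def test_output_is_probability(self, random_graph):
        model = GatClassifier(ModelConfig(), seed=0)
        p = model.model_forward(random_graph)
        assert 0.0 < p < 1.0

    def test_eval_mode_deterministic(self, random_graph):
        model = GatClassifier(ModelConfig(), seed=1)
        assert model.model_forward(random_graph) == model.model_forward(random_graph)

    def test_permutation_equivariance(self, random_graph):
        # consistently permuting ROIs (features + edges) leaves the
        # probability unchanged when pooling scores are untied
        model = GatClassifier(ModelConfig(), seed=2)
        p0 = model.model_forward(random_graph)
        rng = np.random.default_rng(12)
        perm = rng.permutation(random_graph.n_nodes)
        inv = np.argsort(perm)
        pg = _graph_from(random_graph.node_features.values[perm],
                         inv[random_graph.edges])
        assert model.model_forward(pg) == pytest.approx(p0, abs=1e-5)

    def test_multiscale_readout_length(self, random_graph):
        model = GatClassifier(ModelConfig(), seed=3)
        z3, pool1, pool2, pool2_orig = model.embed(random_graph)
        assert z3.shape == (64,)          # 2 * d_hidden
        assert pool1.selected_indices.size == math.ceil(0.2 * 12)
        assert set(pool2_orig) <= set(pool1.selected_indices)

    @pytest.mark.parametrize("variant", ["average", "concat"])
    def test_multihead_variants_run(self, random_graph, variant):
        model = GatClassifier(ModelConfig(multihead_output=variant), seed=4)
        assert 0.0 < model.model_forward(random_graph) < 1.0

    def test_gradient_flow_to_every_parameter(self, random_graph):
        model = GatClassifier(ModelConfig(dropout=0.0), seed=5)
        graphs = [random_graph,
                  _graph_from(np.random.default_rng(13).normal(size=(12, 16)),
                              random_graph.edges, label=1, sid="g2")]
        logits, _ = model.forward_batch(graphs, training=True,
                                        rng=np.random.default_rng(0))
        loss = bce_with_logits(logits, np.array([0.0, 1.0]))
        loss.backward()
        for p in model.parameters():
            assert p.grad is not None and np.any(p.grad != 0)

    def test_checkpoint_round_trip_bit_exact(self, random_graph, tmp_path):
        model = GatClassifier(ModelConfig(n_heads=2), seed=6)
        path = tmp_path / "model.ckpt"
        save_checkpoint(model, path)
        clone = load_checkpoint(path)
        assert clone.config == model.config
        for a, b in zip(model.state_arrays().values(),
                        clone.state_arrays().values()):
            np.testing.assert_array_equal(a, b)
        assert clone.model_forward(random_graph) == model.model_forward(random_graph)

    def test_tampered_checkpoint_rejected(self, tmp_path):
        model = GatClassifier(ModelConfig(n_heads=1), seed=7)
        path = tmp_path / "model.ckpt"
        save_checkpoint(model, path)
        raw = bytearray(path.read_bytes())
        raw[-1] ^= 0xFF                   # flip a payload byte
        path.write_bytes(bytes(raw))
        with pytest.raises(ValueError, match="hash mismatch"):
            load_checkpoint(path)
        path.write_bytes(b"garbage")
        with pytest.raises(ValueError, match="checkpoint"):
            load_checkpoint(path)
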