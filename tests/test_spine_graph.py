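"""Tests for graph construction, dual-stream encoding and edge-aware attention."""

import numpy as np
import pytest

import geospine._autograd as ag
from geospine import phantom
from geospine._autograd import Tensor
from geospine.geometry import LandmarkSet
from geospine.nn import MLP
from geospine.spine_graph import (ImageEncoder, PatchEncoder, SpineGraphModel,
                                  TransformerConfig, build_graph, edge_aware_attention,
                                  encode_nodes, predict, transformer_forward)


def _single_vertebra():
    return LandmarkSet(np.array([[64.0, 64.0]]), np.array([20.0]),
                       np.zeros((0, 2)), np.array([3.0, 3.0]))


def _layer_params(model, li=0):
    layer = model.transformer.layers[li]
    return {"Wq": layer.Wq, "Wk": layer.Wk, "Wv": layer.Wv, "edge_mlp": layer.edge_mlp}


@pytest.fixture(scope="module")
def sample_and_graph():
    s = phantom.generate_samples(n=4, seed=9)[0]
    return s, build_graph(s.landmarks)


@pytest.fixture(scope="module")
def tiny_model():
    return SpineGraphModel(TransformerConfig(node_dim=32, n_heads=4, n_layers=2),
                           d_local=16, d_global=16, seed=0)


class TestBuildGraph:
    def test_node_and_edge_counts(self, sample_and_graph):
        s, g = sample_and_graph
        n = s.landmarks.n_vertebrae
        assert g.n_nodes == 2 * n - 1
        assert len(g.edges) == 2 * n - 2

    def test_singleton_graph(self):
        g = build_graph(_single_vertebra())
        assert g.n_nodes == 1 and len(g.edges) == 0

    def test_adjacency_symmetric(self, sample_and_graph):
        _, g = sample_and_graph
        adj = g.adjacency()
        assert np.array_equal(adj, adj.T)

    def test_disc_nodes_at_centroid_midpoints(self, sample_and_graph):
        s, g = sample_and_graph
        c = s.landmarks.centroids
        disc_positions = g.positions[g.kinds == 1]
        assert np.allclose(disc_positions, (c[:-1] + c[1:]) / 2.0)

    def test_config_rejects_bad_head_split(self):
        with pytest.raises(ValueError, match="divisible"):
            TransformerConfig(node_dim=30, n_heads=4)


class TestEncodeNodes:
    def test_fused_dim_is_sum_of_streams(self, sample_and_graph):
        s, g = sample_and_graph
        rng = np.random.default_rng(0)
        local = PatchEncoder(16, out_dim=8, rng=rng)
        globl = ImageEncoder(out_dim=6, rng=rng)
        fused = encode_nodes(s.image, g, local, globl)
        assert fused.shape == (g.n_nodes, 14)

    def test_global_slice_carries_global_stream(self, sample_and_graph):
        s, g = sample_and_graph
        rng = np.random.default_rng(0)
        local = PatchEncoder(16, out_dim=8, rng=rng)
        globl = ImageEncoder(out_dim=6, rng=rng)
        fused = encode_nodes(s.image, g, local, globl).data

        class ZeroGlobal(ImageEncoder):
            def __call__(self, x):
                return Tensor(np.zeros((np.asarray(x.data if isinstance(x, Tensor) else x).shape[0], self.out_dim)))

        zg = ZeroGlobal(out_dim=6, rng=np.random.default_rng(0))
        fused0 = encode_nodes(s.image, g, local, zg).data
        assert np.allclose(fused[:, :8], fused0[:, :8])   # local part unchanged
        assert np.allclose(fused0[:, 8:], 0.0)            # only global slice zeroed

    def test_identical_inputs_identical_embeddings(self, sample_and_graph):
        s, g = sample_and_graph
        rng = np.random.default_rng(1)
        local = PatchEncoder(16, out_dim=8, rng=rng)
        globl = ImageEncoder(out_dim=6, rng=rng)
        a = encode_nodes(s.image, g, local, globl).data
        b = encode_nodes(s.image, g, local, globl).data
        assert np.array_equal(a, b)


def _dense_reference_attention(h, graph, params, n_heads):
    """Brute-force masked scaled-dot-product attention with edge bias."""
    M, D = h.shape
    dk = D // n_heads
    Wq, Wk, Wv = (params[k] for k in ("Wq", "Wk", "Wv"))
    Q = (h @ Wq.W.data + Wq.b.data).reshape(M, n_heads, dk)
    K = (h @ Wk.W.data + Wk.b.data).reshape(M, n_heads, dk)
    dense_attr = graph.edge_attr_dense()
    adj = graph.adjacency()
    out = np.zeros((n_heads, M, M))
    for hd in range(n_heads):
        for i in range(M):
            nbrs = np.nonzero(adj[i])[0]
            if len(nbrs) == 0:
                out[hd, i, i] = 1.0
                continue
            scores = []
            for j in nbrs:
                e = params["edge_mlp"](Tensor(dense_attr[i, j][None])).data
                phi = e.reshape(n_heads, dk)[hd]
                scores.append(float((Q[i, hd] + phi) @ K[j, hd]) / np.sqrt(dk))
            w = np.exp(scores - np.max(scores))
            w /= w.sum()
            out[hd, i, nbrs] = w
    return out


class TestEdgeAwareAttention:
    def test_matches_dense_bruteforce_oracle(self, tiny_model):
        for n_vert in (2, 3, 5):
            s = phantom.generate_samples(n=1, seed=n_vert)[0]
            lm = s.landmarks
            sub = LandmarkSet(lm.centroids[:n_vert], lm.widths[:n_vert],
                              lm.disc_heights[:n_vert - 1], lm.si_distances)
            g = build_graph(sub)
            assert g.n_nodes <= 9
            h = np.random.default_rng(0).normal(size=(g.n_nodes, 32))
            params = _layer_params(tiny_model)
            got = edge_aware_attention(Tensor(h), g, params, 4)
            want = _dense_reference_attention(h, g, params, 4)
            assert np.max(np.abs(got - want)) < 1e-6

    def test_reduces_to_standard_attention_when_phi_zero(self, sample_and_graph, tiny_model):
        _, g = sample_and_graph
        h = np.random.default_rng(1).normal(size=(g.n_nodes, 32))
        params = dict(_layer_params(tiny_model))
        zero_mlp = MLP([3, 32], np.random.default_rng(0))
        zero_mlp.layers[0].W.data[:] = 0.0
        zero_mlp.layers[0].b.data[:] = 0.0
        params["edge_mlp"] = zero_mlp
        got = edge_aware_attention(Tensor(h), g, params, 4)
        # reference: plain scaled dot product masked to the adjacency
        Wq, Wk = params["Wq"], params["Wk"]
        Q = (h @ Wq.W.data + Wq.b.data).reshape(g.n_nodes, 4, 8)
        K = (h @ Wk.W.data + Wk.b.data).reshape(g.n_nodes, 4, 8)
        adj = g.adjacency()
        for hd in range(4):
            S = Q[:, hd] @ K[:, hd].T / np.sqrt(8)
            S[~adj] = -np.inf
            W = np.exp(S - S.max(axis=1, keepdims=True))
            W /= W.sum(axis=1, keepdims=True)
            assert np.max(np.abs(got[hd] - W)) < 1e-6

    def test_rows_sum_to_one(self, sample_and_graph, tiny_model):
        _, g = sample_and_graph
        h = np.random.default_rng(2).normal(size=(g.n_nodes, 32))
        w = edge_aware_attention(Tensor(h), g, _layer_params(tiny_model), 4)
        assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-6)

    def test_single_neighbor_weight_one(self, tiny_model):
        lm = LandmarkSet(np.array([[60.0, 30.0], [62.0, 60.0]]), np.array([20.0, 20.0]),
                         np.array([[8.0, 8.0]]), np.array([3.0, 3.0]))
        g = build_graph(lm)  # 3-node chain: ends have exactly one neighbor
        h = np.random.default_rng(3).normal(size=(3, 32))
        w = edge_aware_attention(Tensor(h), g, _layer_params(tiny_model), 4)
        assert np.allclose(w[:, 0, 1], 1.0)
        assert np.allclose(w[:, 2, 1], 1.0)

    def test_isolated_node_self_attention_fallback(self, tiny_model):
        g = build_graph(_single_vertebra())
        h = np.random.default_rng(4).normal(size=(1, 32))
        w = edge_aware_attention(Tensor(h), g, _layer_params(tiny_model), 4)
        assert np.allclose(w[:, 0, 0], 1.0)

    def test_edge_attribute_sensitivity(self, sample_and_graph, tiny_model):
        _, g = sample_and_graph
        h = np.random.default_rng(5).normal(size=(g.n_nodes, 32))
        base = edge_aware_attention(Tensor(h), g, _layer_params(tiny_model), 4)
        import copy

        g2 = copy.deepcopy(g)
        g2.edge_attrs[0, 0] += 5.0  # perturb one edge's distance attribute
        new = edge_aware_attention(Tensor(h), g2, _layer_params(tiny_model), 4)
        assert np.max(np.abs(base - new)) > 1e-6


class TestTransformerForward:
    def test_permutation_equivariance(self, sample_and_graph, tiny_model):
        import copy

        _, g = sample_and_graph
        M = g.n_nodes
        h = np.random.default_rng(6).normal(size=(M, 32))
        out = transformer_forward(Tensor(h), g, tiny_model.transformer).data
        perm = np.random.default_rng(7).permutation(M)
        gp = copy.deepcopy(g)
        gp.positions = g.positions[perm]
        inv = np.argsort(perm)
        gp.edges = np.array([[inv[i], inv[j]] for i, j in g.edges])
        out_p = transformer_forward(Tensor(h[perm]), gp, tiny_model.transformer).data
        assert np.allclose(out_p, out[perm], atol=1e-8)

    def test_outputs_finite_over_many_seeds(self, sample_and_graph, tiny_model):
        _, g = sample_and_graph
        for seed in range(100):
            h = np.random.default_rng(seed).normal(size=(g.n_nodes, 32))
            out = transformer_forward(Tensor(h), g, tiny_model.transformer)
            assert np.all(np.isfinite(out.data))

    def test_batched_equals_per_sample_loop(self, tiny_model):
        samples = phantom.generate_samples(n=6, seed=21)
        graphs = [build_graph(s.landmarks) for s in samples]
        summaries = np.stack([s.true_indices.summary() for s in samples])
        batch = tiny_model.prepare_batch([s.image for s in samples], graphs, summaries)
        logits_b, reg_b = tiny_model.forward_batch(batch)
        for k in range(len(samples)):
            single = tiny_model.prepare_batch([samples[k].image], [graphs[k]],
                                              summaries[k:k + 1])
            logits_s, reg_s = tiny_model.forward_batch(single)
            assert np.max(np.abs(logits_s.data[0] - logits_b.data[k])) < 1e-6
            assert np.max(np.abs(reg_s.data[0] - reg_b.data[k])) < 1e-6


class TestPredict:
    def test_logits_shape_and_softmax_normalization(self, sample_and_graph, tiny_model):
        _, g = sample_and_graph
        h = Tensor(np.random.default_rng(8).normal(size=(g.n_nodes, 36)))
        logits, reg = predict(h, tiny_model.heads)
        assert logits.shape == (1, 6) and reg.shape == (1, 4)
        p = ag.softmax(logits, axis=-1).data
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_duplicated_graph_rows_identical(self, tiny_model):
        samples = phantom.generate_samples(n=2, seed=33)
        s = samples[0]
        g = build_graph(s.landmarks)
        summ = s.true_indices.summary()
        batch = tiny_model.prepare_batch([s.image, s.image], [g, g],
                                         np.stack([summ, summ]))
        logits, _ = tiny_model.forward_batch(batch)
        assert np.allclose(logits.data[0], logits.data[1])

    def test_empty_graph_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="empty"):
            predict(Tensor(np.zeros((0, 36))), tiny_model.heads)

    def test_checkpoint_roundtrip(self, tiny_model, tmp_path, sample_and_graph):
        s, g = sample_and_graph
        path = tmp_path / "model.npz"
        tiny_model.save(path)
        loaded = SpineGraphModel.load(path)
        summ = s.true_indices.summary()[None]
        a = tiny_model.predict_proba([s.image], [g], summ)
        b = loaded.predict_proba([s.image], [g], summ)
        assert np.allclose(a, b)
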