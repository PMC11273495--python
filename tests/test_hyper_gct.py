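import numpy as np
import pytest

from hgtmda import hyper_gct as hg
from hgtmda._autograd import Tensor


class TestCosineWeights:
    def test_self_cosine_one(self):
        v = np.array([[1.0, 2.0, 3.0]])
        assert np.isclose(hg.cosine_weights(v, v)[0, 0], 1.0)

    def test_orthogonal_zero(self):
        assert np.isclose(
            hg.cosine_weights(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]))[0, 0],
            0.0)

    def test_hand_value(self):
        C = hg.cosine_weights(np.array([[1.0, 2.0]]), np.array([[2.0, 1.0]]))
        assert np.isclose(C[0, 0], 0.8)

    def test_scale_invariance_and_range(self, rng):
        X, Q = rng.normal(size=(6, 4)), rng.normal(size=(3, 4))
        C = hg.cosine_weights(X, Q)
        assert np.allclose(C, hg.cosine_weights(5 * X, 0.1 * Q), atol=1e-12)
        assert C.min() >= -1 and C.max() <= 1

    def test_zero_row_convention(self, rng):
        X = np.vstack([np.zeros(4), rng.normal(size=4)])
        C = hg.cosine_weights(X, rng.normal(size=(2, 4)))
        assert np.all(C[0] == 0)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            hg.cosine_weights(rng.normal(size=(2, 3)), rng.normal(size=(2, 4)))

    def test_tensor_version_matches_numpy(self, rng):
        X, Q = rng.normal(size=(5, 4)), rng.normal(size=(3, 4))
        C = hg.cosine_weights_t(Tensor(X), Tensor(Q)).data
        assert np.allclose(C, hg.cosine_weights(X, Q), atol=1e-6)


class TestAssembleHypergraph:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.Xm = rng.normal(size=(3, 4))
        self.Xd = rng.normal(size=(2, 4))
        self.Q = rng.normal(size=(1, 4))

    def test_supernode_coupled_to_all_nodes_when_cosines_positive(self):
        Xm, Xd = np.abs(self.Xm), np.abs(self.Xd)
        Q = np.abs(self.Q)
        b = hg.assemble_hypergraph(Xm, Xd, Q, [(0, 0)])
        sup = b.A_hyper[-1]
        assert np.all(sup[:5] > 0)  # connected to all 3+2 entity nodes

    def test_no_known_pairs_zero_bipartite_block(self):
        b = hg.assemble_hypergraph(self.Xm, self.Xd, self.Q, [])
        assert np.all(b.A_hyper[:3, 3:5] == 0)

    def test_negative_cosines_clipped(self):
        b = hg.assemble_hypergraph(self.Xm, self.Xd, self.Q, [])
        assert b.A_hyper.min() >= 0
        assert b.C_mq.min() < 0  # raw cosines keep their sign

    def test_symmetry_and_empty_within_type_blocks(self):
        b = hg.assemble_hypergraph(self.Xm, self.Xd, self.Q, [(1, 0), (2, 1)])
        A = b.A_hyper
        assert np.allclose(A, A.T)
        assert np.all(A[:3, :3] == 0) and np.all(A[3:5, 3:5] == 0)
        assert A[1, 3] == 1.0 and A[2, 4] == 1.0

    def test_leakage_guard(self):
        with pytest.raises(ValueError, match="leak"):
            hg.assemble_hypergraph(self.Xm, self.Xd, self.Q, [(0, 0), (1, 1)],
                                   forbidden_pairs=[(1, 1)])


def floyd_warshall(A, cap):
    n = len(A)
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0)
    D[A > 0] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                D[i, j] = min(D[i, j], D[i, k] + D[k, j])
    D[~np.isfinite(D)] = cap
    return np.minimum(D, cap)


class TestShortestPath:
    def test_chain_distances(self):
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0.]])
        assert np.array_equal(hg.shortest_path_matrix(A),
                              [[0, 1, 2], [1, 0, 1], [2, 1, 0]])

    def test_disconnected_pair_capped(self):
        A = np.zeros((2, 2))
        D = hg.shortest_path_matrix(A, max_sp=8)
        assert D[0, 1] == 8 and D[0, 0] == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_floyd_warshall(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        A = (rng.random((n, n)) < 0.3) * rng.random((n, n))
        A = np.triu(A, 1)
        A = A + A.T
        D = hg.shortest_path_matrix(A, max_sp=8)
        assert np.array_equal(D, floyd_warshall(A, 8))
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)

    def test_triangle_inequality(self, rng):
        A = (rng.random((10, 10)) < 0.25).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        D = hg.shortest_path_matrix(A, max_sp=8)
        for k in range(10):
            assert np.all(D <= D[:, [k]] + D[[k], :] + 1e-12)


class TestSpBiasedAttention:
    def test_zero_qk_uniform_average(self, rng):
        H = rng.normal(size=(4, 6))
        WV = rng.normal(size=(6, 3))
        out, attns = hg.sp_biased_attention(
            H, [(np.zeros((6, 3)), np.zeros((6, 3)), WV)], np.zeros((4, 4)),
            bias=np.zeros((4, 4)))
        assert np.allclose(attns[0], 0.25)
        assert np.allclose(out, np.tile((H @ WV).mean(axis=0), (4, 1)))

    def test_masked_limit_returns_value_rows(self, rng):
        H = rng.normal(size=(3, 4))
        WQ, WK, WV = (rng.normal(size=(4, 2)) for _ in range(3))
        bias = np.full((3, 3), -np.inf)
        np.fill_diagonal(bias, 0.0)
        out, attns = hg.sp_biased_attention(H, [(WQ, WK, WV)],
                                            np.zeros((3, 3)), bias=bias)
        assert np.allclose(out, H @ WV)

    def test_three_node_hand_softmax(self):
        H = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        W = np.eye(2) * 0.5
        Dphi = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        out, attns = hg.sp_biased_attention(H, [(W, W, W)], Dphi)
        logits = (H @ W) @ (H @ W).T / np.sqrt(2) + Dphi
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        expect = (e / e.sum(axis=1, keepdims=True)) @ (H @ W)
        assert np.allclose(out, expect)

    def test_nan_input_rejected(self):
        H = np.array([[np.nan, 1.0]])
        with pytest.raises(ValueError):
            hg.sp_biased_attention(H, [], np.zeros((1, 1)))


def toy_encoder(n=6, dim=8, rng=None, **kw):
    rng = rng or np.random.default_rng(0)
    cfg = hg.GCTConfig(n_layers=2, n_heads=2, d_model=dim, ffn_hidden=16,
                       max_sp=8, supernodes=2, dropout=0.0, **kw)
    return hg.GCTEncoder(cfg, rng), cfg


def toy_graph(n, rng):
    A = (rng.random((n, n)) < 0.4) * rng.random((n, n))
    A = np.triu(A, 1)
    A = A + A.T
    return A


class TestGCTEncoder:
    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError):
            hg.GCTConfig(n_heads=3, d_model=8)

    def test_attention_rows_sum_to_one_every_head_and_layer(self, rng):
        enc, cfg = toy_encoder(rng=rng)
        A = toy_graph(6, rng)
        H0 = Tensor(rng.normal(size=(6, 8)))
        D = hg.shortest_path_matrix(A, cfg.max_sp)
        enc.forward(H0, Tensor(A), D)
        assert len(enc.last_attention) == cfg.n_layers
        for layer in enc.last_attention:
            assert len(layer) == cfg.n_heads
            for attn in layer:
                assert np.allclose(attn.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_update_limit_reduces_to_normalised_gcn_sublayer(self, rng):
        enc, cfg = toy_encoder(rng=rng)
        for lst in (enc.WO, enc.W2):
            for W in lst:
                W.data[:] = 0.0
        A = toy_graph(6, rng)
        H0 = Tensor(rng.normal(size=(6, 8)))
        D = hg.shortest_path_matrix(A, cfg.max_sp)
        out = enc.layer_forward(H0, enc._norm_adj_t(Tensor(A)), D, 0)
        Ahat = hg.GCTEncoder._norm_adj_t(Tensor(A)).data
        Hg = np.maximum(Ahat @ H0.data @ enc.Wg[0].data, 0) + H0.data
        # with zeroed output projections the residual/LayerNorm path dominates
        mu = Hg.mean(axis=1, keepdims=True)
        sd = np.sqrt(Hg.var(axis=1, keepdims=True) + 1e-5)
        assert np.allclose(out.data, (Hg - mu) / sd, atol=1e-4)

    def test_layer_norm_row_statistics(self, rng):
        enc, cfg = toy_encoder(rng=rng)
        A = toy_graph(6, rng)
        out = enc.forward(Tensor(rng.normal(size=(6, 8))), Tensor(A),
                          hg.shortest_path_matrix(A, cfg.max_sp))
        assert np.allclose(out.data.mean(axis=1), 0.0, atol=1e-6)
        assert np.allclose(out.data.var(axis=1), 1.0, atol=1e-3)

    def test_matches_straight_line_reference(self, rng):
        """Two stacked layers reproduce an independently coded forward pass."""
        enc, cfg = toy_encoder(rng=rng)
        A = toy_graph(6, rng)
        D = hg.shortest_path_matrix(A, cfg.max_sp)
        H0 = rng.normal(size=(6, 8))
        out = enc.forward(Tensor(H0), Tensor(A), D).data

        def ln(X):
            mu = X.mean(axis=1, keepdims=True)
            return (X - mu) / np.sqrt(X.var(axis=1, keepdims=True) + 1e-5)

        Ahat = hg.GCTEncoder._norm_adj_t(Tensor(A)).data
        H = H0
        dh = cfg.d_model // cfg.n_heads
        for l in range(cfg.n_layers):
            Hg = np.maximum(Ahat @ H @ enc.Wg[l].data, 0) + H
            Q, K, V = (Hg @ M[l].data for M in (enc.WQ, enc.WK, enc.WV))
            heads = []
            for h in range(cfg.n_heads):
                s = slice(h * dh, (h + 1) * dh)
                logits = Q[:, s] @ K[:, s].T / np.sqrt(dh) \
                    + enc.dist_bias[l][h].data[D]
                e = np.exp(logits - logits.max(axis=1, keepdims=True))
                heads.append((e / e.sum(axis=1, keepdims=True)) @ V[:, s])
            attn_out = np.concatenate(heads, axis=1) @ enc.WO[l].data
            H1 = ln(Hg + attn_out) * enc.ln_g[l][0].data + enc.ln_b[l][0].data
            F = np.maximum(H1 @ enc.W1[l].data + enc.b1[l].data, 0)
            F = F @ enc.W2[l].data + enc.b2[l].data
            H = ln(H1 + F) * enc.ln_g[l][1].data + enc.ln_b[l][1].data
        assert np.allclose(out, H, atol=1e-10)

    def test_encode_shapes_and_purity(self, rng):
        enc, cfg = toy_encoder(rng=rng)
        Xm = Tensor(rng.normal(size=(3, 8)))
        Xd = Tensor(rng.normal(size=(2, 8)))
        Q = Tensor(rng.normal(size=(1, 8)))
        A = toy_graph(6, rng)
        D = hg.shortest_path_matrix(A, cfg.max_sp)
        Zm, Zd = enc.encode(Xm, Xd, Q, Tensor(A), D)
        assert Zm.shape == (3, 8) and Zd.shape == (2, 8)
        Zm2, Zd2 = enc.encode(Xm, Xd, Q, Tensor(A), D)
        assert np.array_equal(Zm.data, Zm2.data)

    def test_permutation_equivariance(self, rng):
        enc, cfg = toy_encoder(n=7, rng=rng)
        A = toy_graph(7, rng)
        D = hg.shortest_path_matrix(A, cfg.max_sp)
        H0 = rng.normal(size=(7, 8))
        out = enc.forward(Tensor(H0), Tensor(A), D).data
        perm = rng.permutation(7)
        out_p = enc.forward(Tensor(H0[perm]), Tensor(A[np.ix_(perm, perm)]),
                            D[np.ix_(perm, perm)]).data
        assert np.allclose(out_p, out[perm], atol=1e-10)

    def test_raw_bias_mode_uses_hop_counts(self, rng):
        enc, cfg = toy_encoder(rng=rng, bias_mode="raw")
        A = toy_graph(6, rng)
        D = hg.shortest_path_matrix(A, cfg.max_sp)
        out = enc.forward(Tensor(rng.normal(size=(6, 8))), Tensor(A), D)
        assert out.shape == (6, 8)
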