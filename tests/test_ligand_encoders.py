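"""GAT / CNN / transformer ligand encoders against straight-line oracles."""

import numpy as np
import pytest

from mgbind import featurize as ft
from mgbind import ligand_encoders as le
from mgbind.nn import Tensor

RNG = np.random.default_rng(42)


def leaky(x, s=0.2):
    return np.where(x > 0, x, s * x)


def elu(x):
    return np.where(x > 0, x, np.exp(np.minimum(x, 0)) - 1)


# ------------------------------------------------------------ gat_attention
class TestGatAttention:
    def test_zero_attention_vector(self):
        h = RNG.normal(size=3)
        assert le.gat_attention(h, h, np.zeros(6)) == pytest.approx(0.0)

    def test_symmetric_halves(self):
        h = RNG.normal(size=4)
        u = RNG.normal(size=4)
        a = np.concatenate([u, u])
        expected = leaky(2 * u @ h)
        assert le.gat_attention(h, h, a) == pytest.approx(expected)

    def test_random_case_matches_formula(self):
        h_i, h_j = RNG.normal(size=4), RNG.normal(size=4)
        a = RNG.normal(size=8)
        expected = leaky(a @ np.concatenate([h_i, h_j]))
        assert le.gat_attention(h_i, h_j, a) == pytest.approx(expected)

    def test_not_symmetric_in_general(self):
        h_i, h_j = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        a = np.array([1.0, 2.0, 3.0, 5.0])
        assert le.gat_attention(h_i, h_j, a) != le.gat_attention(h_j, h_i, a)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            le.gat_attention(np.zeros(3), np.zeros(3), np.zeros(5))


# ---------------------------------------------------------------- gat_layer
def brute_force_gat(node_feats, adj, weight, a_src, a_dst):
    """Explicit softmax + weighted-sum oracle, one head."""
    hw = node_feats @ weight
    n = node_feats.shape[0]
    out = np.zeros_like(hw)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j] > 0]
        e = np.array([leaky(float(a_src[:, 0] @ hw[i] + a_dst[:, 0] @ hw[j]))
                      for j in nbrs])
        alpha = np.exp(e - e.max())
        alpha /= alpha.sum()
        out[i] = elu(sum(al * hw[j] for al, j in zip(alpha, nbrs)))
    return out


class TestGatLayer:
    def test_uniform_attention_with_equal_logits(self):
        # a = 0 makes every logit equal; node 0 has members {self, 1, 2}
        feats = RNG.normal(size=(3, 2))
        edges = [(0, 1), (1, 0), (0, 2), (2, 0)]
        w = np.eye(2)
        _, alpha = le.gat_propagate(
            feats, _adj(edges, 3, self_loops=True), w,
            np.zeros((2, 1)), np.zeros((2, 1)))
        np.testing.assert_allclose(alpha[0, [0, 1, 2]], 1 / 3)
        np.testing.assert_allclose(alpha.sum(axis=-1), 1.0, atol=1e-6)

    def test_single_edge_identity_sigma(self):
        # without self-loops the softmax over one neighbour is exactly 1
        feats = RNG.normal(size=(2, 3))
        adj = np.array([[0.0, 1.0], [1.0, 0.0]])
        w = np.eye(3)
        out, _ = le.gat_propagate(feats, adj, w,
                                  RNG.normal(size=(3, 1)),
                                  RNG.normal(size=(3, 1)),
                                  sigma="identity")
        np.testing.assert_allclose(out[0], feats[1], atol=1e-12)
        np.testing.assert_allclose(out[1], feats[0], atol=1e-12)

    def test_path_graph_matches_brute_force(self):
        feats = RNG.normal(size=(3, 4))
        edges = [(0, 1), (1, 0), (1, 2), (2, 1)]
        weight = RNG.normal(size=(4, 4)) * 0.3
        a = RNG.normal(size=8) * 0.3
        out = le.gat_layer(feats, edges, weight, a)
        adj = _adj(edges, 3, self_loops=True)
        expected = brute_force_gat(feats, adj, weight, a[:4, None], a[4:, None])
        np.testing.assert_allclose(out, expected, atol=1e-5)

    def test_isolated_node_no_nan(self):
        feats = RNG.normal(size=(3, 2))
        out = le.gat_layer(feats, [(0, 1), (1, 0)], np.eye(2),
                           RNG.normal(size=4))
        assert np.all(np.isfinite(out))

    def test_edge_to_padding_node_rejected(self):
        with pytest.raises(ValueError, match="padding"):
            le.gat_layer(np.zeros((3, 2)), [(0, 2), (2, 0)], np.eye(2),
                         np.zeros(4), n_real=2)


def _adj(edges, n, self_loops=False):
    adj = np.zeros((n, n))
    for i, j in edges:
        adj[i, j] = 1.0
    if self_loops:
        np.fill_diagonal(adj, 1.0)
    return adj


# --------------------------------------------------------------- gat_encode
@pytest.fixture(scope="module")
def gat_encoder():
    cfg = le.GATConfig(embed_dim=8, out_dim=8, n_heads=2, n_layers=2)
    return le.GATEncoder(cfg, np.random.default_rng(7)).eval()


class TestGatEncode:
    def test_single_atom(self, gat_encoder):
        g = ft.smiles_to_graph("C", max_atoms=4)
        x_g, map_g = le.gat_encode(g, gat_encoder)
        assert x_g.shape == (8,)
        np.testing.assert_allclose(x_g, map_g[0], atol=1e-12)

    def test_padding_invariance(self, gat_encoder):
        g_small = ft.smiles_to_graph("CCO", max_atoms=5)
        g_big = ft.smiles_to_graph("CCO", max_atoms=12)
        x1, _ = le.gat_encode(g_small, gat_encoder)
        x2, _ = le.gat_encode(g_big, gat_encoder)
        np.testing.assert_allclose(x1, x2, atol=1e-9)

    def test_three_atom_chain_matches_layer_oracle(self, gat_encoder):
        g = ft.smiles_to_graph("CCO", max_atoms=3)
        x_g, _ = le.gat_encode(g, gat_encoder)
        # independent composition: lift, 2-head layer (concat), single-head
        # layer, max pool - all via the brute-force oracle
        enc = gat_encoder
        h = g.node_features @ enc.lift.weight.data + enc.lift.bias.data
        adj = g.adjacency(self_loops=True)
        layer1 = enc.layers[0]
        heads = [brute_force_gat(h, adj, layer1.weights[k].data,
                                 layer1.a_src[k].data, layer1.a_dst[k].data)
                 for k in range(2)]
        h1 = np.concatenate(heads, axis=-1)
        layer2 = enc.layers[1]
        h2 = brute_force_gat(h1, adj, layer2.weights[0].data,
                             layer2.a_src[0].data, layer2.a_dst[0].data)
        np.testing.assert_allclose(x_g, h2.max(axis=0), atol=1e-5)

    def test_permutation_invariance(self, gat_encoder):
        g = ft.smiles_to_graph("CC(N)O", max_atoms=6)
        perm = np.array([2, 0, 3, 1])
        feats = g.node_features.copy()
        feats[:4] = g.node_features[perm]
        inv = np.argsort(perm)
        edges = [(int(inv[i]), int(inv[j])) for i, j in g.edges]
        g_perm = ft.MolecularGraph(feats, edges, g.n_real_atoms)
        x1, _ = le.gat_encode(g, gat_encoder)
        x2, _ = le.gat_encode(g_perm, gat_encoder)
        np.testing.assert_allclose(x1, x2, atol=1e-9)


# --------------------------------------------------------------- cnn_encode
@pytest.fixture(scope="module")
def cnn_encoder():
    cfg = le.CNNConfig(embed_dim=6, n_filters=5, kernel_size=3, out_dim=4)
    return le.CNNEncoder(cfg, np.random.default_rng(11)).eval()


class TestCnnEncode:
    def test_zero_everything_gives_bias_output(self):
        cfg = le.CNNConfig(embed_dim=4, n_filters=3, kernel_size=3, out_dim=2)
        enc = le.CNNEncoder(cfg, np.random.default_rng(1)).eval()
        enc.embedding.weight.data[:] = 0.0
        for conv in enc.convs:
            conv.weight.data[:] = 0.0
        codes = ft.LigandCodes(np.array([1, 2, 0, 0]), n_real=2)
        x_c, _ = le.cnn_encode(codes, enc)
        np.testing.assert_allclose(x_c, enc.project.bias.data, atol=1e-12)

    def test_residual_isolation_with_zero_convs(self, cnn_encoder):
        import copy

        enc = copy.deepcopy(cnn_encoder)
        for conv in enc.convs:
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = 0.0
        for norm in enc.norms:
            norm.running_mean[:] = 0.0
            norm.running_var[:] = 1.0
            norm.beta.data[:] = 0.0
            norm.gamma.data[:] = 1.0
        codes = ft.smiles_to_codes("CCO", max_len=8)
        x_c, _ = le.cnn_encode(codes, enc)
        x_seq = enc.embedding.weight.data[codes.codes[:3]]
        pooled = x_seq.max(axis=0)
        expected = pooled @ enc.project.weight.data + enc.project.bias.data
        np.testing.assert_allclose(x_c, expected, atol=1e-9)

    def test_sliding_window_oracle(self, cnn_encoder):
        codes = ft.LigandCodes(np.array([3, 1, 4, 1, 5]), n_real=5)
        x_c, map_c = le.cnn_encode(codes, cnn_encoder)
        enc = cnn_encoder
        x = enc.embedding.weight.data[codes.codes]        # (5, E)
        h = x
        for conv, norm in zip(enc.convs, enc.norms):
            t, cin = h.shape
            cout = conv.weight.shape[2]
            padded = np.zeros((t + 2, cin))
            padded[1:-1] = h
            out = np.zeros((t, cout))
            for pos in range(t):                          # explicit window
                for k in range(3):
                    out[pos] += padded[pos + k] @ conv.weight.data[k]
                out[pos] += conv.bias.data
            out = ((out - norm.running_mean)
                   / np.sqrt(norm.running_var + norm.eps)
                   * norm.gamma.data + norm.beta.data)
            h = np.maximum(out, 0.0)
        residual = x + h
        expected_map = residual @ enc.project.weight.data + enc.project.bias.data
        expected_x = (residual.max(axis=0) @ enc.project.weight.data
                      + enc.project.bias.data)
        np.testing.assert_allclose(map_c, expected_map, atol=1e-5)
        np.testing.assert_allclose(x_c, expected_x, atol=1e-5)

    def test_padding_invariance(self, cnn_encoder):
        x1, _ = le.cnn_encode(ft.smiles_to_codes("CCO", max_len=6),
                              cnn_encoder)
        x2, _ = le.cnn_encode(ft.smiles_to_codes("CCO", max_len=20),
                              cnn_encoder)
        np.testing.assert_allclose(x1, x2, atol=1e-9)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            le.CNNConfig(kernel_size=4)


# ---------------------------------------------------------------- mt_encode
@pytest.fixture(scope="module")
def mt_encoder():
    cfg = le.MTConfig(embed_dim=8, n_heads=1, n_blocks=1, out_dim=4)
    return le.MTEncoder(cfg, vocab_size=10, max_tokens=6,
                        rng=np.random.default_rng(13)).eval()


class TestMtEncode:
    def test_single_token_attention_is_one(self, mt_encoder):
        toks = ft.SubstructureTokens(np.array([2, 0, 0, 0, 0, 0]),
                                     np.array([1, 0, 0, 0, 0, 0]), n_real=1)
        le.mt_encode(toks, mt_encoder)
        att = mt_encoder.blocks[0].msa.last_attention
        assert att[0, 0, 0, 0] == pytest.approx(1.0)

    def test_attention_rows_sum_to_one(self, mt_encoder):
        toks = ft.SubstructureTokens(np.array([1, 2, 3, 0, 0, 0]),
                                     np.array([1, 1, 1, 0, 0, 0]), n_real=3)
        le.mt_encode(toks, mt_encoder)
        att = mt_encoder.blocks[0].msa.last_attention
        np.testing.assert_allclose(att.sum(axis=-1), 1.0, atol=1e-6)

    def test_two_token_qkv_oracle(self, mt_encoder):
        toks = ft.SubstructureTokens(np.array([4, 7, 0, 0, 0, 0]),
                                     np.array([1, 1, 0, 0, 0, 0]), n_real=2)
        x_t, map_t = le.mt_encode(toks, mt_encoder)
        enc = mt_encoder
        ids = np.array([5, 8])  # 1-based shift
        x = enc.embedding.weight.data[ids] + enc.positional.data[:2]
        blk = enc.blocks[0]
        # explicit scaled-dot-product, one head
        qkv = x @ blk.msa.qkv.weight.data + blk.msa.qkv.bias.data
        q, k, v = qkv[:, :8], qkv[:, 8:16], qkv[:, 16:]
        scores = q @ k.T / np.sqrt(8)
        att = np.exp(scores - scores.max(axis=-1, keepdims=True))
        att /= att.sum(axis=-1, keepdims=True)
        msa = (att @ v) @ blk.msa.out.weight.data + blk.msa.out.bias.data
        x_att = _layernorm(np.maximum(
            msa @ blk.fc_att.weight.data + blk.fc_att.bias.data, 0) + x,
            blk.norm1)
        x_mlp = _layernorm(
            x_att @ blk.fc_mlp.weight.data + blk.fc_mlp.bias.data + x_att,
            blk.norm2)
        mlp = np.maximum(x_mlp @ enc.mlp_hidden.weight.data
                         + enc.mlp_hidden.bias.data, 0)
        expected_map = mlp @ enc.mlp_out.weight.data + enc.mlp_out.bias.data
        np.testing.assert_allclose(map_t[:2], expected_map, atol=1e-5)
        pooled = x_mlp.max(axis=0)
        hidden = np.maximum(pooled @ enc.mlp_hidden.weight.data
                            + enc.mlp_hidden.bias.data, 0)
        expected_x = hidden @ enc.mlp_out.weight.data + enc.mlp_out.bias.data
        np.testing.assert_allclose(x_t, expected_x, atol=1e-5)

    def test_padding_invariance(self):
        cfg = le.MTConfig(embed_dim=8, n_heads=2, n_blocks=2, out_dim=4)
        enc_small = le.MTEncoder(cfg, vocab_size=10, max_tokens=4,
                                 rng=np.random.default_rng(3)).eval()
        enc_big = le.MTEncoder(cfg, vocab_size=10, max_tokens=9,
                               rng=np.random.default_rng(99)).eval()
        enc_big.load_state_dict({
            k: (v if k != "param:positional"
                else np.vstack([v, enc_big.positional.data[4:]]))
            for k, v in enc_small.state_dict().items()})
        toks3 = ft.SubstructureTokens(np.array([1, 2, 3, 0]),
                                      np.array([1, 1, 1, 0]), n_real=3)
        toks3_big = ft.SubstructureTokens(np.array([1, 2, 3, 0, 0, 0, 0, 0, 0]),
                                          np.array([1, 1, 1, 0, 0, 0, 0, 0, 0]),
                                          n_real=3)
        x1, _ = le.mt_encode(toks3, enc_small)
        x2, _ = le.mt_encode(toks3_big, enc_big)
        np.testing.assert_allclose(x1, x2, atol=1e-9)

    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            le.MTConfig(embed_dim=9, n_heads=2)


def _layernorm(x, norm):
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    return ((x - mu) / np.sqrt(var + norm.eps) * norm.gamma.data
            + norm.beta.data)


# ------------------------------------------------------- shared invariants
def test_all_outputs_finite_on_random_inputs():
    rng = np.random.default_rng(0)
    cfg = le.GATConfig(embed_dim=6, out_dim=6, n_heads=2)
    enc = le.GATEncoder(cfg, rng).eval()
    for _ in range(50):
        n = int(rng.integers(1, 8))
        feats = rng.normal(size=(8, 78))
        feats[n:] = 0.0
        edges = []
        for i in range(n - 1):
            edges += [(i, i + 1), (i + 1, i)]
        g = ft.MolecularGraph(feats, edges, n)
        x_g, map_g = le.gat_encode(g, enc)
        assert np.all(np.isfinite(x_g)) and np.all(np.isfinite(map_g))
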