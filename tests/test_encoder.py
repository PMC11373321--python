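"""Laplacian positional encoding, gated graph attention and full encoding."""

import numpy as np
import pytest

import morphembed as me
from morphembed.encoder import (add_adapters, cls_adjacency, graph_attention,
                                init_params, laplacian_pe, load_checkpoint,
                                save_checkpoint)
from morphembed.preprocess import FeatureGraph, featurize, center_tree

SMALL = me.EncoderConfig(n_layers=2, d_model=32, n_heads=4, d_k=8,
                         n_eigvecs=6, mlp_hidden=48, seed=3)


def random_tree_adjacency(rng, n):
    """Adjacency of a random labelled tree (Prufer-free: random parent)."""
    adj = np.zeros((n, n))
    for i in range(1, n):
        j = int(rng.integers(i))
        adj[i, j] = adj[j, i] = 1.0
    return adj


class TestLaplacianPE:
    def test_path3_spectrum(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
        _, vals = laplacian_pe(adj, 3, return_eigenvalues=True)
        np.testing.assert_allclose(np.sort(vals), [0.0, 1.0, 2.0], atol=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_zero_eigvec_proportional_to_sqrt_degree(self, seed):
        rng = np.random.default_rng(seed)
        adj = random_tree_adjacency(rng, int(rng.integers(5, 40)))
        vecs, vals = laplacian_pe(adj, 1, return_eigenvalues=True)
        assert abs(vals[0]) < 1e-9
        expected = np.sqrt(adj.sum(axis=1))
        expected /= np.linalg.norm(expected)
        np.testing.assert_allclose(np.abs(vecs[:, 0]), expected, atol=1e-8)

    def test_full_decomposition_recomposes(self):
        rng = np.random.default_rng(0)
        adj = random_tree_adjacency(rng, 12)
        vecs, vals = laplacian_pe(adj, 12, return_eigenvalues=True)
        deg = adj.sum(axis=1)
        L = np.eye(12) - adj / np.sqrt(np.outer(deg, deg))
        np.testing.assert_allclose(vecs @ np.diag(vals) @ vecs.T, L, atol=1e-8)

    def test_matches_dense_eigensolver_oracle(self):
        """Eigenvalues match a dense eigensolver; eigenvectors match up to
        sign for simple eigenvalues and as subspaces for degenerate ones."""
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = int(rng.integers(4, 50))
            adj = random_tree_adjacency(rng, n)
            k = min(6, n)
            vecs, vals = laplacian_pe(adj, k, return_eigenvalues=True)
            deg = adj.sum(axis=1)
            L = np.eye(n) - adj / np.sqrt(np.outer(deg, deg))
            ref_vals, ref_vecs = np.linalg.eigh(L)
            np.testing.assert_allclose(vals, ref_vals[:k], atol=1e-8)
            j = 0
            while j < k:
                group = [j]
                while (group[-1] + 1 < k
                       and ref_vals[group[-1] + 1] - ref_vals[j] < 1e-8):
                    group.append(group[-1] + 1)
                if len(group) == 1:
                    r = ref_vecs[:, j]
                    assert (np.allclose(vecs[:, j], r, atol=1e-6)
                            or np.allclose(vecs[:, j], -r, atol=1e-6))
                else:
                    # degenerate eigenvalue: compare spanned subspaces
                    a, b = vecs[:, group], ref_vecs[:, group]
                    np.testing.assert_allclose(a @ a.T, b @ b.T, atol=1e-6)
                j = group[-1] + 1

    def test_pads_when_k_exceeds_n(self):
        adj = np.array([[0, 1], [1, 0]], float)
        vecs = laplacian_pe(adj, 5)
        assert vecs.shape == (2, 5)
        assert np.all(vecs[:, 2:] == 0)

    def test_rejects_asymmetric(self):
        adj = np.array([[0, 1], [0, 0]], float)
        with pytest.raises(ValueError, match="symmetric"):
            laplacian_pe(adj, 1)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(5)
        adj = random_tree_adjacency(rng, 20)
        a = laplacian_pe(adj, 4)
        b = laplacian_pe(adj, 4)
        np.testing.assert_array_equal(a, b)


def vanilla_attention_oracle(x, params, cfg, layer=0):
    """Independent multi-head scaled-dot-product attention (no graph term)."""
    n = x.shape[0]
    qkv = x @ params[f"layer{layer}.attn.w_qkv"] + params[f"layer{layer}.attn.b_qkv"]
    qkv = qkv.reshape(n, 3, cfg.n_heads, cfg.d_k)
    heads = []
    for h in range(cfg.n_heads):
        q, k, v = qkv[:, 0, h], qkv[:, 1, h], qkv[:, 2, h]
        scores = q @ k.T / np.sqrt(cfg.d_k)
        scores -= scores.max(axis=1, keepdims=True)
        w = np.exp(scores)
        w /= w.sum(axis=1, keepdims=True)
        heads.append(w @ v)
    out = np.concatenate(heads, axis=1)
    return out @ params[f"layer{layer}.attn.w_out"] \
        + params[f"layer{layer}.attn.b_out"]


class TestGraphAttention:
    @pytest.mark.parametrize("seed", range(20))
    def test_gamma_zero_reduces_to_vanilla_attention(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 31))
        x = rng.normal(size=(n, SMALL.d_model))
        adj = random_tree_adjacency(rng, n)
        params = init_params(SMALL)
        params["layer0.attn.b_gate"] = np.array([0.0, -1e4])  # lam=1, gam=0
        out = graph_attention(x, adj, params, SMALL)
        ref = vanilla_attention_oracle(x, params, SMALL)
        np.testing.assert_allclose(out, ref, atol=1e-6)

    def test_lambda_zero_is_adjacency_softmax(self):
        rng = np.random.default_rng(7)
        n = 9
        x = rng.normal(size=(n, SMALL.d_model))
        adj = cls_adjacency(random_tree_adjacency(rng, n - 1))
        params = init_params(SMALL)
        params["layer0.attn.b_gate"] = np.array([-1e4, 0.0])  # lam=0, gam=1
        out, weights = graph_attention(x, adj, params, SMALL,
                                       return_weights=True)
        expected = np.exp(adj)
        expected /= expected.sum(axis=1, keepdims=True)
        for h in range(SMALL.n_heads):
            np.testing.assert_allclose(weights[h], expected, atol=1e-12)
        assert np.all(np.isfinite(out))

    def test_attention_rows_are_probability_vectors(self):
        rng = np.random.default_rng(9)
        n = 15
        x = rng.normal(size=(n, SMALL.d_model)) * 3
        adj = random_tree_adjacency(rng, n)
        _, weights = graph_attention(x, adj, init_params(SMALL), SMALL,
                                     return_weights=True)
        np.testing.assert_allclose(weights.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(weights >= 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            graph_attention(np.zeros((4, SMALL.d_model)), np.zeros((3, 3)),
                            init_params(SMALL), SMALL)


class TestEncode:
    def graph(self, seed, n=25):
        spec = me.example_class_specs()["tufted"].with_node_range(n, n)
        return featurize(center_tree(me.generate_neuron(spec, seed)))

    def test_deterministic_bitwise(self):
        g = self.graph(0)
        p = init_params(SMALL)
        c1, n1 = me.encode(g, p, SMALL)
        c2, n2 = me.encode(g, p, SMALL)
        assert np.array_equal(c1, c2) and np.array_equal(n1, n2)

    def test_single_node_graph(self):
        g = FeatureGraph(n=1, features=np.zeros((1, 9)),
                         adjacency=np.zeros((1, 1)),
                         node_ids=np.array([1]))
        g.features[0, 4] = 1.0
        cls, nodes = me.encode(g, init_params(SMALL), SMALL)
        assert cls.shape == (SMALL.d_model,) and np.all(np.isfinite(cls))
        assert nodes.shape == (1, SMALL.d_model)

    def test_permutation_invariance_of_cls(self):
        """Relabelling nodes leaves the CLS embedding unchanged.  Asserted
        only on graphs where every positional-encoding column is
        unambiguous: a repeated eigenvalue leaves the basis defined only up
        to a rotation, and an eigenvector that is antisymmetric under a
        graph automorphism (e.g. twin terminal leaves; sum of cubes = 0)
        admits no node-order-invariant sign at all."""
        p = init_params(SMALL)
        asserted = 0
        for seed in range(15):
            g = self.graph(seed)
            vecs, vals = laplacian_pe(g.adjacency, SMALL.n_eigvecs + 1,
                                      return_eigenvalues=True)
            cubes = np.abs((vecs[:, :SMALL.n_eigvecs] ** 3).sum(axis=0))
            if np.min(np.diff(vals)) < 1e-6 or np.min(cubes) < 1e-8:
                continue
            cls, _ = me.encode(g, p, SMALL)
            rng = np.random.default_rng(seed + 50)
            perm = rng.permutation(g.n)
            gp = FeatureGraph(n=g.n, features=g.features[perm],
                              adjacency=g.adjacency[np.ix_(perm, perm)],
                              node_ids=g.node_ids[perm])
            cls_p, _ = me.encode(gp, p, SMALL)
            np.testing.assert_allclose(cls_p, cls, atol=1e-5)
            asserted += 1
        assert asserted >= 3

    def test_gradcheck_through_full_encoder(self):
        """Backprop through embed+PE+attention+FF matches finite differences."""
        from morphembed._autodiff import Tensor
        from morphembed.encoder import forward
        cfg = me.EncoderConfig(n_layers=1, d_model=8, n_heads=2, d_k=4,
                               n_eigvecs=3, mlp_hidden=10, seed=1)
        g = self.graph(1, n=6)
        base = init_params(cfg)
        for name in ["embed.w0", "layer0.attn.w_qkv", "layer0.attn.w_gate",
                     "cls.token", "pe.w", "layer0.ff.w1"]:
            params = {k: Tensor(v.copy(), requires_grad=(k == name))
                      for k, v in base.items()}
            cls, _ = forward(g, params, cfg)
            (cls * cls).sum().backward()
            analytic = params[name].grad
            arr = base[name].copy()
            flat = arr.reshape(-1)
            idx = np.linspace(0, flat.size - 1, num=min(6, flat.size),
                              dtype=int)
            for i in idx:
                eps = 1e-6
                for sgn in (1, -1):
                    flat[i] += sgn * eps
                    pp = {k: Tensor(v if k != name else arr.reshape(base[name].shape))
                          for k, v in base.items()}
                    c, _ = forward(g, pp, cfg)
                    val = float((c * c).sum())
                    if sgn == 1:
                        hi = val
                    else:
                        lo = val
                    flat[i] -= sgn * eps
                num = (hi - lo) / (2 * eps)
                assert abs(num - analytic.reshape(-1)[i]) < 1e-4 * max(
                    1.0, abs(num))


class TestParamsAndCheckpoints:
    def test_seeded_init(self):
        a, b = init_params(SMALL), init_params(SMALL)
        assert all(np.array_equal(a[k], b[k]) for k in a)
        other = init_params(me.EncoderConfig(
            n_layers=2, d_model=32, n_heads=4, d_k=8, n_eigvecs=6,
            mlp_hidden=48, seed=4))
        assert any(not np.array_equal(a[k], other[k]) for k in a)

    def test_invalid_width_combination(self):
        with pytest.raises(ValueError):
            me.EncoderConfig(d_model=30, n_heads=4, d_k=8)

    def test_adapter_insertion_is_identity(self):
        spec = me.example_class_specs()["sparse"].with_node_range(30, 30)
        g = featurize(center_tree(me.generate_neuron(spec, 2)))
        p = init_params(SMALL)
        cls, _ = me.encode(g, p, SMALL)
        p2, cfg2 = add_adapters(p, SMALL, 8)
        cls2, _ = me.encode(g, p2, cfg2)
        np.testing.assert_array_equal(cls, cls2)

    def test_checkpoint_round_trip(self, tmp_path):
        ck = me.EncoderCheckpoint(init_params(SMALL), SMALL)
        save_checkpoint(ck, tmp_path / "model")
        back = load_checkpoint(tmp_path / "model")
        assert back.config == SMALL
        assert all(np.array_equal(back.params[k], ck.params[k])
                   for k in ck.params)

    def test_checkpoint_shape_mismatch_detected(self, tmp_path):
        ck = me.EncoderCheckpoint(init_params(SMALL), SMALL)
        save_checkpoint(ck, tmp_path / "model")
        wrong = me.EncoderConfig(n_layers=2, d_model=64, n_heads=4, d_k=16,
                                 n_eigvecs=6, mlp_hidden=48, seed=3)
        (tmp_path / "model.json").write_text(
            (tmp_path / "model.json").read_text()
            .replace('"d_model": 32', '"d_model": 64')
            .replace('"d_k": 8', '"d_k": 16'))
        with pytest.raises(ValueError, match="shape"):
            load_checkpoint(tmp_path / "model")
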