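"""Encoder correctness: adjacency normalization, GCN/attention oracles,
equivariance, variants, fusion head and checkpoints."""

import itertools
from dataclasses import replace

import numpy as np
import pytest

from molfuse import make_variant
from molfuse.model import (
    FittedModel,
    ModelConfig,
    MolFuseNetwork,
    _make_cache,
    featurize_record,
    forward,
    gcn_layer,
    load_checkpoint,
    normalize_adjacency,
    save_checkpoint,
    schema_hash,
)
from molfuse.nn import MultiHeadSelfAttention, Tensor
from conftest import random_rigid_motion


def all_small_graphs(max_nodes=5):
    """Every undirected simple graph on 1..max_nodes nodes (upto ~1000)."""
    for n in range(1, max_nodes + 1):
        pairs = list(itertools.combinations(range(n), 2))
        for bits in range(2 ** len(pairs)):
            A = np.zeros((n, n))
            for p, (i, j) in enumerate(pairs):
                if bits >> p & 1:
                    A[i, j] = A[j, i] = 1.0
            yield A


class TestNormalizeAdjacency:
    def test_single_node(self):
        assert np.array_equal(normalize_adjacency(np.zeros((1, 1))), np.ones((1, 1)))

    def test_two_node_edge(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert np.allclose(normalize_adjacency(A), np.full((2, 2), 0.5))

    def test_disconnected_nodes_identity(self):
        assert np.allclose(normalize_adjacency(np.zeros((2, 2))), np.eye(2))

    def test_matches_dense_oracle_on_all_small_graphs(self):
        # brute-force: D̃^{-1/2}(A+I)D̃^{-1/2} evaluated with explicit matrices
        for n in (1, 2, 3, 4, 5):
            rng = np.random.default_rng(n)
            for _ in range(40):
                A = (rng.random((n, n)) < 0.4).astype(float)
                A = np.triu(A, 1)
                A = A + A.T
                A_tilde = A + np.eye(n)
                D = np.diag(A_tilde.sum(axis=1))
                oracle = np.linalg.inv(np.sqrt(D)) @ A_tilde @ np.linalg.inv(np.sqrt(D))
                assert np.allclose(normalize_adjacency(A), oracle, atol=1e-12)

    def test_symmetry_preserved(self):
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        N = normalize_adjacency(A)
        assert np.allclose(N, N.T)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            normalize_adjacency(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            normalize_adjacency(np.array([[0, 1], [0, 0]], dtype=float))
        with pytest.raises(ValueError):
            normalize_adjacency(np.eye(2))


class TestGCNLayerOracle:
    def test_identity_case(self):
        H = np.array([[1.0, -2.0]])
        out = gcn_layer(H, np.ones((1, 1)), np.eye(2), activation="none")
        assert np.allclose(out, H)

    def test_zero_features_zero_output(self):
        out = gcn_layer(np.zeros((3, 4)), np.eye(3), np.ones((4, 2)))
        assert np.all(out == 0)

    def test_matches_triple_product_on_small_graphs(self):
        rng = np.random.default_rng(0)
        for A in itertools.islice(all_small_graphs(4), 0, 200, 7):
            n = A.shape[0]
            A_hat = normalize_adjacency(A)
            H = rng.normal(size=(n, 3))
            W = rng.normal(size=(3, 2))
            assert np.allclose(gcn_layer(H, A_hat, W), np.maximum(A_hat @ H @ W, 0), atol=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            gcn_layer(np.zeros((3, 4)), np.eye(2), np.eye(4))


class TestAttentionOracle:
    def _attn(self, hidden=8, heads=1):
        return MultiHeadSelfAttention(np.random.default_rng(0), hidden, heads)

    def test_rows_sum_to_one(self):
        attn = self._attn(heads=4)
        attn(Tensor(np.random.default_rng(1).normal(size=(5, 8))))
        assert np.allclose(attn.last_weights.sum(axis=-1), 1.0)

    def test_identical_keys_give_uniform_weights(self):
        attn = self._attn(heads=2)
        H = np.tile(np.random.default_rng(2).normal(size=(1, 8)), (6, 1))
        attn(Tensor(H))
        assert np.allclose(attn.last_weights, 1.0 / 6.0)

    def test_matches_scalar_softmax_oracle(self):
        # hand-computed two-row single-head attention
        from molfuse.nn.autograd import multi_head_attention

        Q = np.array([[1.0, 0.0], [0.0, 2.0]])
        K = np.array([[1.0, 1.0], [0.0, 1.0]])
        V = np.array([[1.0, 2.0], [3.0, 4.0]])
        out, P = multi_head_attention(Tensor(Q), Tensor(K), Tensor(V), heads=1)
        scale = 1 / np.sqrt(2)
        S = Q @ K.T * scale
        expected_P = np.exp(S - S.max(axis=1, keepdims=True))
        expected_P /= expected_P.sum(axis=1, keepdims=True)
        assert np.allclose(P[0], expected_P, atol=1e-12)
        assert np.allclose(out.data, expected_P @ V, atol=1e-12)

    def test_oracle_on_all_graph_sizes_up_to_five(self):
        from molfuse.nn.autograd import multi_head_attention

        rng = np.random.default_rng(3)
        for n in range(1, 6):
            Q, K, V = (rng.normal(size=(n, 4)) for _ in range(3))
            out, P = multi_head_attention(Tensor(Q), Tensor(K), Tensor(V), heads=2)
            for h in range(2):
                cols = slice(h * 2, (h + 1) * 2)
                S = Q[:, cols] @ K[:, cols].T / np.sqrt(2)
                eP = np.exp(S - S.max(axis=1, keepdims=True))
                eP /= eP.sum(axis=1, keepdims=True)
                assert np.allclose(P[h], eP, atol=1e-12)
                assert np.allclose(out.data[:, cols], eP @ V[:, cols], atol=1e-12)


class TestEGNNUpdate:
    def _setup(self, coord_update="mean"):
        from molfuse.nn import EGNNLayer

        layer = EGNNLayer(np.random.default_rng(0), hidden=8, coord_update=coord_update)
        rng = np.random.default_rng(1)
        H = Tensor(rng.normal(size=(4, 8)))
        X = rng.normal(size=(4, 3))
        src = np.array([0, 1, 1, 2])
        dst = np.array([1, 0, 2, 1])
        return layer, H, X, src, dst

    def test_isolated_node_coordinates_unchanged(self):
        layer, H, X, src, dst = self._setup()
        _, Xo = layer(H, Tensor(X), src, dst)
        assert np.allclose(Xo.data[3], X[3])  # node 3 has no edges

    def test_translation_equivariance(self):
        layer, H, X, src, dst = self._setup()
        t = np.array([2.0, -1.0, 0.5])
        Ho, Xo = layer(H, Tensor(X), src, dst)
        Ht, Xt = layer(H, Tensor(X + t), src, dst)
        assert np.allclose(Ht.data, Ho.data)
        assert np.allclose(Xt.data, Xo.data + t)

    def test_rotation_equivariance(self):
        layer, H, X, src, dst = self._setup()
        Q, _ = random_rigid_motion(np.random.default_rng(5))
        Ho, Xo = layer(H, Tensor(X), src, dst)
        Hr, Xr = layer(H, Tensor(X @ Q.T), src, dst)
        assert np.allclose(Hr.data, Ho.data)
        assert np.allclose(Xr.data, Xo.data @ Q.T)

    def test_sum_mode_matches_plain_weighted_sum(self):
        layer, H, X, src, dst = self._setup(coord_update="sum")
        _, Xo = layer(H, Tensor(X), src, dst)
        # node 1 has two incoming edges; its delta is an unnormalized sum
        assert Xo.data.shape == X.shape


class TestVariants:
    def test_make_variant_enum(self):
        assert make_variant("Mini").use_egnn is False
        assert make_variant("Full").use_egnn is True
        with pytest.raises(ValueError):
            make_variant("tiny")

    def test_mini_blocks_contain_attention_only(self):
        net = MolFuseNetwork(np.random.default_rng(0), make_variant("Mini", hidden_dim=32))
        assert all(egnn is None for egnn, _, _ in net.atom_channel.blocks)

    def test_fp_variant_has_no_graph_channels(self):
        net = MolFuseNetwork(np.random.default_rng(0), make_variant("FP", hidden_dim=32))
        assert net.atom_channel is None and net.bond_channel is None

    def test_default_attention_heads_is_four(self):
        assert ModelConfig().attention_heads == 4
        net = MolFuseNetwork(np.random.default_rng(0), make_variant("Atom", hidden_dim=32))
        assert all(attn.heads == 4 for _, attn, _ in net.atom_channel.blocks)

    def test_head_must_divide_hidden(self):
        with pytest.raises(ValueError):
            ModelConfig(hidden_dim=30, attention_heads=4)


def _fitted(variant="Full", task_type="classification", seed=0, **kw):
    config = make_variant(variant, task_type=task_type, hidden_dim=32, encoder_blocks=2, **kw)
    network = MolFuseNetwork(np.random.default_rng(seed), config)
    return FittedModel(config=config, network=network, schema=schema_hash(config))


class TestForward:
    def test_classification_outputs_are_probabilities(self, fixture_molecules):
        fitted = _fitted()
        preds = forward(fixture_molecules[:8], fitted)
        assert preds.shape == (8, 1)
        assert np.all((preds >= 0) & (preds <= 1))

    def test_fp_variant_ignores_coordinates(self, fixture_molecules):
        fitted = _fitted("FP")
        rec = fixture_molecules[0]
        moved = replace(rec, coords=rec.coords + 3.0)
        assert np.array_equal(forward([rec], fitted), forward([moved], fitted))

    def test_batch_independence(self, fixture_molecules):
        fitted = _fitted()
        single = forward(fixture_molecules[:1], fitted)
        batch = forward(fixture_molecules[:6], fitted)
        assert np.allclose(single[0], batch[0], atol=1e-10)

    def test_empty_bond_graph_is_finite(self, methane):
        fitted = _fitted()
        pred = forward([methane], fitted)
        assert np.isfinite(pred).all()

    def test_rigid_motion_invariance(self, fixture_molecules):
        fitted = _fitted()
        rng = np.random.default_rng(0)
        for rec in fixture_molecules[:5]:
            Q, t = random_rigid_motion(rng)
            moved = replace(rec, coords=rec.coords @ Q.T + t)
            a, b = forward([rec], fitted), forward([moved], fitted)
            assert np.max(np.abs(a - b)) <= 1e-5 * max(np.max(np.abs(a)), 1e-12)

    def test_atom_permutation_invariance(self, fixture_molecules):
        fitted = _fitted()
        config = fitted.config
        rng = np.random.default_rng(1)
        for rec in fixture_molecules[:5]:
            fm = featurize_record(rec, config)
            base = fitted.predict_features([fm])
            n, m = fm.atom_graph.n_nodes, fm.bond_graph.n_nodes
            p = rng.permutation(n)
            P = np.eye(n)[p]
            ag = replace(fm.atom_graph, adjacency=P @ fm.atom_graph.adjacency @ P.T,
                         features=fm.atom_graph.features[p], coords=fm.atom_graph.coords[p])
            q = rng.permutation(m)
            Pb = np.eye(m)[q]
            bg = replace(fm.bond_graph, adjacency=Pb @ fm.bond_graph.adjacency @ Pb.T,
                         features=fm.bond_graph.features[q], coords=fm.bond_graph.coords[q])
            fm2 = replace(fm, atom_graph=ag, bond_graph=bg,
                          atom_cache=_make_cache(ag, config.egnn_neighborhood),
                          bond_cache=_make_cache(bg, config.egnn_neighborhood))
            assert np.allclose(fitted.predict_features([fm2]), base, atol=1e-9)

    def test_coordinate_rows_preserved_through_blocks(self, fixture_molecules):
        # the CLS contract: attention sees n+1 rows, geometry sees n rows
        fitted = _fitted()
        attn = fitted.attention_for(fixture_molecules[0])
        n = fixture_molecules[0].n_heavy
        for maps in attn["atom"]:
            assert maps.shape[1] == n + 1


class TestCheckpoint:
    def test_round_trip_predictions(self, fixture_molecules, tmp_path):
        fitted = _fitted()
        path = str(tmp_path / "model.npz")
        save_checkpoint(fitted, path)
        loaded = load_checkpoint(path)
        assert np.allclose(
            forward(fixture_molecules[:3], loaded), forward(fixture_molecules[:3], fitted)
        )

    def test_schema_mismatch_fails_loudly(self, tmp_path):
        fitted = _fitted()
        fitted.schema = "bogus_hash"
        path = str(tmp_path / "model.npz")
        save_checkpoint(fitted, path)
        with pytest.raises(ValueError, match="schema"):
            load_checkpoint(path)
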