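"""Equivariance and closed-form behavior of the geometric layers."""

import numpy as np
import pytest

from geofunc.autodiff import Tensor
from geofunc.gvp import (GVP, ScalarVector, SVLayerNorm, GVPConv, GVPBackbone,
                         GnnConfig)
from geofunc.model import batch_graphs
from conftest import random_rotation


def _sv(rng, L, ns, nv):
    return ScalarVector(Tensor(rng.standard_normal((L, ns))),
                        Tensor(rng.standard_normal((L, nv, 3))))


def _rotate(V: np.ndarray, R: np.ndarray) -> np.ndarray:
    return np.einsum("ij,lcj->lci", R, V)


def test_gvp_zero_vectors_give_zero_vector_output_and_pure_scalar_path():
    rng = np.random.default_rng(0)
    gvp = GVP((4, 2), (8, 3), rng)
    s = rng.standard_normal((5, 4))
    x = ScalarVector(Tensor(s), Tensor(np.zeros((5, 2, 3))))
    out = gvp(x)
    assert np.all(out.V.data == 0.0)
    # scalar path must equal sigma(W_m concat(0, s) + b) exactly
    h = gvp.h_dim
    s_in = np.concatenate([np.zeros((5, h)), s], axis=1)
    expected = np.maximum(s_in @ gvp.W_m.W.data.T + gvp.W_m.b.data, 0.0)
    assert np.allclose(out.s.data, expected, atol=0, rtol=0)


def test_gvp_output_widths():
    rng = np.random.default_rng(1)
    gvp = GVP((4, 2), (8, 3), rng)
    out = gvp(_sv(rng, 6, 4, 2))
    assert out.s.shape == (6, 8)
    assert out.V.shape == (6, 3, 3)
    with pytest.raises(ValueError):
        gvp(_sv(rng, 6, 5, 2))


def test_gvp_rotation_equivariance_20_draws():
    rng = np.random.default_rng(2)
    gvp = GVP((6, 4), (5, 3), rng)
    x = _sv(rng, 8, 6, 4)
    base = gvp(x)
    for _ in range(20):
        R = random_rotation(rng)
        xr = ScalarVector(Tensor(x.s.data.copy()),
                          Tensor(_rotate(x.V.data, R)))
        out = gvp(xr)
        assert np.allclose(out.s.data, base.s.data, rtol=1e-5, atol=1e-10)
        assert np.allclose(out.V.data, _rotate(base.V.data, R), atol=1e-6)


def test_sv_layernorm_statistics_and_rotation():
    rng = np.random.default_rng(3)
    ln = SVLayerNorm((10, 4))
    x = _sv(rng, 7, 10, 4)
    out = ln(x)
    assert np.allclose(out.s.data.mean(axis=1), 0.0, atol=1e-9)
    assert np.allclose(out.s.data.var(axis=1), 1.0, atol=1e-6)
    # constant scalar row normalizes to the affine offset (zero pre-affine)
    xc = ScalarVector(Tensor(np.full((2, 10), 3.3)), Tensor(np.zeros((2, 4, 3))))
    assert np.allclose(ln(xc).s.data, 0.0, atol=1e-3)
    R = random_rotation(rng)
    xr = ScalarVector(Tensor(x.s.data.copy()), Tensor(_rotate(x.V.data, R)))
    outr = ln(xr)
    assert np.allclose(outr.V.data, _rotate(out.V.data, R), atol=1e-9)


def test_message_concat_widths_and_zero_case():
    rng = np.random.default_rng(4)
    cfg = GnnConfig(node_dims=(8, 3), edge_dims=(6, 2), msg_depth=2)
    conv = GVPConv(cfg, rng)
    h_v = ScalarVector(Tensor(rng.standard_normal((4, 8))),
                       Tensor(np.zeros((4, 3, 3))))
    edge_index = np.array([[0, 1, 2], [1, 2, 3]])
    h_e = ScalarVector(Tensor(rng.standard_normal((3, 6))),
                       Tensor(np.zeros((3, 2, 3))))
    msg = conv.message(h_v, h_e, edge_index)
    assert msg.s.shape == (3, 8) and msg.V.shape == (3, 3, 3)
    assert np.all(msg.V.data == 0.0)      # zero vectors propagate to zero
    assert conv.stack[0].in_dims == (8 + 6, 3 + 2)


def test_message_rotation_equivariance():
    rng = np.random.default_rng(5)
    cfg = GnnConfig(node_dims=(8, 3), edge_dims=(6, 2), msg_depth=3)
    conv = GVPConv(cfg, rng)
    h_v = _sv(rng, 4, 8, 3)
    h_e = _sv(rng, 5, 6, 2)
    edge_index = np.array([[0, 1, 2, 3, 0], [1, 2, 3, 0, 2]])
    base = conv.message(h_v, h_e, edge_index)
    R = random_rotation(rng)
    h_v_r = ScalarVector(Tensor(h_v.s.data.copy()), Tensor(_rotate(h_v.V.data, R)))
    h_e_r = ScalarVector(Tensor(h_e.s.data.copy()), Tensor(_rotate(h_e.V.data, R)))
    out = conv.message(h_v_r, h_e_r, edge_index)
    assert np.allclose(out.s.data, base.s.data, rtol=1e-5, atol=1e-10)
    assert np.allclose(out.V.data, _rotate(base.V.data, R), atol=1e-6)


def test_node_update_message_permutation_invariance():
    rng = np.random.default_rng(6)
    cfg = GnnConfig(node_dims=(8, 3), edge_dims=(6, 2), msg_depth=2, dropout=0.0)
    conv = GVPConv(cfg, rng)
    h_v = _sv(rng, 3, 8, 3)
    h_e = _sv(rng, 4, 6, 2)
    edge_index = np.array([[0, 1, 2, 1], [2, 2, 0, 0]])
    out1 = conv(h_v, h_e, edge_index, np.random.default_rng(0))
    # permute the edge list: aggregation must be order-independent
    perm = np.array([3, 1, 0, 2])
    h_e_p = ScalarVector(Tensor(h_e.s.data[perm]), Tensor(h_e.V.data[perm]))
    out2 = conv(h_v, h_e_p, edge_index[:, perm], np.random.default_rng(0))
    assert np.array_equal(out1.s.data, out2.s.data)
    assert np.array_equal(out1.V.data, out2.V.data)


def test_isolated_node_reduces_to_residual_layernorm_oracle():
    """With no incoming edges a layer must equal sv_layernorm(h_v)."""
    rng = np.random.default_rng(7)
    cfg = GnnConfig(node_dims=(8, 3), edge_dims=(6, 2), msg_depth=2, dropout=0.0)
    conv = GVPConv(cfg, rng)
    h_v = _sv(rng, 2, 8, 3)
    h_e = _sv(rng, 1, 6, 2)
    edge_index = np.array([[0], [1]])      # node 0 receives nothing
    out = conv(h_v, h_e, edge_index, np.random.default_rng(0))
    solo = conv.norm(ScalarVector(h_v.s[0:1], h_v.V[0:1]))
    assert np.allclose(out.s.data[0], solo.s.data[0], atol=1e-12)
    assert np.allclose(out.V.data[0], solo.V.data[0], atol=1e-12)


def test_gnn_config_validation():
    with pytest.raises(ValueError):
        GnnConfig(n_layers=0)
    with pytest.raises(ValueError):
        GnnConfig(node_dims=(0, 4))
    with pytest.raises(ValueError):
        GnnConfig(aggregation="max")


def test_backbone_eval_forward_deterministic(mixed_graph):
    rng = np.random.default_rng(8)
    cfg = GnnConfig(node_dims=(16, 4), n_layers=2, msg_depth=2, out_scalar_dim=12)
    bb = GVPBackbone((mixed_graph.node_scalar.shape[1], 3), (32, 1), cfg, rng)
    batch = batch_graphs([mixed_graph])
    F1 = bb.forward(batch.node, batch.edge, batch.edge_index,
                    np.random.default_rng(0)).data
    F2 = bb.forward(batch.node, batch.edge, batch.edge_index,
                    np.random.default_rng(99)).data
    assert np.array_equal(F1, F2)          # eval mode: no stochastic elements
    assert F1.shape == (mixed_graph.n_nodes, 12)


def test_collapse_and_full_trunk_rotation_invariance(mixed_backbone, small_manifest):
    from geofunc.features import featurize, dummy_embedder
    rng = np.random.default_rng(9)
    cfg = GnnConfig(node_dims=(16, 4), n_layers=2, msg_depth=2, out_scalar_dim=12)
    emb = dummy_embedder(16)
    g = featurize(mixed_backbone, emb, small_manifest)
    bb = GVPBackbone((g.node_scalar.shape[1], 3), (32, 1), cfg, rng)
    batch = batch_graphs([g])
    F = bb.forward(batch.node, batch.edge, batch.edge_index,
                   np.random.default_rng(0)).data
    for _ in range(3):
        R = random_rotation(rng)
        t = rng.normal(0, 10, 3)
        g2 = featurize(mixed_backbone.transformed(R, t), emb, small_manifest)
        b2 = batch_graphs([g2])
        # hidden vector activations must rotate exactly with R
        h_v, h_e = bb.lift(b2.node, b2.edge)
        h_v = bb.propagate(h_v, h_e, b2.edge_index, np.random.default_rng(0))
        h_v0, h_e0 = bb.lift(batch.node, batch.edge)
        h_v0 = bb.propagate(h_v0, h_e0, batch.edge_index, np.random.default_rng(0))
        assert np.allclose(h_v.V.data, _rotate(h_v0.V.data, R), atol=1e-5)
        F2 = bb.forward(b2.node, b2.edge, b2.edge_index,
                        np.random.default_rng(0)).data
        assert np.max(np.abs(F2 - F)) / np.max(np.abs(F)) < 1e-4
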