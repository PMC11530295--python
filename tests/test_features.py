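"""Featurization correctness against independent geometric oracles."""

import numpy as np
import pytest

from geofunc.features import (backbone_dihedrals, secondary_structure, sasa,
                              shrake_rupley, rbf_encode, positional_encode,
                              build_graph, node_features, edge_features,
                              dummy_embed, dummy_embedder, featurize,
                              FeatureManifest, ResidueGraph)
from geofunc.structure import BackboneStructure, virtual_cbeta
from geofunc.synthetic import synthetic_backbone
from conftest import random_rotation


# --------------------------------------------------------------- dihedrals

def _dihedral_oracle(p0, p1, p2, p3):
    """Independent projection-based atan2 formula (praxeolitic form)."""
    b0 = -(np.asarray(p1) - np.asarray(p0))
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1u = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return np.arctan2(y, x)


def test_dihedrals_match_independent_oracle():
    from geofunc.features import dihedral_angle
    rng = np.random.default_rng(0)
    for _ in range(20):
        pts = rng.normal(0, 5, (4, 3))
        assert abs(dihedral_angle(*pts) - _dihedral_oracle(*pts)) < 1e-9


def test_planar_trans_and_cis_dihedrals():
    from geofunc.features import dihedral_angle
    # coplanar zig-zag: trans arrangement -> +/- pi
    trans = [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)]
    assert abs(abs(dihedral_angle(*trans)) - np.pi) < 1e-12
    cis = [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)]
    assert abs(dihedral_angle(*cis)) < 1e-12


def test_backbone_dihedral_termini_flagged(mixed_backbone):
    phi, psi, def_phi, def_psi = backbone_dihedrals(mixed_backbone)
    assert not def_phi[0] and not def_psi[-1]
    assert def_phi[1:].all() and def_psi[:-1].all()


# --------------------------------------------------- secondary structure

def test_fallback_ss_classifies_ideal_segments():
    helix = synthetic_backbone([("helix", 12)], seed=0)
    labels, classes = secondary_structure(helix)
    assert classes == ("H", "E", "C")
    assert all(l == "H" for l in labels[1:-1])
    assert labels[0] == "C" and labels[-1] == "C"   # undefined termini -> coil
    strand = synthetic_backbone([("strand", 10)], seed=0)
    labels, _ = secondary_structure(strand)
    assert all(l == "E" for l in labels[1:-1])


# -------------------------------------------------------------------- SASA

def test_isolated_residue_fully_accessible():
    s = synthetic_backbone([("strand", 4)], seed=1)
    # glycine: its backbone alone already exceeds the max-ASA normalizer
    one = BackboneStructure(chain_id="A", seq_pos=s.seq_pos[:1].copy(),
                            aa=["G"], N=s.N[:1].copy(), CA=s.CA[:1].copy(),
                            C=s.C[:1].copy(), O=s.O[:1].copy(),
                            has_O=s.has_O[:1].copy())
    assert sasa(one)[0] == 1.0


def _sasa_oracle(coords, radii, probe=1.4, n_pts=400):
    """Brute-force sphere-point SASA with an independent point set."""
    rng = np.random.default_rng(123)
    pts = rng.standard_normal((n_pts, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    expanded = radii + probe
    out = np.zeros(len(coords))
    for i in range(len(coords)):
        surface = coords[i] + expanded[i] * pts
        free = np.ones(n_pts, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            free &= ((surface - coords[j]) ** 2).sum(axis=1) >= expanded[j] ** 2
        out[i] = 4 * np.pi * expanded[i] ** 2 * free.mean()
    return out


def test_shrake_rupley_matches_bruteforce_oracle():
    rng = np.random.default_rng(7)
    coords = rng.normal(0, 3.0, (12, 3))
    radii = np.full(12, 1.7)
    mine = shrake_rupley(coords, radii)
    oracle = _sasa_oracle(coords, radii)
    total_area = 4 * np.pi * (1.7 + 1.4) ** 2
    assert np.max(np.abs(mine - oracle)) < 0.06 * total_area


def test_buried_residue_low_accessibility():
    # a residue at the center of a dense shell of others
    rng = np.random.default_rng(9)
    base = synthetic_backbone([("helix", 5)], seed=2)
    center = base.CA[2].copy()
    structures = [base]
    shells = []
    for k in range(26):
        v = rng.standard_normal(3)
        v = 4.5 * v / np.linalg.norm(v)
        shells.append(v)
    L = 1 + len(shells)
    N = np.vstack([base.N[2][None], center + np.array(shells) + (1.4, 0, 0)])
    CA = np.vstack([base.CA[2][None], center + np.array(shells)])
    C = np.vstack([base.C[2][None], center + np.array(shells) + (0, 1.4, 0)])
    s = BackboneStructure(chain_id="A", seq_pos=np.arange(1, L + 1),
                          aa=["A"] * L, N=N, CA=CA, C=C)
    rel = sasa(s)
    assert rel[0] < 0.2


def test_sasa_rotation_invariant(mixed_backbone):
    base = sasa(mixed_backbone)
    rng = np.random.default_rng(4)
    R = random_rotation(rng)
    moved = sasa(mixed_backbone.transformed(R, rng.normal(0, 20, 3)))
    assert np.max(np.abs(base - moved)) < 1e-9


def test_sasa_bounded(mixed_backbone):
    rel = sasa(mixed_backbone)
    assert np.all(rel >= 0) and np.all(rel <= 1)


# ------------------------------------------------------------- encodings

def test_rbf_matches_closed_form():
    rng = np.random.default_rng(2)
    d = rng.uniform(0, 25, 100)
    K, lo, hi = 16, 0.0, 20.0
    out = rbf_encode(d, K, lo, hi)
    mu = np.linspace(lo, hi, K)
    sig = (hi - lo) / (K - 1)
    expected = np.exp(-((d[:, None] - mu) ** 2) / (2 * sig**2))
    assert np.allclose(out, expected, atol=0, rtol=0)
    # value 1 exactly at a center, vanishing far beyond the range
    assert rbf_encode(np.array([mu[3]]), K, lo, hi)[0, 3] == 1.0
    assert np.all(rbf_encode(np.array([hi + 10 * sig]), K, lo, hi) < 1e-8)


def test_rbf_rejects_bad_input():
    with pytest.raises(ValueError):
        rbf_encode(np.array([np.nan]))
    with pytest.raises(ValueError):
        rbf_encode(np.array([1.0]), centers=1)


def test_positional_encoding_parity_and_shape():
    for dim in (2, 8, 16):
        assert positional_encode(np.array([3]), dim).shape == (1, dim)
    z = positional_encode(np.array([0]), 8)[0]
    assert np.allclose(z[0::2], 0.0) and np.allclose(z[1::2], 1.0)
    plus = positional_encode(np.array([5]), 16)[0]
    minus = positional_encode(np.array([-5]), 16)[0]
    assert np.allclose(minus[0::2], -plus[0::2])
    assert np.allclose(minus[1::2], plus[1::2])
    with pytest.raises(ValueError):
        positional_encode(np.array([1]), 7)


# ------------------------------------------------------------------ graph

def _knn_oracle(CA, k):
    """Exhaustive neighbor search with explicit (distance, index) sorting."""
    L = len(CA)
    edges = set()
    for i in range(L):
        cand = sorted((np.linalg.norm(CA[j] - CA[i]), j)
                      for j in range(L) if j != i)
        for _, j in cand[:min(k, L - 1)]:
            edges.add((j, i))
    return edges


def test_knn_graph_matches_exhaustive_search():
    rng = np.random.default_rng(11)
    for trial in range(10):
        L = int(rng.integers(5, 15))
        CA = rng.normal(0, 8, (L, 3))
        s = BackboneStructure(chain_id="A", seq_pos=np.arange(1, L + 1),
                              aa=["A"] * L, N=CA + (1.2, 0, 0), CA=CA,
                              C=CA + (0, 1.2, 0))
        k = int(rng.integers(1, 6))
        edge_index = build_graph(s, k)
        got = set(zip(edge_index[0].tolist(), edge_index[1].tolist()))
        assert got == _knn_oracle(CA, k)


def test_knn_complete_graph_and_errors():
    CA = np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0.1]], dtype=float)
    s = BackboneStructure(chain_id="A", seq_pos=np.arange(1, 4), aa=["A"] * 3,
                          N=CA + (1, 0, 0), CA=CA, C=CA + (0, 1, 0))
    edge_index = build_graph(s, 5)
    assert edge_index.shape == (2, 6)
    assert np.all(edge_index[0] != edge_index[1])
    with pytest.raises(ValueError):
        build_graph(s, 0)


def test_knn_duplicate_coordinates_deterministic():
    CA = np.array([[0, 0, 0], [5, 0, 0], [5, 0, 0], [10, 0, 0]], dtype=float)
    s = BackboneStructure(chain_id="A", seq_pos=np.arange(1, 5), aa=["A"] * 4,
                          N=CA + (1, 0, 0), CA=CA, C=CA + (0, 1, 0))
    e1 = build_graph(s, 1)
    e2 = build_graph(s, 1)
    assert np.array_equal(e1, e2)
    # node 0's single neighbor: tie between nodes 1 and 2 -> smaller index
    nbr0 = e1[0][e1[1] == 0]
    assert nbr0.tolist() == [1]


# --------------------------------------------------------- node/edge feats

def test_node_feature_contracts(mixed_backbone, small_manifest):
    emb = dummy_embedder(16).embed(mixed_backbone.sequence)
    ns, nv = node_features(mixed_backbone, emb, small_manifest)
    L = len(mixed_backbone)
    assert ns.shape == (L, small_manifest.node_scalar_dim)
    assert nv.shape == (L, 3, 3)
    norms = np.linalg.norm(nv, axis=2)
    assert np.allclose(norms[0, 0], 0.0)       # first residue: no backward
    assert np.allclose(norms[-1, 1], 0.0)      # last residue: no forward
    defined = norms > 0
    assert np.allclose(norms[defined], 1.0, atol=1e-6)
    # CB channel comes from the idealized construction (no stored CB)
    cb = virtual_cbeta(mixed_backbone.N[4], mixed_backbone.CA[4],
                       mixed_backbone.C[4])
    expected = (cb - mixed_backbone.CA[4])
    expected /= np.linalg.norm(expected)
    assert np.allclose(nv[4, 2], expected, atol=1e-9)


def test_edge_feature_contracts(mixed_backbone, small_manifest):
    edge_index = build_graph(mixed_backbone, 6)
    es, ev = edge_features(mixed_backbone, edge_index, small_manifest)
    assert es.shape == (edge_index.shape[1], 32)
    # reciprocal edges carry opposite unit vectors
    pairs = {(int(a), int(b)): i for i, (a, b) in enumerate(edge_index.T)}
    found = 0
    for (a, b), i in pairs.items():
        j = pairs.get((b, a))
        if j is not None:
            assert np.allclose(ev[i, 0], -ev[j, 0], atol=1e-9)
            found += 1
    assert found > 0
    # RBF argmax sits at the center nearest the true CA distance
    src, dst = edge_index
    d = np.linalg.norm(mixed_backbone.CA[dst] - mixed_backbone.CA[src], axis=1)
    mu = np.linspace(small_manifest.rbf_d_min, small_manifest.rbf_d_max,
                     small_manifest.rbf_centers)
    for i in range(0, len(d), 17):
        assert np.argmax(es[i, :16]) == np.argmin(np.abs(mu - d[i]))


def test_translation_leaves_edge_features_unchanged(mixed_backbone, small_manifest):
    edge_index = build_graph(mixed_backbone, 6)
    es, ev = edge_features(mixed_backbone, edge_index, small_manifest)
    moved = mixed_backbone.transformed(np.eye(3), np.array([11.0, -7.0, 3.0]))
    es2, ev2 = edge_features(moved, edge_index, small_manifest)
    assert np.allclose(es, es2, atol=1e-9)
    assert np.allclose(ev, ev2, atol=1e-9)


def test_full_featurization_rigid_motion_invariance(mixed_backbone, small_manifest):
    emb = dummy_embedder(16)
    g = featurize(mixed_backbone, emb, small_manifest)
    rng = np.random.default_rng(21)
    for _ in range(3):
        R = random_rotation(rng)
        t = rng.normal(0, 15, 3)
        g2 = featurize(mixed_backbone.transformed(R, t), emb, small_manifest)
        assert np.array_equal(g.edge_index, g2.edge_index)
        assert np.allclose(g.node_scalar, g2.node_scalar, rtol=1e-5, atol=1e-9)
        assert np.allclose(g.edge_scalar, g2.edge_scalar, rtol=1e-5, atol=1e-9)
        assert np.allclose(g2.node_vector,
                           np.einsum("ij,lcj->lci", R, g.node_vector), atol=1e-6)
        assert np.allclose(g2.edge_vector,
                           np.einsum("ij,ecj->eci", R, g.edge_vector), atol=1e-6)


# ------------------------------------------------------------- embeddings

def test_dummy_embed_deterministic_and_typed():
    a = dummy_embed("ACDY", 8, seed=3)
    b = dummy_embed("ACDY", 8, seed=3)
    assert np.array_equal(a, b)
    assert a.shape == (4, 8)
    assert not np.allclose(a[0], a[1])   # different residue types differ
    with pytest.raises(ValueError):
        dummy_embed("ACZ", 8, seed=0)


def test_manifest_roundtrip_and_graph_io(tmp_path, mixed_graph):
    m2 = FeatureManifest.from_json(mixed_graph.manifest.to_json())
    assert m2 == mixed_graph.manifest
    mixed_graph.save(tmp_path / "g")
    g2 = ResidueGraph.load(tmp_path / "g")
    assert np.array_equal(g2.edge_index, mixed_graph.edge_index)
    assert np.array_equal(g2.node_scalar, mixed_graph.node_scalar)
    assert g2.manifest == mixed_graph.manifest
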