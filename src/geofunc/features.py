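"""Multi-scale geometric featurization of protein backbones.

Each chain becomes a directed residue graph: nodes carry rotation-invariant
scalars (secondary structure, backbone torsions, solvent accessibility,
sequence embeddings) and rotation-equivariant 3-vector channels (local CA
trace directions and the CA->CB orientation); edges connect each residue to
its k nearest CA neighbors and carry a Gaussian-RBF distance encoding, a
sinusoidal sequence-offset encoding, and the unit inter-CA direction.

Undefined geometric channels (chain termini, coincident atoms) use the zero
vector as a sentinel — rotations map zero to zero, so equivariance is
preserved exactly.
"""

from __future__ import annotations

import json
import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
import biotite.structure as struc

from .structure import BackboneStructure, virtual_cbeta, write_backbone_pdb

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

# Theoretical maximum accessible surface areas per residue type (A^2),
# Tien et al. 2013; used to normalize raw SASA to relative accessibility.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
    "X": 197.0,
}


# --------------------------------------------------------------------------
# geometry primitives
# --------------------------------------------------------------------------

def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral of four points (radians, in (-pi, pi])."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=np.float64) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n < 1e-10 or np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("degenerate atom quadruple: dihedral undefined")
    return float(np.arctan2(np.dot(np.cross(n1, n2), b2) / b2n, np.dot(n1, n2)))


def backbone_dihedrals(s: BackboneStructure):
    """Per-residue (phi, psi) in radians.

    phi(i) uses C(i-1), N(i), CA(i), C(i); psi(i) uses N(i), CA(i), C(i),
    N(i+1).  Returns (phi, psi, defined_phi, defined_psi); phi of the first
    and psi of the last residue are undefined, as is any angle built from a
    degenerate quadruple.
    """
    L = len(s)
    if L < 2:
        raise ValueError("need at least 2 residues for backbone dihedrals")
    phi = np.zeros(L)
    psi = np.zeros(L)
    def_phi = np.zeros(L, dtype=bool)
    def_psi = np.zeros(L, dtype=bool)
    for i in range(L):
        if i > 0:
            try:
                phi[i] = dihedral_angle(s.C[i - 1], s.N[i], s.CA[i], s.C[i])
                def_phi[i] = True
            except ValueError:
                logger.warning("degenerate phi at residue %d", s.seq_pos[i])
        if i < L - 1:
            try:
                psi[i] = dihedral_angle(s.N[i], s.CA[i], s.C[i], s.N[i + 1])
                def_psi[i] = True
            except ValueError:
                logger.warning("degenerate psi at residue %d", s.seq_pos[i])
    return phi, psi, def_phi, def_psi


SS_CLASSES_FALLBACK = ("H", "E", "C")            # helix / strand / coil
SS_CLASSES_DSSP = ("H", "B", "E", "G", "I", "T", "S", "-")


def _ramachandran_class(phi: float, psi: float) -> str:
    """3-state assignment from (phi, psi) boxes around the ideal points."""
    pd, sd = np.degrees(phi), np.degrees(psi)
    if -100.0 <= pd <= -30.0 and -80.0 <= sd <= -5.0:
        return "H"
    if -180.0 <= pd <= -90.0 and (sd >= 90.0 or sd <= -150.0):
        return "E"
    return "C"


def secondary_structure(s: BackboneStructure, dssp_path: str | None = None):
    """Per-residue secondary-structure labels.

    If `dssp_path` points to a working DSSP executable its 8-state labels
    are used; otherwise a deterministic 3-state fallback assigns helix,
    strand, or coil from Ramachandran boxes.  Residues with undefined
    torsions are coil.  Returns (labels, classes).
    """
    if dssp_path is not None:
        try:
            return _dssp_labels(s, dssp_path), SS_CLASSES_DSSP
        except Exception as exc:  # noqa: BLE001 - any tool failure falls back
            logger.warning("DSSP invocation failed (%s); using Ramachandran fallback", exc)
    phi, psi, def_phi, def_psi = backbone_dihedrals(s)
    labels = []
    for i in range(len(s)):
        if not (def_phi[i] and def_psi[i]):
            labels.append("C")
        else:
            labels.append(_ramachandran_class(phi[i], psi[i]))
    return labels, SS_CLASSES_FALLBACK


def _dssp_labels(s: BackboneStructure, dssp_path: str) -> list:
    if shutil.which(dssp_path) is None:
        raise FileNotFoundError(dssp_path)
    with tempfile.TemporaryDirectory() as tmp:
        pdb_path = Path(tmp) / "in.pdb"
        write_backbone_pdb(s, pdb_path)
        out = subprocess.run([dssp_path, str(pdb_path)], capture_output=True,
                             text=True, check=True).stdout
    labels = {}
    in_table = False
    for line in out.splitlines():
        if line.startswith("  #  RESIDUE"):
            in_table = True
            continue
        if in_table and len(line) > 16 and line[13] != "!":
            try:
                res_id = int(line[5:10])
            except ValueError:
                continue
            ss = line[16] if line[16] != " " else "-"
            labels[res_id] = ss if ss in SS_CLASSES_DSSP else "-"
    return [labels.get(int(p), "-") for p in s.seq_pos]


_VDW_RADII = {"N": 1.55, "C": 1.70, "O": 1.52, "S": 1.80}


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit directions (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Rotate centered coordinates into a deterministic principal-axis frame.

    Axis signs are fixed by the largest-magnitude projection, and
    handedness is enforced, so any rigid motion of the input yields the
    same canonical coordinates (up to float64 rounding).  This makes the
    numerical SASA exactly rotation-invariant.
    """
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    vecs = vecs[:, ::-1]                    # descending variance
    proj = centered @ vecs
    for k in range(3):
        j = np.argmax(np.abs(proj[:, k]))
        if proj[j, k] < 0:
            vecs[:, k] = -vecs[:, k]
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] = -vecs[:, 2]
    return centered @ vecs


def shrake_rupley(coords: np.ndarray, radii: np.ndarray,
                  probe_radius: float = 1.4, point_number: int = 240) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), float64 throughout.

    Test-sphere directions are fixed in a canonical molecular frame, so the
    result is invariant under rigid motion of the input coordinates.
    """
    coords = _canonical_frame(np.asarray(coords, dtype=np.float64))
    radii = np.asarray(radii, dtype=np.float64)
    n = len(coords)
    sphere = _fibonacci_sphere(point_number)
    expanded = radii + probe_radius
    out = np.zeros(n)
    cutoff = 2.0 * expanded.max()
    dmat = cdist(coords, coords)
    for i in range(n):
        neigh = np.nonzero((dmat[i] < cutoff) & (np.arange(n) != i))[0]
        pts = coords[i] + expanded[i] * sphere          # (P, 3)
        if len(neigh):
            d2 = ((pts[:, None, :] - coords[neigh][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (expanded[neigh] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        out[i] = 4.0 * np.pi * expanded[i] ** 2 * frac
    return out


def sasa(s: BackboneStructure, probe_radius: float = 1.4, point_number: int = 240) -> np.ndarray:
    """Relative per-residue solvent accessibility in [0, 1].

    Shrake-Rupley numerical SASA over the available backbone atoms (plus CB
    where present), normalized by per-residue-type maximal accessibility and
    clipped to [0, 1].
    """
    L = len(s)
    if L == 0:
        return np.zeros(0)
    coords, radii, res_idx = [], [], []
    for i in range(L):
        entries = [("N", s.N[i]), ("C", s.CA[i]), ("C", s.C[i])]
        if s.has_O[i]:
            entries.append(("O", s.O[i]))
        if s.has_CB[i]:
            entries.append(("C", s.CB[i]))
        for el, xyz in entries:
            coords.append(xyz)
            radii.append(_VDW_RADII[el])
            res_idx.append(i)
    atom_sasa = shrake_rupley(np.asarray(coords), np.asarray(radii),
                              probe_radius, point_number)
    per_res = np.zeros(L)
    np.add.at(per_res, np.asarray(res_idx), atom_sasa)
    max_asa = np.array([MAX_ASA.get(a, MAX_ASA["X"]) for a in s.aa])
    return np.clip(per_res / max_asa, 0.0, 1.0)


# --------------------------------------------------------------------------
# scalar encodings
# --------------------------------------------------------------------------

def rbf_encode(d, centers: int = 16, d_min: float = 0.0, d_max: float = 20.0) -> np.ndarray:
    """Gaussian radial-basis expansion of distances.

    Component k is exp(-(d - mu_k)^2 / (2 sigma^2)) with `centers` centers
    mu_k evenly spaced on [d_min, d_max] and sigma equal to the center
    spacing.  Accepts a scalar or an array; output has one trailing axis of
    size `centers`.
    """
    if centers < 2:
        raise ValueError("need at least 2 RBF centers")
    if d_max <= d_min:
        raise ValueError("d_max must exceed d_min")
    d = np.asarray(d, dtype=np.float64)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite distance passed to rbf_encode")
    mu = np.linspace(d_min, d_max, centers)
    sigma = (d_max - d_min) / (centers - 1)
    return np.exp(-((d[..., None] - mu) ** 2) / (2.0 * sigma**2))


def positional_encode(offset, dim: int = 16) -> np.ndarray:
    """Transformer-style sinusoidal encoding of signed sequence offsets.

    Interleaves sin and cos of the offset at `dim/2` geometrically spaced
    frequencies (base period 10000).  `dim` must be even.
    """
    if dim < 2 or dim % 2 != 0:
        raise ValueError(f"positional encoding dim must be even and >= 2, got {dim}")
    offset = np.asarray(offset, dtype=np.float64)
    freqs = np.exp(-np.log(10000.0) * np.arange(dim // 2) * 2.0 / dim)
    args = offset[..., None] * freqs
    out = np.empty(offset.shape + (dim,))
    out[..., 0::2] = np.sin(args)
    out[..., 1::2] = np.cos(args)
    return out


# --------------------------------------------------------------------------
# graph construction
# --------------------------------------------------------------------------

def build_graph(s: BackboneStructure, k: int = 30) -> np.ndarray:
    """Directed k-nearest-neighbor graph on CA coordinates.

    Returns edge_index of shape (2, E): row 0 holds sources j, row 1 holds
    destinations i, with an edge j->i for each of i's k nearest neighbors.
    Distance ties break toward the smaller residue index, so the graph is
    deterministic.  If k >= L-1 the result is the complete digraph without
    self-loops.
    """
    L = len(s)
    if L < 2:
        raise ValueError("need at least 2 residues to build a graph")
    if k < 1:
        raise ValueError("k must be >= 1")
    k_eff = min(k, L - 1)
    dist = cdist(s.CA, s.CA)
    np.fill_diagonal(dist, np.inf)
    # lexsort: primary key distance, secondary key index -> deterministic ties
    idx = np.arange(L)
    src_list, dst_list = [], []
    for i in range(L):
        order = np.lexsort((idx, dist[i]))[:k_eff]
        src_list.append(order)
        dst_list.append(np.full(k_eff, i))
    return np.stack([np.concatenate(src_list), np.concatenate(dst_list)])


# --------------------------------------------------------------------------
# embeddings
# --------------------------------------------------------------------------

@dataclass
class EmbedderSpec:
    """Contract for a per-residue sequence embedder.

    `provider` maps a one-letter sequence of length L to an (L, dim) float
    matrix.  Real language-model embeddings (ESM2, ProtTrans) plug in here
    as precomputed matrices; `dummy_embedder` supplies an offline stand-in.
    """

    name: str
    dim: int
    provider: object = None

    def __post_init__(self):
        if self.dim <= 0:
            raise ValueError("embedding dim must be positive")

    def embed(self, sequence: str) -> np.ndarray:
        out = np.asarray(self.provider(sequence), dtype=np.float64)
        if out.shape != (len(sequence), self.dim):
            raise ValueError(
                f"embedder {self.name} returned {out.shape}, "
                f"expected ({len(sequence)}, {self.dim})")
        return out


def dummy_embed(sequence: str, dim: int = 32, seed: int = 0) -> np.ndarray:
    """Offline embedding stand-in: one-hot(21) times a fixed seeded projection.

    Deterministic given (sequence, dim, seed); raises on characters outside
    the 21-letter alphabet.
    """
    if dim <= 0:
        raise ValueError("embedding dim must be positive")
    bad = set(sequence) - set(AA_ALPHABET)
    if bad:
        raise ValueError(f"unknown amino-acid code(s): {sorted(bad)}")
    rng = np.random.default_rng(seed)
    proj = rng.standard_normal((len(AA_ALPHABET), dim)) / np.sqrt(dim)
    onehot = np.zeros((len(sequence), len(AA_ALPHABET)))
    for i, a in enumerate(sequence):
        onehot[i, _AA_INDEX[a]] = 1.0
    return onehot @ proj


def dummy_embedder(dim: int = 32, seed: int = 0) -> EmbedderSpec:
    return EmbedderSpec(name=f"dummy-{dim}-s{seed}", dim=dim,
                        provider=lambda seq: dummy_embed(seq, dim, seed))


# --------------------------------------------------------------------------
# feature assembly
# --------------------------------------------------------------------------

@dataclass
class FeatureManifest:
    """Records the exact column layout of a featurized graph."""

    ss_classes: tuple = SS_CLASSES_FALLBACK
    embed_name: str = "dummy-32-s0"
    embed_dim: int = 32
    rbf_centers: int = 16
    rbf_d_min: float = 0.0
    rbf_d_max: float = 20.0
    posenc_dim: int = 16
    posenc_mode: str = "sequence_offset"     # or "spatial_distance"
    k_neighbors: int = 30
    dssp_path: str | None = None

    @property
    def node_scalar_dim(self) -> int:
        return len(self.ss_classes) + 4 + 1 + self.embed_dim

    @property
    def node_vector_dim(self) -> int:
        return 3

    @property
    def edge_scalar_dim(self) -> int:
        return self.rbf_centers + self.posenc_dim

    @property
    def edge_vector_dim(self) -> int:
        return 1

    def columns(self) -> list:
        cols = [f"ss_{c}" for c in self.ss_classes]
        cols += ["sin_phi", "cos_phi", "sin_psi", "cos_psi", "rel_sasa"]
        cols += [f"emb_{i}" for i in range(self.embed_dim)]
        return cols

    def to_json(self) -> str:
        d = asdict(self)
        d["ss_classes"] = list(self.ss_classes)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FeatureManifest":
        d = json.loads(text)
        d["ss_classes"] = tuple(d["ss_classes"])
        return cls(**d)

    def digest(self) -> str:
        """Stable hash of the column layout, recorded in run manifests."""
        import hashlib

        return hashlib.sha1(self.to_json().encode()).hexdigest()[:12]


@dataclass
class ResidueGraph:
    """The model's input: a featurized directed residue graph."""

    n_nodes: int
    edge_index: np.ndarray        # (2, E) int64, [src; dst]
    node_scalar: np.ndarray       # (L, n_s)
    node_vector: np.ndarray       # (L, n_v, 3)
    edge_scalar: np.ndarray       # (E, e_s)
    edge_vector: np.ndarray       # (E, e_v, 3)
    manifest: FeatureManifest = field(default_factory=FeatureManifest)
    name: str = ""

    def __post_init__(self):
        E = self.edge_index.shape[1]
        if self.edge_index.shape[0] != 2:
            raise ValueError("edge_index must have shape (2, E)")
        if np.any(self.edge_index[0] == self.edge_index[1]):
            raise ValueError("self-loops are not allowed")
        if self.edge_index.size and (self.edge_index.min() < 0
                                     or self.edge_index.max() >= self.n_nodes):
            raise ValueError("edge endpoint out of range")
        for arr, n in ((self.node_scalar, self.n_nodes), (self.node_vector, self.n_nodes),
                       (self.edge_scalar, E), (self.edge_vector, E)):
            if arr.shape[0] != n or not np.all(np.isfinite(arr)):
                raise ValueError("feature array shape/finiteness violation")

    def save(self, path):
        path = Path(path)
        np.savez(path.with_suffix(".npz"),
                 edge_index=self.edge_index, node_scalar=self.node_scalar,
                 node_vector=self.node_vector, edge_scalar=self.edge_scalar,
                 edge_vector=self.edge_vector)
        path.with_suffix(".json").write_text(json.dumps(
            {"n_nodes": self.n_nodes, "name": self.name,
             "manifest": json.loads(self.manifest.to_json())}, indent=2))

    @classmethod
    def load(cls, path) -> "ResidueGraph":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(n_nodes=meta["n_nodes"], name=meta.get("name", ""),
                   manifest=FeatureManifest.from_json(json.dumps(meta["manifest"])),
                   edge_index=arrays["edge_index"], node_scalar=arrays["node_scalar"],
                   node_vector=arrays["node_vector"], edge_scalar=arrays["edge_scalar"],
                   edge_vector=arrays["edge_vector"])


def _unit_rows(v: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Normalize rows to unit length; rows shorter than tol become zero."""
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    out = np.where(n > tol, v / np.maximum(n, tol), 0.0)
    return out


def node_features(s: BackboneStructure, emb: np.ndarray,
                  manifest: FeatureManifest | None = None):
    """Node scalar and vector features.

    Vector channels per residue: unit CA(i-1)-CA(i), unit CA(i+1)-CA(i),
    unit CB(i)-CA(i) (idealized CB where the file has none); undefined
    channels at the termini are zero.  Scalars concatenate [SS one-hot |
    sin/cos phi,psi | relative SASA | embedding], in manifest column order.
    """
    manifest = manifest or FeatureManifest()
    L = len(s)
    emb = np.asarray(emb, dtype=np.float64)
    if emb.shape != (L, manifest.embed_dim):
        raise ValueError(f"embedding shape {emb.shape} != ({L}, {manifest.embed_dim})")

    vec = np.zeros((L, 3, 3))
    vec[1:, 0] = _unit_rows(s.CA[:-1] - s.CA[1:])      # backward
    vec[:-1, 1] = _unit_rows(s.CA[1:] - s.CA[:-1])     # forward
    cb = s.cbeta_coords()
    vec[:, 2] = _unit_rows(cb - s.CA)

    phi, psi, def_phi, def_psi = backbone_dihedrals(s)
    torsion = np.zeros((L, 4))
    torsion[def_phi, 0] = np.sin(phi[def_phi])
    torsion[def_phi, 1] = np.cos(phi[def_phi])
    torsion[def_psi, 2] = np.sin(psi[def_psi])
    torsion[def_psi, 3] = np.cos(psi[def_psi])

    labels, classes = secondary_structure(s, manifest.dssp_path)
    if tuple(classes) != tuple(manifest.ss_classes):
        raise ValueError("secondary-structure class set differs from manifest")
    onehot = np.zeros((L, len(classes)))
    class_idx = {c: i for i, c in enumerate(classes)}
    for i, lab in enumerate(labels):
        onehot[i, class_idx[lab]] = 1.0

    rel_sasa = sasa(s)[:, None]
    scalar = np.concatenate([onehot, torsion, rel_sasa, emb], axis=1)
    return scalar, vec


def edge_features(s: BackboneStructure, edge_index: np.ndarray,
                  manifest: FeatureManifest | None = None):
    """Edge scalar and vector features for the given directed edges.

    For edge j->i the vector channel is the unit CA(i)-CA(j) direction; the
    scalar block is [RBF of the CA distance | sinusoidal encoding of the
    signed sequence offset j-i] (or of the spatial distance when the
    manifest selects that mode).
    """
    manifest = manifest or FeatureManifest()
    src, dst = edge_index
    diff = s.CA[dst] - s.CA[src]
    d = np.linalg.norm(diff, axis=1)
    if np.any(d < 1e-6):
        logger.warning("coincident CA pair(s) in edge set; zero direction sentinel used")
    vec = _unit_rows(diff)[:, None, :]
    rbf = rbf_encode(d, manifest.rbf_centers, manifest.rbf_d_min, manifest.rbf_d_max)
    if manifest.posenc_mode == "spatial_distance":
        pos = positional_encode(d, manifest.posenc_dim)
    else:
        offset = s.seq_pos[src] - s.seq_pos[dst]
        pos = positional_encode(offset, manifest.posenc_dim)
    return np.concatenate([rbf, pos], axis=1), vec


def featurize(s: BackboneStructure, embedder: EmbedderSpec | None = None,
              manifest: FeatureManifest | None = None, name: str = "") -> ResidueGraph:
    """Full pipeline: backbone -> featurized residue graph."""
    manifest = manifest or FeatureManifest()
    if embedder is None:
        embedder = dummy_embedder(manifest.embed_dim)
    if embedder.dim != manifest.embed_dim:
        raise ValueError("embedder width disagrees with manifest")
    emb = embedder.embed(s.sequence)
    edge_index = build_graph(s, manifest.k_neighbors)
    ns, nv = node_features(s, emb, manifest)
    es, ev = edge_features(s, edge_index, manifest)
    return ResidueGraph(n_nodes=len(s), edge_index=edge_index,
                        node_scalar=ns, node_vector=nv,
                        edge_scalar=es, edge_vector=ev,
                        manifest=manifest, name=name or s.chain_id)
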