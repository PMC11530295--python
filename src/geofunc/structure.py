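"""Reading protein backbones from PDB/mmCIF files.

A protein chain is reduced to its backbone: per-residue N, CA, C plus
optional O and CB coordinates in Angstroms, with one-letter amino-acid
codes.  Only the first model of multi-model files is used and alternate
locations are resolved to the highest-occupancy conformer.  Residues missing
any of N/CA/C are dropped with a warning — downstream featurization needs
all three.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb_io
import biotite.structure.io.pdbx as pdbx_io

logger = logging.getLogger(__name__)

__all__ = [
    "BackboneStructure",
    "parse_structure",
    "virtual_cbeta",
    "write_backbone_pdb",
    "ChainNotFoundError",
    "EmptyStructureError",
    "DegenerateGeometryError",
]

# Three-to-one mapping for the 20 standard residues; selenomethionine is
# treated as methionine, anything else becomes 'X'.
_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}

_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items() if k != "MSE"}
_ONE_TO_THREE["X"] = "UNK"


class ChainNotFoundError(KeyError):
    pass


class EmptyStructureError(ValueError):
    pass


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class BackboneStructure:
    """One protein chain's backbone.

    Coordinates are float64 arrays of shape (L, 3) in Angstroms.  Missing O
    or CB atoms are flagged in the boolean masks; the corresponding
    coordinate rows are zero and must not be read.
    """

    chain_id: str
    seq_pos: np.ndarray          # (L,) 1-based, strictly increasing
    aa: list                     # (L,) one-letter codes
    N: np.ndarray                # (L, 3)
    CA: np.ndarray               # (L, 3)
    C: np.ndarray                # (L, 3)
    O: np.ndarray = field(default=None)       # (L, 3) or zeros where absent
    CB: np.ndarray = field(default=None)
    has_O: np.ndarray = field(default=None)   # (L,) bool
    has_CB: np.ndarray = field(default=None)

    def __post_init__(self):
        L = len(self.aa)
        for name in ("N", "CA", "C"):
            arr = getattr(self, name)
            if arr.shape != (L, 3):
                raise ValueError(f"{name} must have shape ({L}, 3)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite coordinates in {name}")
        if self.O is None:
            self.O = np.zeros((L, 3))
            self.has_O = np.zeros(L, dtype=bool)
        if self.CB is None:
            self.CB = np.zeros((L, 3))
            self.has_CB = np.zeros(L, dtype=bool)
        if np.any(np.diff(self.seq_pos) <= 0):
            raise ValueError("seq_pos must be strictly increasing")

    def __len__(self) -> int:
        return len(self.aa)

    @property
    def sequence(self) -> str:
        return "".join(self.aa)

    def cbeta_coords(self) -> np.ndarray:
        """CB for every residue, using the idealized position where absent."""
        out = self.CB.copy()
        for i in np.nonzero(~self.has_CB)[0]:
            out[i] = virtual_cbeta(self.N[i], self.CA[i], self.C[i])
        return out

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "BackboneStructure":
        """Apply the rigid motion x -> R x + t to all stored coordinates."""
        def mv(arr, mask=None):
            out = arr @ R.T + t
            if mask is not None:
                out[~mask] = 0.0
            return out

        return BackboneStructure(
            chain_id=self.chain_id,
            seq_pos=self.seq_pos.copy(),
            aa=list(self.aa),
            N=mv(self.N), CA=mv(self.CA), C=mv(self.C),
            O=mv(self.O, self.has_O), CB=mv(self.CB, self.has_CB),
            has_O=self.has_O.copy(), has_CB=self.has_CB.copy(),
        )


def virtual_cbeta(N: np.ndarray, CA: np.ndarray, C: np.ndarray,
                  tol: float = 1e-8) -> np.ndarray:
    """Idealized CB position from tetrahedral backbone geometry.

    Uses the fixed coefficients on b = CA - N, c = C - CA, a = b x c that
    place CB ~1.53 A from CA in the standard side-chain direction; exactly
    rotation/translation equivariant.  Raises for collinear N, CA, C.
    """
    N, CA, C = (np.asarray(x, dtype=np.float64) for x in (N, CA, C))
    b = CA - N
    c = C - CA
    a = np.cross(b, c)
    if np.linalg.norm(a) < tol:
        raise DegenerateGeometryError("N, CA, C are collinear; CB undefined")
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * c + CA


def _read_atom_array(path: Path) -> struc.AtomArray:
    try:
        if path.suffix.lower() in (".cif", ".mmcif", ".pdbx"):
            cif = pdbx_io.CIFFile.read(str(path))
            return pdbx_io.get_structure(cif, model=1, altloc="occupancy")
        pdb = pdb_io.PDBFile.read(str(path))
        return pdb_io.get_structure(pdb, model=1, altloc="occupancy")
    except ValueError as exc:   # e.g. a file with no models/atoms at all
        raise EmptyStructureError(f"no parsable structure in {path}: {exc}") from exc


def parse_structure(path, chain: str = "first") -> BackboneStructure:
    """Extract one chain's backbone from a PDB or mmCIF file.

    Parameters
    ----------
    path:
        Structure file.  Format chosen by extension (.cif/.mmcif -> mmCIF,
        anything else -> PDB).
    chain:
        Chain identifier, or "first" for the first chain containing amino
        acids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    atoms = _read_atom_array(path)
    atoms = atoms[struc.filter_amino_acids(atoms)]
    if atoms.array_length() == 0:
        raise EmptyStructureError(f"no amino-acid residues in {path}")

    chain_ids = list(dict.fromkeys(atoms.chain_id))
    if chain == "first":
        chain = chain_ids[0]
    elif chain not in chain_ids:
        raise ChainNotFoundError(f"chain {chain!r} not in {path} (has {chain_ids})")
    atoms = atoms[atoms.chain_id == chain]

    seq_pos, aa = [], []
    coords = {k: [] for k in ("N", "CA", "C", "O", "CB")}
    has_O, has_CB = [], []
    n_dropped = 0
    pos = 0
    for res in struc.residue_iter(atoms):
        names = list(res.atom_name)
        sel = {}
        for atom in ("N", "CA", "C", "O", "CB"):
            if atom in names:
                sel[atom] = res.coord[names.index(atom)].astype(np.float64)
        if not all(a in sel for a in ("N", "CA", "C")):
            n_dropped += 1
            continue
        pos += 1
        seq_pos.append(pos)
        aa.append(_THREE_TO_ONE.get(str(res.res_name[0]), "X"))
        for atom in ("N", "CA", "C"):
            coords[atom].append(sel[atom])
        coords["O"].append(sel.get("O", np.zeros(3)))
        coords["CB"].append(sel.get("CB", np.zeros(3)))
        has_O.append("O" in sel)
        has_CB.append("CB" in sel)

    if n_dropped:
        logger.warning("%s chain %s: dropped %d residue(s) missing N/CA/C",
                       path.name, chain, n_dropped)
    if not seq_pos:
        raise EmptyStructureError(f"chain {chain} of {path} has no complete backbone residues")

    return BackboneStructure(
        chain_id=str(chain),
        seq_pos=np.asarray(seq_pos, dtype=np.int64),
        aa=aa,
        N=np.asarray(coords["N"]), CA=np.asarray(coords["CA"]),
        C=np.asarray(coords["C"]),
        O=np.asarray(coords["O"]), CB=np.asarray(coords["CB"]),
        has_O=np.asarray(has_O, dtype=bool), has_CB=np.asarray(has_CB, dtype=bool),
    )


def write_backbone_pdb(s: BackboneStructure, path, bfactors: np.ndarray | None = None):
    """Write the backbone as a standard PDB file.

    `bfactors` (one value per residue) fills the B-factor column of every
    atom of that residue; defaults to zero.
    """
    L = len(s)
    if bfactors is None:
        bfactors = np.zeros(L)
    bfactors = np.asarray(bfactors, dtype=np.float64)
    if bfactors.shape != (L,):
        raise ValueError(f"need one B-factor per residue, got {bfactors.shape}")

    n_atoms = int(3 * L + s.has_O.sum() + s.has_CB.sum())
    arr = struc.AtomArray(n_atoms)
    idx = 0
    for i in range(L):
        res3 = _ONE_TO_THREE.get(s.aa[i], "UNK")
        entries = [("N", "N", s.N[i]), ("CA", "C", s.CA[i]), ("C", "C", s.C[i])]
        if s.has_O[i]:
            entries.append(("O", "O", s.O[i]))
        if s.has_CB[i]:
            entries.append(("CB", "C", s.CB[i]))
        for name, element, xyz in entries:
            arr.coord[idx] = xyz
            arr.chain_id[idx] = s.chain_id
            arr.res_id[idx] = int(s.seq_pos[i])
            arr.res_name[idx] = res3
            arr.atom_name[idx] = name
            arr.element[idx] = element
            arr.hetero[idx] = False
            idx += 1
    arr.set_annotation("b_factor", np.repeat(
        bfactors, [3 + int(s.has_O[i]) + int(s.has_CB[i]) for i in range(L)]))
    pdb = pdb_io.PDBFile()
    pdb_io.set_structure(pdb, arr)
    pdb.write(str(path))
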