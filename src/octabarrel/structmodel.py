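"""Core structural data model and PDB input/output.

A :class:`StructureModel` is a single protein chain represented by its
backbone atoms (N, CA, C, O per residue) plus an optional three-state
secondary-structure string.  Designed side chains are represented only by an
idealized pseudo-CB, reconstructed on demand from the backbone
(:func:`idealized_cb`), so models never carry rotamer-level detail.

Residue numbering is 1-based and sequential, chain 'A', no insertion codes:
designed proteins need no crystallographic bookkeeping.  Hydrogens are never
stored; the amide H needed for hydrogen-bond detection is reconstructed
geometrically in :mod:`octabarrel.secstruct`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .geometry import IDEAL_GEOMETRY, place_atom

ATOM_ORDER = ("N", "CA", "C", "O")

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
AA1_TO_3["X"] = "UNK"

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"


class StructureError(ValueError):
    """Structured error for invalid or incomplete models."""


@dataclass
class ResidueRecord:
    """One residue: 1-based index, one-letter code, backbone atom map."""

    index: int
    aa: str
    atoms: dict

    def __post_init__(self):
        for name in ("N", "CA", "C"):
            if name not in self.atoms:
                raise StructureError(
                    f"residue {self.index} ({self.aa}): missing backbone atom {name}"
                )
        for name, xyz in self.atoms.items():
            if not np.all(np.isfinite(xyz)):
                raise StructureError(
                    f"residue {self.index} ({self.aa}): non-finite coordinate for {name}"
                )


@dataclass
class StructureModel:
    """Single-chain backbone model.

    ``coords`` has shape (n_res, 4, 3) in ATOM_ORDER; ``seq`` is the
    one-letter sequence; ``ss3`` (optional) labels each residue H/E/L.
    ``meta`` carries builder bookkeeping (loop spans, ensemble seeds, ...).
    """

    coords: np.ndarray
    seq: str
    chain_id: str = "A"
    ss3: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (4, 3):
            raise StructureError("coords must have shape (n_res, 4, 3)")
        if len(self.seq) != self.coords.shape[0]:
            raise StructureError("sequence length does not match coordinates")
        if self.ss3 is not None and len(self.ss3) != len(self.seq):
            raise StructureError("ss3 length does not match residue count")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def residues(self) -> list[ResidueRecord]:
        out = []
        for i in range(len(self)):
            atoms = {name: self.coords[i, j].copy() for j, name in enumerate(ATOM_ORDER)}
            out.append(ResidueRecord(index=i + 1, aa=self.seq[i], atoms=atoms))
        return out

    def ca(self) -> np.ndarray:
        return self.coords[:, 1]

    def validate_chain(self, lo: float = 2.8, hi: float = 4.2) -> bool:
        """True when every consecutive CA-CA distance lies in [lo, hi] A."""
        if len(self) < 2:
            return True
        d = np.linalg.norm(np.diff(self.ca(), axis=0), axis=1)
        return bool(np.all((d >= lo) & (d <= hi)))

    def copy(self) -> "StructureModel":
        return StructureModel(
            coords=self.coords.copy(), seq=self.seq, chain_id=self.chain_id,
            ss3=self.ss3, meta=dict(self.meta),
        )


def read_pdb(path, chain_id: str | None = None) -> StructureModel:
    """Read a single-chain backbone model from a PDB file.

    Alternate locations resolve to altloc 'A' or blank; insertion codes are
    rejected.  A residue missing any of N, CA, C raises a
    :class:`StructureError` naming the residue.  Files with multiple chains
    require an explicit ``chain_id``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    f = pdb.PDBFile.read(str(path))
    arr = f.get_structure(model=1, altloc="first")
    arr = arr[struc.filter_amino_acids(arr)]
    if arr.array_length() == 0:
        raise StructureError(f"{path}: no protein ATOM records")
    chains = sorted(set(arr.chain_id))
    if chain_id is None:
        if len(chains) > 1:
            raise StructureError(
                f"{path}: multiple chains present ({', '.join(chains)}); "
                "pass an explicit chain id to select one"
            )
        chain_id = chains[0]
    arr = arr[arr.chain_id == chain_id]
    if arr.array_length() == 0:
        raise StructureError(f"{path}: chain {chain_id!r} not found")
    if np.any(arr.ins_code != ""):
        raise StructureError(f"{path}: insertion codes are not supported")

    res_ids = arr.res_id
    order = np.unique(res_ids)
    coords = np.zeros((len(order), 4, 3))
    seq = []
    for i, rid in enumerate(order):
        mask = res_ids == rid
        res = arr[mask]
        name3 = res.res_name[0]
        aa = AA3_TO_1.get(name3, "X")
        seq.append(aa)
        for j, atom_name in enumerate(ATOM_ORDER):
            sel = res[res.atom_name == atom_name]
            if sel.array_length() == 0:
                if atom_name == "O":
                    # tolerate a missing terminal oxygen by rebuilding it later
                    coords[i, j] = np.nan
                    continue
                raise StructureError(
                    f"{path}: residue {rid} ({name3}) is missing backbone atom {atom_name}"
                )
            coords[i, j] = sel.coord[0]
    coords = _fill_missing_oxygens(coords)
    return StructureModel(coords=coords, seq="".join(seq), chain_id=str(chain_id))


def _fill_missing_oxygens(coords: np.ndarray) -> np.ndarray:
    g = IDEAL_GEOMETRY
    for i in range(coords.shape[0]):
        if np.any(np.isnan(coords[i, 3])):
            N, CA, C = coords[i, 0], coords[i, 1], coords[i, 2]
            if i + 1 < coords.shape[0]:
                coords[i, 3] = place_atom(coords[i + 1, 0], CA, C,
                                          g["C_O"], g["CA_C_O"], 180.0)
            else:
                coords[i, 3] = place_atom(N, CA, C, g["C_O"], g["CA_C_O"], 0.0)
    return coords


def write_pdb(model: StructureModel, path) -> None:
    """Write standard ATOM/TER/END records, occupancy 1.00 and B-factor 0.00."""
    if len(model) == 0:
        raise StructureError("cannot write an empty model")
    n_res = len(model)
    n_atoms = n_res * 4
    arr = struc.AtomArray(n_atoms)
    arr.coord = model.coords.reshape(-1, 3)
    arr.chain_id = np.full(n_atoms, model.chain_id)
    arr.res_id = np.repeat(np.arange(1, n_res + 1), 4)
    arr.res_name = np.repeat([AA1_TO_3.get(a, "UNK") for a in model.seq], 4)
    arr.atom_name = np.tile(np.array(ATOM_ORDER), n_res)
    arr.element = np.tile(np.array(["N", "C", "C", "O"]), n_res)
    arr.hetero = np.zeros(n_atoms, dtype=bool)
    arr.set_annotation("occupancy", np.ones(n_atoms))
    arr.set_annotation("b_factor", np.zeros(n_atoms))
    f = pdb.PDBFile()
    f.set_structure(arr)
    f.write(str(path))


def idealized_cb(res: ResidueRecord) -> np.ndarray | None:
    """Idealized CB from backbone N, CA, C; ``None`` for glycine.

    Construction: NeRF placement with CA-CB = 1.53 A, angle N-CA-CB = 110.5
    deg and improper dihedral C-N-CA-CB = -122.6 deg (L-amino-acid
    chirality), which puts CB on the opposite side of the backbone plane
    from the carbonyl.
    """
    if res.aa == "G":
        return None
    return _pseudo_cb_from_backbone(res.atoms["N"], res.atoms["CA"], res.atoms["C"])


def _pseudo_cb_from_backbone(N: np.ndarray, CA: np.ndarray, C: np.ndarray) -> np.ndarray:
    g = IDEAL_GEOMETRY
    v1 = CA - N
    v2 = C - CA
    cross = np.linalg.norm(np.cross(v1, v2))
    if cross < 1e-6:
        raise StructureError("collinear N, CA, C: cannot place CB")
    return place_atom(C, N, CA, g["CA_CB"], g["N_CA_CB"], g["C_N_CA_CB"])


def pseudo_cb_array(model: StructureModel) -> np.ndarray:
    """Virtual CB positions for every residue, glycine included.

    Energy and classification geometry treat glycine as carrying a virtual
    CB at the ideal position so that burial and contact measures depend only
    on the backbone, not on the working sequence.  Vectorized NeRF placement
    (same construction as :func:`idealized_cb`).
    """
    g = IDEAL_GEOMETRY
    N = model.coords[:, 0]
    CA = model.coords[:, 1]
    C = model.coords[:, 2]
    # NeRF frame of place_atom(C, N, CA, ...): bc = CA - N, ab = N - C
    bc = CA - N
    bc /= np.linalg.norm(bc, axis=1, keepdims=True)
    ab = N - C
    nv = np.cross(ab, bc)
    norms = np.linalg.norm(nv, axis=1, keepdims=True)
    if np.any(norms < 1e-6):
        raise StructureError("collinear N, CA, C: cannot place CB")
    nv /= norms
    mv = np.cross(nv, bc)
    ang = np.deg2rad(g["N_CA_CB"])
    dih = np.deg2rad(g["C_N_CA_CB"])
    bond = g["CA_CB"]
    d0 = -bond * np.cos(ang)
    d1 = bond * np.sin(ang) * np.cos(dih)
    d2 = bond * np.sin(ang) * np.sin(dih)
    return CA + d0 * bc + d1 * mv + d2 * nv


def read_fasta(path) -> str:
    """Read a single-record FASTA sequence (uppercased)."""
    lines = Path(path).read_text().splitlines()
    seqs = []
    n_headers = 0
    for ln in lines:
        if ln.startswith(">"):
            n_headers += 1
            continue
        seqs.append(ln.strip())
    if n_headers > 1:
        raise StructureError(f"{path}: expected a single FASTA record")
    seq = "".join(seqs).upper()
    if not seq:
        raise StructureError(f"{path}: empty sequence")
    bad = set(seq) - set(CANONICAL_AA + "X")
    if bad:
        raise StructureError(f"{path}: invalid letters {sorted(bad)}")
    return seq


def write_fasta(seq: str, path, header: str = "design") -> None:
    with open(path, "w") as fh:
        fh.write(f">{header}\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i:i + 60] + "\n")
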