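"""Idealized (beta/alpha)8 barrel backbone generation.

The inner sheet is modelled as a closed barrel of N parallel strands with
shear number S.  Unrolling the barrel surface, strands advance by one
lattice vector per residue (rise ``a`` along the strand) and by one
perpendicular lattice vector per strand (spacing ``b``); closure around N
strands requires the accumulated register to equal S residues, which fixes
the strand tilt  alpha = atan(S a / (N b))  and the barrel circumference
C = sqrt((S a)^2 + (N b)^2).  The classic chord-polygon radius

    R = C / (2 N sin(pi / N))

is exposed by :func:`barrel_radius`; the construction itself wraps the
lattice onto the smooth cylinder of radius C / (2 pi), which differs from R
by well under half an Angstrom for N = 8.

Strand backbones are "stamped": an ideal-torsion reference strand is solved
so its axial rise matches ``a``, the offsets of C, O and N within each
local CA-triple frame are measured once, and those offsets are applied to
the curved CA lattice of the barrel.  Helices are built from ideal torsions
and placed rigidly on a concentric cylinder, antiparallel to their
flanking strands.  Loops are sampled from an internal coil torsion library
and closed by cyclic coordinate descent (CCD); a hook accepts an external
fragment file (TSV of phi, psi, weight rows) in place of the internal
library.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from ._ccd import close_loop
from .geometry import (
    IDEAL_GEOMETRY,
    build_backbone,
    place_atom,
    principal_axis,
    rotation_about_axis,
)
from .structmodel import StructureModel, StructureError

STRAND_PHI = -120.0
HELIX_PHI, HELIX_PSI = -57.0, -47.0

#: internal coil torsion library: (phi, psi, weight, jitter_sd) in degrees
COIL_TORSION_BINS = (
    (-120.0, 140.0, 0.30, 20.0),
    (-75.0, 150.0, 0.25, 20.0),
    (-65.0, -40.0, 0.25, 15.0),
    (60.0, 45.0, 0.10, 15.0),
    (-90.0, 0.0, 0.10, 20.0),
)

CCD_TOL = 0.30          # A, RMS over the three anchor atoms
CCD_MAX_SWEEPS = 40
CLOSURE_ATTEMPTS = 30
CLOSURE_ROUNDS = 4


class LoopClosureError(StructureError):
    """Raised when a loop gap cannot be closed after repeated resampling."""


@dataclass(frozen=True)
class LoopPattern:
    """Ten-symbol fragment secondary-structure pattern around a loop."""

    kind: str      # "ba" (strand -> helix) or "ab" (helix -> strand)
    pattern: str

    def __post_init__(self):
        expected = {"ba": "EELLLLLLHH", "ab": "HHLLLLLLEE"}
        if self.kind not in expected:
            raise ValueError(f"unknown loop kind {self.kind!r}")
        if self.pattern != expected[self.kind]:
            raise ValueError(
                f"{self.kind} loop pattern must be {expected[self.kind]!r}"
            )


BETA_ALPHA = LoopPattern(kind="ba", pattern="EELLLLLLHH")
ALPHA_BETA = LoopPattern(kind="ab", pattern="HHLLLLLLEE")


@dataclass
class BarrelParams:
    """Geometric parameters of the idealized barrel.

    Defaults realise the canonical TIM-barrel lattice (N = 8, S = 8) and a
    216-residue chain: 8 x (6 strand + 9 helix + 2 x 6 loop).
    """

    n_strands: int = 8
    shear: int = 8
    strand_len: int = 6
    helix_len: int = 9
    loop_len: int = 6
    rise_per_res_strand: float = 3.3
    interstrand_dist: float = 4.4
    helix_offset: float = 10.0

    def __post_init__(self):
        if self.n_strands < 3:
            raise ValueError("n_strands must be >= 3")
        if self.shear < 0:
            raise ValueError("shear must be >= 0")
        for name in ("strand_len", "helix_len", "loop_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("rise_per_res_strand", "interstrand_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.helix_offset <= 0:
            raise ValueError("helix_offset must be positive")

    @property
    def total_residues(self) -> int:
        return self.n_strands * (self.strand_len + self.helix_len + 2 * self.loop_len)


@dataclass
class BackboneEnsemble:
    members: list
    seed: int
    params: BarrelParams

    def __len__(self):
        return len(self.members)


def barrel_radius(params: BarrelParams) -> float:
    """Chord-polygon barrel radius R = sqrt((S a)^2 + (N b)^2) / (2 N sin(pi/N))."""
    N, S = params.n_strands, params.shear
    a, b = params.rise_per_res_strand, params.interstrand_dist
    return float(np.hypot(S * a, N * b) / (2.0 * N * np.sin(np.pi / N)))


def strand_tilt_deg(params: BarrelParams) -> float:
    """Strand tilt versus the barrel axis, alpha = atan(S a / (N b)), degrees."""
    return float(np.rad2deg(np.arctan2(
        params.shear * params.rise_per_res_strand,
        params.n_strands * params.interstrand_dist,
    )))


# ---------------------------------------------------------------------------
# reference strand and stamping constants

def _strand_rise(psi: float, phi: float = STRAND_PHI, n: int = 13) -> float:
    coords = build_backbone(np.full(n, phi), np.full(n, psi))
    ca = coords[:, 1]
    axis = principal_axis(ca)
    steps = np.diff(ca, axis=0) @ axis
    return float(np.mean(steps))


def _solve_strand_torsions(a: float) -> tuple[float, float]:
    """psi (at phi = -120) whose ideal-strand axial rise equals ``a``."""
    lo, hi = 100.0, 178.0
    f = lambda psi: _strand_rise(psi) - a
    if f(lo) * f(hi) > 0:
        raise ValueError(
            f"rise_per_res_strand={a} not achievable by an ideal strand"
        )
    psi = brentq(f, lo, hi, xtol=1e-6)
    return STRAND_PHI, float(psi)


def _stamp_constants(phi: float, psi: float) -> dict:
    """Offsets of C, O, N(next) within the local CA-triple frame of an
    ideal strand, plus its CA-CA distance.  The uniform-torsion chain has
    one-residue screw symmetry, so a single interior peptide suffices."""
    coords = build_backbone(np.full(13, phi), np.full(13, psi))
    ca = coords[:, 1]
    i = 5
    u, m, n = _triple_frame(ca[i], ca[i + 1], ca[i + 2])
    B = np.stack([u, m, n])
    return {
        "C": B @ (coords[i, 2] - ca[i]),
        "O": B @ (coords[i, 3] - ca[i]),
        "N1": B @ (coords[i + 1, 0] - ca[i]),
        "d_ca": float(np.linalg.norm(ca[i + 1] - ca[i])),
    }


def _triple_frame(p0, p1, p2):
    u = p1 - p0
    u = u / np.linalg.norm(u)
    t = p2 - p1
    n = np.cross(u, t)
    nn = np.linalg.norm(n)
    if nn < 1e-8:
        raise ValueError("collinear CA triple in stamping frame")
    n = n / nn
    m = np.cross(n, u)
    return u, m, n


def _stamp_backbone(lattice: np.ndarray, const: dict) -> np.ndarray:
    """Backbone (L, 4, 3) for residues 0..L-1 given lattice CAs for indices
    -1 .. L+1 (i.e. an (L+3, 3) array)."""
    L = lattice.shape[0] - 3
    out = np.empty((L, 4, 3))
    for j in range(L):
        i = j + 1  # index of residue j in the padded lattice
        # peptide j-1 -> j supplies N_j
        u, m, n = _triple_frame(lattice[i - 1], lattice[i], lattice[i + 1])
        out[j, 0] = lattice[i - 1] + const["N1"][0] * u + const["N1"][1] * m + const["N1"][2] * n
        # peptide j -> j+1 supplies C_j, O_j
        u, m, n = _triple_frame(lattice[i], lattice[i + 1], lattice[i + 2])
        out[j, 1] = lattice[i]
        out[j, 2] = lattice[i] + const["C"][0] * u + const["C"][1] * m + const["C"][2] * n
        out[j, 3] = lattice[i] + const["O"][0] * u + const["O"][1] * m + const["O"][2] * n
    return out


def _strand_lattice(params: BarrelParams, k: int, d_ca: float) -> np.ndarray:
    """Padded CA lattice (strand_len + 3, 3) for strand k, j = -1 .. L+1."""
    N, S = params.n_strands, params.shear
    a, b = params.rise_per_res_strand, params.interstrand_dist
    L = params.strand_len
    alpha = np.arctan2(S * a, N * b)
    ceff = np.hypot(S * a, N * b)
    r_cyl = ceff / (2.0 * np.pi)
    # pleat amplitude: the CA zigzag is perpendicular to the sheet surface
    # (radial in the barrel), which keeps the carbonyls in the sheet plane
    # pointing at the neighbouring strands
    e = 0.5 * np.sqrt(max(d_ca ** 2 - a ** 2, 0.0))
    pts = np.empty((L + 3, 3))
    for idx, j in enumerate(range(-1, L + 2)):
        s = (j - (L - 1) / 2.0) * a
        sigma = 1.0 if (j + k) % 2 == 0 else -1.0
        x = k * ceff / N + s * np.sin(alpha)
        z = s * np.cos(alpha)
        theta = x / r_cyl
        r = r_cyl + e * sigma
        pts[idx] = (r * np.cos(theta), r * np.sin(theta), z)
    return pts


def _build_helix_template(helix_len: int) -> np.ndarray:
    """Ideal helix with one extra residue supplying the virtual next N."""
    n = helix_len + 1
    return build_backbone(np.full(n, HELIX_PHI), np.full(n, HELIX_PSI))


def _place_helix(params: BarrelParams, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rigidly place helix k between strands k and k+1.

    Returns (backbone (helix_len, 4, 3), virtual next N position)."""
    N, S = params.n_strands, params.shear
    a, b = params.rise_per_res_strand, params.interstrand_dist
    alpha = np.arctan2(S * a, N * b)
    ceff = np.hypot(S * a, N * b)
    r_cyl = ceff / (2.0 * np.pi)
    theta = (k * ceff / N + ceff / (2.0 * N)) / r_cyl
    r_hat = np.array([np.cos(theta), np.sin(theta), 0.0])
    t_hat = np.array([-np.sin(theta), np.cos(theta), 0.0])
    d_target = -(np.sin(alpha) * t_hat + np.cos(alpha) * np.array([0.0, 0.0, 1.0]))
    centroid_target = (r_cyl + params.helix_offset) * r_hat

    tpl = _build_helix_template(params.helix_len)
    ca = tpl[:params.helix_len, 1]
    axis = principal_axis(ca)
    centroid = ca.mean(axis=0)
    # align axis, then roll the first-residue direction toward the barrel
    rot1 = _align_rotation(axis, d_target)
    perp0 = ca[0] - centroid
    perp0 = perp0 - np.dot(perp0, axis) * axis
    perp0 = rot1 @ perp0
    roll_target = -r_hat - np.dot(-r_hat, d_target) * d_target
    rot2 = _align_rotation_about(d_target, perp0, roll_target)
    R = rot2 @ rot1
    flat = tpl.reshape(-1, 3)
    placed = (flat - centroid) @ R.T + centroid_target
    placed = placed.reshape(tpl.shape)
    backbone = placed[:params.helix_len]
    virtual_n = placed[params.helix_len, 0]
    return backbone, virtual_n


def _align_rotation(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation taking unit vector u onto unit vector v (minimal angle)."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.clip(np.dot(u, v), -1.0, 1.0))
    axis = np.cross(u, v)
    na = np.linalg.norm(axis)
    if na < 1e-9:
        if c > 0:
            return np.eye(3)
        # pick any perpendicular axis for a half turn
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        return rotation_about_axis(axis, np.pi)
    return rotation_about_axis(axis / na, np.arctan2(na, c))


def _align_rotation_about(axis: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation about ``axis`` taking the perpendicular component of u
    toward that of v."""
    axis = axis / np.linalg.norm(axis)
    up = u - np.dot(u, axis) * axis
    vp = v - np.dot(v, axis) * axis
    if np.linalg.norm(up) < 1e-9 or np.linalg.norm(vp) < 1e-9:
        return np.eye(3)
    up /= np.linalg.norm(up)
    vp /= np.linalg.norm(vp)
    ang = np.arctan2(np.dot(np.cross(up, vp), axis), np.clip(np.dot(up, vp), -1, 1))
    return rotation_about_axis(axis, ang)


# ---------------------------------------------------------------------------
# scaffold assembly

def build_scaffold(params: BarrelParams | None = None) -> StructureModel:
    """Assemble the strand/helix scaffold; loops are left open.

    The returned model contains only strand and helix residues in chain
    order (s0, h0, s1, h1, ...).  ``meta['gaps']`` records every open loop
    with its anchor geometry for :func:`build_loops`; ``meta['segments']``
    maps scaffold residue spans to their secondary-structure element.
    """
    params = params or BarrelParams()
    phi_s, psi_s = _solve_strand_torsions(params.rise_per_res_strand)
    const = _stamp_constants(phi_s, psi_s)

    coords_parts = []
    ss3_parts = []
    segments = []
    gaps = []
    pos = 0
    for k in range(params.n_strands):
        lattice = _strand_lattice(params, k, const["d_ca"])
        sb = _stamp_backbone(lattice, const)
        coords_parts.append(sb)
        ss3_parts.append("E" * params.strand_len)
        segments.append(("E", pos, pos + params.strand_len))
        pos += params.strand_len
        # virtual N after the strand (for the beta-alpha loop start)
        uL, mL, nL = _triple_frame(lattice[-3], lattice[-2], lattice[-1])
        virt_n_strand = lattice[-3] + (const["N1"][0] * uL + const["N1"][1] * mL
                                       + const["N1"][2] * nL)
        hb, virt_n_helix = _place_helix(params, k)
        gaps.append({
            "kind": "ba", "anchor": pos - 1, "loop_len": params.loop_len,
            "start_n": virt_n_strand, "target": pos,
        })
        coords_parts.append(hb)
        ss3_parts.append("H" * params.helix_len)
        segments.append(("H", pos, pos + params.helix_len))
        pos += params.helix_len
        gaps.append({
            "kind": "ab", "anchor": pos - 1, "loop_len": params.loop_len,
            "start_n": virt_n_helix,
            "target": pos if k < params.n_strands - 1 else None,  # tail loop
        })
    coords = np.concatenate(coords_parts, axis=0)
    model = StructureModel(
        coords=coords,
        seq="G" * coords.shape[0],
        ss3="".join(ss3_parts),
        meta={"segments": segments, "gaps": gaps, "params": params},
    )
    return model


# ---------------------------------------------------------------------------
# loop construction

def _load_fragment_library(path) -> tuple:
    rows = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        phi, psi = float(parts[0]), float(parts[1])
        w = float(parts[2]) if len(parts) > 2 else 1.0
        sd = float(parts[3]) if len(parts) > 3 else 10.0
        rows.append((phi, psi, w, sd))
    if not rows:
        raise ValueError(f"{path}: empty fragment library")
    return tuple(rows)


def _sample_torsions(rng: np.random.Generator, shape, library) -> tuple[np.ndarray, np.ndarray]:
    """Sample (phi, psi) arrays of the given shape from a torsion library."""
    lib = np.asarray(library, dtype=float)  # columns: phi, psi, weight, sd
    weights = lib[:, 2] / lib[:, 2].sum()
    idx = rng.choice(len(lib), size=shape, p=weights)
    sd = lib[idx, 3]
    phi = lib[idx, 0] + rng.normal(0.0, sd)
    psi = lib[idx, 1] + rng.normal(0.0, sd)
    return phi, psi


def _close_gap(scaffold_coords: np.ndarray, gap: dict,
               rng: np.random.Generator, library) -> np.ndarray:
    """Sample and close one loop; returns (loop_len, 4, 3) backbone."""
    L = gap["loop_len"]
    anchor = scaffold_coords[gap["anchor"]]
    # pre-sample every attempt's torsions in one deterministic block
    phis, psis = _sample_torsions(rng, (CLOSURE_ATTEMPTS, L), library)
    phis = np.deg2rad(phis)
    psis = np.deg2rad(psis)
    if gap["target"] is None:
        # open C-terminal tail: one sampled conformation, no closure
        atoms, _, _ = close_loop(anchor, gap["start_n"], phis[:1], psis[:1],
                                 target=None, tol=CCD_TOL,
                                 max_sweeps=CCD_MAX_SWEEPS)
        return _loop_backbone_from_atoms(atoms, next_n=None)
    target = scaffold_coords[gap["target"], :3]  # N, CA, C of the landing residue
    best_atoms, best_err = None, np.inf
    for _ in range(CLOSURE_ROUNDS):
        atoms, err, attempt = close_loop(anchor, gap["start_n"], phis, psis,
                                         target=target, tol=CCD_TOL,
                                         max_sweeps=CCD_MAX_SWEEPS)
        if attempt >= 0:
            return _loop_backbone_from_atoms(atoms, next_n=target[0])
        if err < best_err:
            best_atoms, best_err = atoms, err
        phis, psis = _sample_torsions(rng, (CLOSURE_ATTEMPTS, L), library)
        phis = np.deg2rad(phis)
        psis = np.deg2rad(psis)
    if best_err <= 0.5 and _junction_ok(best_atoms, scaffold_coords, gap):
        return _loop_backbone_from_atoms(best_atoms, next_n=target[0])
    raise LoopClosureError(
        f"could not close {gap['kind']} loop after residue "
        f"{gap['anchor'] + 1} (best closure error {best_err:.2f} A)"
    )


def _junction_ok(atoms: np.ndarray, scaffold_coords: np.ndarray, gap: dict) -> bool:
    L = gap["loop_len"]
    ca_last = atoms[3 * (L - 1) + 1]
    ca_next = scaffold_coords[gap["target"], 1]
    d = np.linalg.norm(ca_last - ca_next)
    return 2.8 <= d <= 4.2


def _loop_backbone_from_atoms(atoms: np.ndarray, next_n: np.ndarray | None) -> np.ndarray:
    g = IDEAL_GEOMETRY
    L = (atoms.shape[0] - 3) // 3
    out = np.empty((L, 4, 3))
    for r in range(L):
        b = 3 * r
        out[r, 0] = atoms[b]
        out[r, 1] = atoms[b + 1]
        out[r, 2] = atoms[b + 2]
        n_next = atoms[b + 3] if r < L - 1 else (next_n if next_n is not None else atoms[3 * L])
        out[r, 3] = place_atom(n_next, out[r, 1], out[r, 2], g["C_O"], g["CA_C_O"], 180.0)
    return out


def build_loops(scaffold: StructureModel, rng_seed: int,
                fragment_library=None) -> StructureModel:
    """Fill every open loop gap of a scaffold; returns the full-length model.

    Loop residues are glycine in the working sequence.  The same seed always
    reproduces the same coordinates.
    """
    if "gaps" not in scaffold.meta:
        raise StructureError("model has no open loop gaps (not a scaffold)")
    library = (_load_fragment_library(fragment_library)
               if fragment_library is not None else COIL_TORSION_BINS)
    rng = np.random.default_rng(int(rng_seed) % (2 ** 31))
    params: BarrelParams = scaffold.meta["params"]
    loops = [_close_gap(scaffold.coords, gap, rng, library)
             for gap in scaffold.meta["gaps"]]

    # interleave scaffold segments and loops in chain order
    parts = []
    ss3_parts = []
    segments = []
    pos = 0
    loop_spans = []
    gi = 0
    for kind, start, end in scaffold.meta["segments"]:
        parts.append(scaffold.coords[start:end])
        ss3_parts.append(kind * (end - start))
        segments.append((kind, pos, pos + end - start))
        pos += end - start
        gap = scaffold.meta["gaps"][gi]
        if gap["anchor"] == end - 1:
            parts.append(loops[gi])
            L = gap["loop_len"]
            ss3_parts.append("L" * L)
            segments.append(("L", pos, pos + L))
            loop_spans.append((pos, pos + L))
            pos += L
            gi += 1
    coords = np.concatenate(parts, axis=0)
    model = StructureModel(
        coords=coords,
        seq="G" * coords.shape[0],
        ss3="".join(ss3_parts),
        meta={
            "segments": segments,
            "loop_spans": loop_spans,
            "params": params,
            "seed": int(rng_seed),
        },
    )
    return model


def generate_ensemble(params: BarrelParams, n: int, seed: int,
                      fragment_library=None) -> BackboneEnsemble:
    """Ensemble of ``n`` barrel conformations sharing one scaffold and
    differing only in loop atoms.  Member i uses seed ``seed + i``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    scaffold = build_scaffold(params)
    members = []
    for i in range(n):
        m = build_loops(scaffold, rng_seed=seed + i, fragment_library=fragment_library)
        m.meta["member"] = i
        members.append(m)
    return BackboneEnsemble(members=members, seed=seed, params=params)


def write_ensemble_manifest(ensemble: BackboneEnsemble, path) -> None:
    """TSV manifest: member id, seed, chain-continuity flag."""
    with open(path, "w") as fh:
        fh.write("member\tseed\tn_res\tcontinuous\n")
        for i, m in enumerate(ensemble.members):
            fh.write(f"{i}\t{m.meta.get('seed', '')}\t{len(m)}\t"
                     f"{int(m.validate_chain())}\n")
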