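"""Low-level backbone geometry: internal-coordinate atom placement, torsions,
rigid transforms and cyclic-coordinate-descent (CCD) loop closure.

All coordinates are in Angstroms in a right-handed frame.  Bond lengths and
angles follow standard (Engh/Huber-style) values collected in
:data:`IDEAL_GEOMETRY`; they are the single source of ideal-geometry constants
for the whole package.
"""

from __future__ import annotations

import numpy as np

# Ideal backbone geometry constants (lengths in A, angles in degrees).
IDEAL_GEOMETRY = {
    "N_CA": 1.458,
    "CA_C": 1.525,
    "C_N": 1.329,
    "C_O": 1.231,
    "CA_CB": 1.53,
    "N_CA_C": 111.2,
    "CA_C_N": 116.2,
    "C_N_CA": 121.7,
    "CA_C_O": 120.8,
    "N_CA_CB": 110.5,
    "OMEGA": 180.0,
    # chirality-fixing improper C-N-CA-CB for an L-amino acid
    "C_N_CA_CB": -122.6,
}


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom ``d`` given three predecessors using the natural extension
    reference frame (NeRF): ``|d-c| = bond``, ``angle(d,c,b) = angle_deg`` and
    ``dihedral(d,c,b,a) = dihedral_deg``.
    """
    ang = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-8:
        raise ValueError("collinear reference atoms in place_atom")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(dih),
        bond * np.sin(ang) * np.sin(dih),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees for four points (IUPAC convention)."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.rad2deg(np.arctan2(y, x)))


def bond_angle(p0, p1, p2) -> float:
    """Angle p0-p1-p2 in degrees."""
    u = np.asarray(p0) - np.asarray(p1)
    v = np.asarray(p2) - np.asarray(p1)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))


def rotation_about_axis(axis: np.ndarray, theta: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis by ``theta`` radians."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


def build_backbone(phi: np.ndarray, psi: np.ndarray,
                   omega: np.ndarray | None = None) -> np.ndarray:
    """Build an ``(n, 4, 3)`` backbone (atom order N, CA, C, O) from torsions.

    ``phi[0]`` is unused (the first residue has no phi); omega defaults to
    trans (180 deg) everywhere.  Oxygens are placed in the peptide plane anti
    to the next nitrogen; the last oxygen uses the psi + 180 convention.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n = len(phi)
    if len(psi) != n:
        raise ValueError("phi and psi must have equal length")
    if omega is None:
        omega = np.full(n, IDEAL_GEOMETRY["OMEGA"])
    g = IDEAL_GEOMETRY
    coords = np.zeros((n, 4, 3))
    # seed frame: N at origin, CA on x-axis, C in the xy-plane
    coords[0, 0] = [0.0, 0.0, 0.0]
    coords[0, 1] = [g["N_CA"], 0.0, 0.0]
    ang = np.deg2rad(g["N_CA_C"])
    coords[0, 2] = coords[0, 1] + g["CA_C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n - 1):
        N, CA, C = coords[i, 0], coords[i, 1], coords[i, 2]
        N1 = place_atom(N, CA, C, g["C_N"], g["CA_C_N"], psi[i])
        CA1 = place_atom(CA, C, N1, g["N_CA"], g["C_N_CA"], omega[i])
        C1 = place_atom(C, N1, CA1, g["CA_C"], g["N_CA_C"], phi[i + 1])
        coords[i + 1, 0] = N1
        coords[i + 1, 1] = CA1
        coords[i + 1, 2] = C1
        coords[i, 3] = place_atom(N1, CA, C, g["C_O"], g["CA_C_O"], 180.0)
    # last oxygen from the psi + 180 convention
    N, CA, C = coords[-1, 0], coords[-1, 1], coords[-1, 2]
    coords[-1, 3] = place_atom(N, CA, C, g["C_O"], g["CA_C_O"], psi[-1] + 180.0)
    return coords


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t with ``R @ P.T + t ~ Q`` (Kabsch)."""
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def principal_axis(points: np.ndarray) -> np.ndarray:
    """First principal axis (unit vector) of a point cloud, sign such that it
    points from the first toward the last point."""
    X = points - points.mean(axis=0)
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    axis = Vt[0]
    if np.dot(points[-1] - points[0], axis) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def ccd_close(atoms: np.ndarray, pivots: list[tuple[int, int]],
              target: np.ndarray, max_sweeps: int = 40,
              tol: float = 0.25) -> tuple[np.ndarray, float]:
    """Cyclic coordinate descent closure.

    ``atoms``: (m, 3) array in chain-build order; the last three rows are the
    virtual anchor copies that must land on ``target`` (3, 3).  ``pivots`` are
    (i, j) index pairs into ``atoms`` defining rotatable bond axes; rotating a
    pivot moves every atom after ``j``.  Returns adjusted atoms and the final
    RMS closure error.

    Each pivot update uses the closed-form optimum: writing the moving target
    copies as M(theta) = O + cos(theta) r + sin(theta) (u x r) about the axis,
    the residual is minimised at theta = atan2(B, A) with
    A = sum f.r and B = sum f.(u x r).
    """
    atoms = atoms.copy()
    m = atoms.shape[0]
    err = _rms(atoms[-3:], target)
    for _ in range(max_sweeps):
        if err <= tol:
            break
        for (i, j) in pivots:
            p = atoms[i]
            u = atoms[j] - p
            nu = np.linalg.norm(u)
            if nu < 1e-9:
                continue
            u = u / nu
            mov = atoms[m - 3:m]
            rel = mov - p
            proj = rel @ u
            O = p + proj[:, None] * u
            r = mov - O
            f = target - O
            A = float(np.sum(f * r))
            B = float(np.sum(f * np.cross(np.broadcast_to(u, r.shape), r)))
            theta = np.arctan2(B, A)
            if abs(theta) < 1e-10:
                continue
            R = rotation_about_axis(u, theta)
            seg = atoms[j + 1:] - p
            atoms[j + 1:] = seg @ R.T + p
        err = _rms(atoms[-3:], target)
    return atoms, err


def _rms(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
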