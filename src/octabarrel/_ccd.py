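"""Hot-path kernels for loop building and CCD closure.

Compiled with numba when available; a pure-NumPy fallback keeps the package
functional (slower) without it.  Semantics are identical on both paths and
are covered by the same tests.  The kernels are written in scalar form to
avoid small-array allocation inside the compiled loops.
"""

from __future__ import annotations

import numpy as np

from .geometry import IDEAL_GEOMETRY

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


_N_CA = IDEAL_GEOMETRY["N_CA"]
_CA_C = IDEAL_GEOMETRY["CA_C"]
_C_N = IDEAL_GEOMETRY["C_N"]
_ANG_N_CA_C = float(np.deg2rad(IDEAL_GEOMETRY["N_CA_C"]))
_ANG_CA_C_N = float(np.deg2rad(IDEAL_GEOMETRY["CA_C_N"]))
_ANG_C_N_CA = float(np.deg2rad(IDEAL_GEOMETRY["C_N_CA"]))
_OMEGA = float(np.deg2rad(IDEAL_GEOMETRY["OMEGA"]))


@njit(cache=True, fastmath=True)
def _place_into(atoms, ia, ib, ic, iout, bond, ang, dih):
    """NeRF placement writing into ``atoms[iout]`` (all scalar math)."""
    ax, ay, az = atoms[ia, 0], atoms[ia, 1], atoms[ia, 2]
    bx, by, bz = atoms[ib, 0], atoms[ib, 1], atoms[ib, 2]
    cx, cy, cz = atoms[ic, 0], atoms[ic, 1], atoms[ic, 2]
    # unit bc
    ux, uy, uz = cx - bx, cy - by, cz - bz
    un = np.sqrt(ux * ux + uy * uy + uz * uz)
    ux, uy, uz = ux / un, uy / un, uz / un
    # n = (b - a) x u, normalized
    vx, vy, vz = bx - ax, by - ay, bz - az
    nx = vy * uz - vz * uy
    ny = vz * ux - vx * uz
    nz = vx * uy - vy * ux
    nn = np.sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx / nn, ny / nn, nz / nn
    # m = n x u
    mx = ny * uz - nz * uy
    my = nz * ux - nx * uz
    mz = nx * uy - ny * ux
    d0 = -bond * np.cos(ang)
    sa = bond * np.sin(ang)
    d1 = sa * np.cos(dih)
    d2 = sa * np.sin(dih)
    atoms[iout, 0] = cx + d0 * ux + d1 * mx + d2 * nx
    atoms[iout, 1] = cy + d0 * uy + d1 * my + d2 * ny
    atoms[iout, 2] = cz + d0 * uz + d1 * mz + d2 * nz


@njit(cache=True, fastmath=True)
def _build_loop(atoms, phi, psi, virtual_phi):
    """Forward NeRF build.  ``atoms[0:2]`` must hold the anchor CA and C,
    ``atoms[2]`` the starting N; fills residues into ``atoms[2:]`` as
    [N1, CA1, C1, ..., NL, CAL, CL, N*, CA*, C*]."""
    L = phi.shape[0]
    # CA1 from (anchor_ca, anchor_c, N1)
    _place_into(atoms, 0, 1, 2, 3, _N_CA, _ANG_C_N_CA, _OMEGA)
    _place_into(atoms, 1, 2, 3, 4, _CA_C, _ANG_N_CA_C, phi[0])
    for r in range(1, L):
        b = 3 * r + 2
        _place_into(atoms, b - 3, b - 2, b - 1, b, _C_N, _ANG_CA_C_N, psi[r - 1])
        _place_into(atoms, b - 2, b - 1, b, b + 1, _N_CA, _ANG_C_N_CA, _OMEGA)
        _place_into(atoms, b - 1, b, b + 1, b + 2, _CA_C, _ANG_N_CA_C, phi[r])
    b = 3 * L + 2
    _place_into(atoms, b - 3, b - 2, b - 1, b, _C_N, _ANG_CA_C_N, psi[L - 1])
    _place_into(atoms, b - 2, b - 1, b, b + 1, _N_CA, _ANG_C_N_CA, _OMEGA)
    _place_into(atoms, b - 1, b, b + 1, b + 2, _CA_C, _ANG_N_CA_C, virtual_phi)


@njit(cache=True, fastmath=True)
def _closure_err(atoms, target):
    m = atoms.shape[0]
    s = 0.0
    for t in range(3):
        dx = atoms[m - 3 + t, 0] - target[t, 0]
        dy = atoms[m - 3 + t, 1] - target[t, 1]
        dz = atoms[m - 3 + t, 2] - target[t, 2]
        s += dx * dx + dy * dy + dz * dz
    return np.sqrt(s / 3.0)


@njit(cache=True, fastmath=True)
def _ccd_kernel(atoms, pivots, target, max_sweeps, tol):
    m = atoms.shape[0]
    err = _closure_err(atoms, target)
    prev = err
    for _ in range(max_sweeps):
        if err <= tol:
            break
        for p in range(pivots.shape[0]):
            i = pivots[p, 0]
            j = pivots[p, 1]
            px, py, pz = atoms[i, 0], atoms[i, 1], atoms[i, 2]
            ux, uy, uz = atoms[j, 0] - px, atoms[j, 1] - py, atoms[j, 2] - pz
            un = np.sqrt(ux * ux + uy * uy + uz * uz)
            if un < 1e-9:
                continue
            ux, uy, uz = ux / un, uy / un, uz / un
            A = 0.0
            B = 0.0
            for t in range(3):
                mx = atoms[m - 3 + t, 0] - px
                my = atoms[m - 3 + t, 1] - py
                mz = atoms[m - 3 + t, 2] - pz
                proj = mx * ux + my * uy + mz * uz
                rx, ry, rz = mx - proj * ux, my - proj * uy, mz - proj * uz
                fx = target[t, 0] - px - proj * ux
                fy = target[t, 1] - py - proj * uy
                fz = target[t, 2] - pz - proj * uz
                A += fx * rx + fy * ry + fz * rz
                cx = uy * rz - uz * ry
                cy = uz * rx - ux * rz
                cz = ux * ry - uy * rx
                B += fx * cx + fy * cy + fz * cz
            theta = np.arctan2(B, A)
            if abs(theta) < 1e-10:
                continue
            ct = np.cos(theta)
            st = np.sin(theta)
            for q in range(j + 1, m):
                rx, ry, rz = atoms[q, 0] - px, atoms[q, 1] - py, atoms[q, 2] - pz
                proj = rx * ux + ry * uy + rz * uz
                wx, wy, wz = rx - proj * ux, ry - proj * uy, rz - proj * uz
                cx = uy * wz - uz * wy
                cy = uz * wx - ux * wz
                cz = ux * wy - uy * wx
                atoms[q, 0] = px + proj * ux + ct * wx + st * cx
                atoms[q, 1] = py + proj * uy + ct * wy + st * cy
                atoms[q, 2] = pz + proj * uz + ct * wz + st * cz
        err = _closure_err(atoms, target)
        if prev - err < 5e-4:  # stalled in a local minimum
            break
        prev = err
    return err


@njit(cache=True, fastmath=True)
def _close_loop_batch(anchor_ca, anchor_c, start_n, phis, psis, virtual_phi,
                      target, tol, max_sweeps, pivots):
    """Try each pre-sampled torsion set until one closes.  Returns
    (work array, err, attempt index); attempt index -1 means no attempt met
    the tolerance and the best one is returned."""
    T, L = phis.shape
    natoms = 3 * L + 5  # 2 anchor atoms + loop + 3 virtual
    atoms = np.empty((natoms, 3))
    best = np.empty((natoms, 3))
    atoms[0] = anchor_ca
    atoms[1] = anchor_c
    atoms[2] = start_n
    best_err = 1e30
    for t in range(T):
        _build_loop(atoms, phis[t], psis[t], virtual_phi)
        err = _ccd_kernel(atoms, pivots, target, max_sweeps, tol)
        if err < best_err:
            best[:] = atoms
            best_err = err
        if err <= tol:
            # junction CA-CA continuity with the landing residue
            dx = atoms[3 * (L - 1) + 3, 0] - target[1, 0]
            dy = atoms[3 * (L - 1) + 3, 1] - target[1, 1]
            dz = atoms[3 * (L - 1) + 3, 2] - target[1, 2]
            dd = np.sqrt(dx * dx + dy * dy + dz * dz)
            if 2.8 <= dd <= 4.2:
                return atoms, err, t
    return best, best_err, -1


def close_loop(anchor: np.ndarray, start_n: np.ndarray,
               phis: np.ndarray, psis: np.ndarray,
               target: np.ndarray | None,
               tol: float, max_sweeps: int,
               virtual_phi: float = float(np.deg2rad(-120.0))):
    """Close (or, with ``target=None``, just build) one loop.

    ``phis``/``psis`` are (attempts, L) arrays in radians.  Returns
    (atoms (3L+3, 3) in build order [N1, CA1, C1, ...], closure_error,
    attempt_index); attempt_index is -1 when no attempt met the tolerance
    (the best attempt is returned).
    """
    phis = np.ascontiguousarray(phis, dtype=float)
    psis = np.ascontiguousarray(psis, dtype=float)
    L = phis.shape[1]
    if target is None:
        atoms = np.empty((3 * L + 5, 3))
        atoms[0], atoms[1], atoms[2] = anchor[1], anchor[2], start_n
        _build_loop(atoms, phis[0], psis[0], virtual_phi)
        return atoms[2:], 0.0, 0
    # pivot axes, offset by the 2 anchor rows: phi/psi of each loop residue
    # plus the virtual phi
    pivots = np.empty((2 * L + 1, 2), dtype=np.int64)
    for r in range(L):
        pivots[2 * r] = (3 * r + 2, 3 * r + 3)
        pivots[2 * r + 1] = (3 * r + 3, 3 * r + 4)
    pivots[2 * L] = (3 * L + 2, 3 * L + 3)
    atoms, err, attempt = _close_loop_batch(
        np.ascontiguousarray(anchor[1]), np.ascontiguousarray(anchor[2]),
        np.ascontiguousarray(start_n), phis, psis, virtual_phi,
        np.ascontiguousarray(target), tol, max_sweeps, pivots)
    return atoms[2:], err, attempt
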