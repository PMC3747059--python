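"""Shrake-Rupley solvent-accessible surface area on the reduced
backbone + pseudo-CB representation.

Sphere sampling uses a deterministic golden-spiral point set, so results
are exactly reproducible for a fixed ``points`` count.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

try:  # pragma: no cover
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


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic, nearly even unit-sphere sampling (Fibonacci spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


@njit(cache=True, fastmath=True)
def _atom_sasa_kernel(centers, radii, probe, sphere, neigh_idx, neigh_start,
                      neigh_count, out):
    n_atoms = centers.shape[0]
    n_pts = sphere.shape[0]
    for i in range(n_atoms):
        ri = radii[i] + probe
        exposed = 0
        for p in range(n_pts):
            px = centers[i, 0] + ri * sphere[p, 0]
            py = centers[i, 1] + ri * sphere[p, 1]
            pz = centers[i, 2] + ri * sphere[p, 2]
            free = True
            for kk in range(neigh_count[i]):
                j = neigh_idx[neigh_start[i] + kk]
                rj = radii[j] + probe
                dx = px - centers[j, 0]
                dy = py - centers[j, 1]
                dz = pz - centers[j, 2]
                if dx * dx + dy * dy + dz * dz < rj * rj:
                    free = False
                    break
            if free:
                exposed += 1
        out[i] = 4.0 * np.pi * ri * ri * exposed / n_pts


def atom_sasa(centers: np.ndarray, radii: np.ndarray, probe: float = 1.4,
              points: int = 960) -> np.ndarray:
    """Per-atom accessible area (A^2)."""
    centers = np.ascontiguousarray(centers, dtype=float)
    radii = np.ascontiguousarray(radii, dtype=float)
    n = centers.shape[0]
    if n == 0:
        return np.zeros(0)
    sphere = golden_spiral_points(points)
    tree = cKDTree(centers)
    cutoff = 2.0 * (radii.max() + probe)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        # adjacency restricted to spheres that can actually intersect
        d = np.linalg.norm(centers[pairs[:, 0]] - centers[pairs[:, 1]], axis=1)
        keep = d < radii[pairs[:, 0]] + radii[pairs[:, 1]] + 2 * probe
        pairs = pairs[keep]
        src = np.concatenate([pairs[:, 0], pairs[:, 1]])
        dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
        order = np.argsort(src, kind="stable")
        src, dst = src[order], dst[order]
        neigh_count = np.bincount(src, minlength=n).astype(np.int64)
        neigh_start = np.concatenate([[0], np.cumsum(neigh_count)[:-1]]).astype(np.int64)
        neigh_idx = dst.astype(np.int64)
    else:
        neigh_count = np.zeros(n, dtype=np.int64)
        neigh_start = np.zeros(n, dtype=np.int64)
        neigh_idx = np.zeros(0, dtype=np.int64)
    out = np.empty(n)
    _atom_sasa_kernel(centers, radii, probe, sphere, neigh_idx, neigh_start,
                      neigh_count, out)
    return out
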