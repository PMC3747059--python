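"""Packaged knowledge tables used by the design energy and the assessment
battery.

Provenance notes
----------------
* ``HYDROPATHY``: Kyte-Doolittle sidechain hydropathy divided by 4.5 so the
  scale spans [-1, 1], with glycine pinned to exactly 0 as the neutral
  reference (it has no side chain in our pseudo-CB representation).
* ``SS_PROPENSITY``: classic Chou-Fasman helix/sheet/turn propensities,
  renormalized per amino acid into a probability triple over (H, E, L).
* ``CONTACT_TABLE``: constructed 20x20 pairwise contact energy,
  e(a, b) = -h(a) h(b) + 0.5 q(a) q(b), i.e. hydrophobic-hydrophobic
  contacts are favorable and like-charge contacts unfavorable.  It is a
  smooth surrogate for statistical contact potentials, not mined from the
  PDB.
* ``SIDECHAIN_RADIUS``: effective side-chain sphere radius from mean residue
  volumes (Zamyatnin), r = (3 (V - V_Gly) / 4 pi)^(1/3); used both as the
  pseudo-CB sphere radius in surface-area calculations and to scale steric
  footprints.
* ``EXPOSURE_TABLE``: constructed joint probability P(aa, exposure bin) over
  5 relative-SASA bins.  P(bin | aa) follows a Boltzmann weight
  exp(-kappa h(aa) c_bin) with c_bin the bin center mapped to [-1, 1] and
  kappa = 1.5; amino-acid marginals are uniform.  This encodes the standard
  observation that hydrophobics favor burial; it is a documented surrogate,
  not a PDB-derived statistic.
"""

from __future__ import annotations

import numpy as np

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

_KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": 0.0, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}
HYDROPATHY = {a: v / 4.5 for a, v in _KYTE_DOOLITTLE.items()}

FORMAL_CHARGE = {a: 0.0 for a in AA_ORDER}
FORMAL_CHARGE.update({"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0})

# Chou-Fasman (P_alpha, P_beta, P_turn)
_CHOU_FASMAN = {
    "A": (1.42, 0.83, 0.66), "R": (0.98, 0.93, 0.95), "N": (0.67, 0.89, 1.56),
    "D": (1.01, 0.54, 1.46), "C": (0.70, 1.19, 1.19), "Q": (1.11, 1.10, 0.98),
    "E": (1.51, 0.37, 0.74), "G": (0.57, 0.75, 1.56), "H": (1.00, 0.87, 0.95),
    "I": (1.08, 1.60, 0.47), "L": (1.21, 1.30, 0.59), "K": (1.14, 0.74, 1.01),
    "M": (1.45, 1.05, 0.60), "F": (1.13, 1.38, 0.60), "P": (0.57, 0.55, 1.52),
    "S": (0.77, 0.75, 1.43), "T": (0.83, 1.19, 0.96), "W": (1.08, 1.37, 0.96),
    "Y": (0.69, 1.47, 1.14), "V": (1.06, 1.70, 0.50),
}

#: P(state | aa) over states (H, E, L), rows sum to 1
SS_PROPENSITY = {
    a: tuple(np.array(v) / np.sum(v)) for a, v in _CHOU_FASMAN.items()
}


def ss_propensity_matrix() -> np.ndarray:
    """(20, 3) matrix of P(H/E/L | aa) in AA_ORDER."""
    return np.array([SS_PROPENSITY[a] for a in AA_ORDER])


def contact_table() -> np.ndarray:
    """(20, 20) pairwise contact energies in AA_ORDER (symmetric)."""
    h = np.array([HYDROPATHY[a] for a in AA_ORDER])
    q = np.array([FORMAL_CHARGE[a] for a in AA_ORDER])
    return -np.outer(h, h) + 0.5 * np.outer(q, q)


CONTACT_TABLE = contact_table()

# mean residue volumes (A^3), Zamyatnin
_RESIDUE_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
    "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
    "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
    "Y": 193.6, "V": 140.0,
}

SIDECHAIN_RADIUS = {
    a: float((3.0 * max(v - _RESIDUE_VOLUME["G"], 0.0) / (4.0 * np.pi)) ** (1.0 / 3.0))
    for a, v in _RESIDUE_VOLUME.items()
}

# van der Waals radii for backbone atoms (A)
ATOM_RADIUS = {"N": 1.55, "CA": 1.70, "C": 1.70, "O": 1.52}

N_EXPOSURE_BINS = 5
EXPOSURE_BIN_EDGES = np.linspace(0.0, 1.0, N_EXPOSURE_BINS + 1)


def exposure_table(kappa: float = 1.5) -> np.ndarray:
    """(20, 5) joint probability table P(aa, bin); sums to 1."""
    h = np.array([HYDROPATHY[a] for a in AA_ORDER])
    centers = 0.5 * (EXPOSURE_BIN_EDGES[:-1] + EXPOSURE_BIN_EDGES[1:])
    c = 2.0 * centers - 1.0  # map exposure [0, 1] to [-1, 1]
    w = np.exp(-kappa * np.outer(h, c))
    cond = w / w.sum(axis=1, keepdims=True)  # P(bin | aa)
    return cond / 20.0


EXPOSURE_TABLE = exposure_table()

# Ramachandran region boxes (phi_min, phi_max, psi_min, psi_max) in degrees.
# Coarse, documented rectangles: sheet (including the polyproline shoulder),
# right-handed alpha, and left-handed alpha.  "Allowed" expands every favored
# box by RAMA_MARGIN degrees; glycine additionally uses the mirrored boxes.
RAMA_FAVORED = (
    ("beta", -180.0, -45.0, 90.0, 180.0),
    ("beta_wrap", -180.0, -45.0, -180.0, -150.0),
    ("alpha_R", -100.0, -30.0, -80.0, -5.0),
    ("alpha_L", 30.0, 100.0, -20.0, 80.0),
)
RAMA_MARGIN = 20.0

HYDROPHOBIC_AA = set("AVLIMFWY")
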