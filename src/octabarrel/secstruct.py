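"""Secondary structure from coordinates (Kabsch-Sander style) and
three-state per-residue probability predictions.

The hydrogen-bond model is the published Kabsch-Sander electrostatic form

    E = 27.888 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

(27.888 = 0.42 * 0.20 * 332) with a bond declared when E < -0.5 kcal/mol and
|i - j| >= 2.  Amide hydrogens are reconstructed geometrically: H sits 1.0 A
from N along the direction anti to the preceding carbonyl C=O; the first
residue of a segment has no amide H and cannot donate.

The eight-state pattern logic is reduced to three states: n -> n+4 turn
ladders give helix, bridge ladders give strand, everything else is loop,
with minimum run lengths of 4 (helix) and 2 (strand).  The reduction is the
common coarse one; full DSSP fidelity (3-10/pi helices, bends) is out of
scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structmodel import StructureModel, StructureError
from .tables import SS_PROPENSITY

HBOND_Q = 27.888          # kcal/mol * A, = 0.42 * 0.20 * 332
HBOND_CUTOFF = -0.5       # kcal/mol
MIN_HELIX_RUN = 4
MIN_STRAND_RUN = 2
STATES = "HEL"


@dataclass
class SSAssignment:
    states: str
    hbonds: list  # (donor_index, acceptor_index, energy) 0-based

    def __len__(self):
        return len(self.states)


@dataclass
class SSPrediction:
    probs: np.ndarray  # (n, 3) over (H, E, L)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 3:
            raise ValueError("probs must have shape (n, 3)")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("probability rows must sum to 1")

    def __len__(self):
        return self.probs.shape[0]


def amide_hydrogens(model: StructureModel) -> np.ndarray:
    """(n, 3) reconstructed amide H; NaN where no H exists (first residue,
    segment starts after chain breaks, prolines are not special-cased)."""
    n = len(model)
    H = np.full((n, 3), np.nan)
    breaks = chain_breaks(model)
    for i in range(1, n):
        if i in breaks:
            continue
        C_prev = model.coords[i - 1, 2]
        O_prev = model.coords[i - 1, 3]
        d = C_prev - O_prev
        nd = np.linalg.norm(d)
        if nd < 1e-8:
            continue
        H[i] = model.coords[i, 0] + d / nd
    return H


def chain_breaks(model: StructureModel, lo: float = 2.8, hi: float = 4.2) -> set:
    """Indices i whose CA is discontinuous with residue i-1."""
    ca = model.ca()
    d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    return {i + 1 for i in np.nonzero((d < lo) | (d > hi))[0]}


def hbond_energy(donor_N: np.ndarray, donor_H: np.ndarray,
                 acceptor_C: np.ndarray, acceptor_O: np.ndarray) -> float:
    """Kabsch-Sander electrostatic hydrogen-bond energy in kcal/mol.

    Returns +inf when the donor has no amide hydrogen (NaN input)."""
    if np.any(np.isnan(donor_H)):
        return float("inf")
    r_on = np.linalg.norm(acceptor_O - donor_N)
    r_ch = np.linalg.norm(acceptor_C - donor_H)
    r_oh = np.linalg.norm(acceptor_O - donor_H)
    r_cn = np.linalg.norm(acceptor_C - donor_N)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -9.9  # atoms essentially overlapping; clamp like DSSP
    return float(HBOND_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn))


def backbone_hbonds(model: StructureModel, cutoff: float = HBOND_CUTOFF):
    """All (donor i, acceptor j, E) with E < cutoff and |i - j| >= 2.

    Vectorized over an N...O distance prefilter (< 5.2 A)."""
    n = len(model)
    N = model.coords[:, 0]
    C = model.coords[:, 2]
    O = model.coords[:, 3]
    H = amide_hydrogens(model)
    has_h = ~np.isnan(H[:, 0])
    # prefilter on N-O distance
    d_no = np.linalg.norm(N[:, None, :] - O[None, :, :], axis=2)
    di, ai = np.nonzero(d_no < 5.2)
    keep = (np.abs(di - ai) >= 2) & has_h[di]
    di, ai = di[keep], ai[keep]
    if len(di) == 0:
        return []
    r_on = d_no[di, ai]
    r_ch = np.linalg.norm(C[ai] - H[di], axis=1)
    r_oh = np.linalg.norm(O[ai] - H[di], axis=1)
    r_cn = np.linalg.norm(C[ai] - N[di], axis=1)
    rmin = np.minimum.reduce([r_on, r_ch, r_oh, r_cn])
    E = HBOND_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    E = np.where(rmin < 0.5, -9.9, E)
    sel = E < cutoff
    return [(int(d), int(a), float(e)) for d, a, e in zip(di[sel], ai[sel], E[sel])]


def assign_ss(model: StructureModel) -> SSAssignment:
    """Three-state secondary structure from backbone coordinates."""
    n = len(model)
    if n == 0:
        return SSAssignment(states="", hbonds=[])
    bonds = backbone_hbonds(model)
    bond_set = {(d, a) for d, a, _ in bonds}

    def hb(d, a):
        """N-H of residue d donates to C=O of residue a."""
        return (d, a) in bond_set

    # n -> n+4 turns: donor i+4, acceptor i
    turn4 = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        if hb(i + 4, i):
            turn4[i] = True
    helix = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        # two consecutive turns start a minimal helix i+1 .. i+4; a single
        # turn at a helix terminus still covers i .. i+4 which keeps ideal
        # short helices intact
        if turn4[i] and (i + 1 < n and turn4[i + 1]):
            helix[i + 1:i + 5] = True
    # lone turns flanking existing helix extend it by one residue
    for i in range(n - 4):
        if turn4[i] and (helix[i + 1] or (i > 0 and helix[i])):
            helix[i:i + 5] = True

    # bridges
    strand = np.zeros(n, dtype=bool)
    for i in range(1, n - 1):
        for j in range(1, n - 1):
            if abs(i - j) < 3:
                continue
            # Kabsch-Sander bridge rules, written with hb(donor, acceptor):
            # their Hbond(i, j) is "C=O of i accepts N-H of j" = hb(j, i)
            parallel = (hb(j, i - 1) and hb(i + 1, j)) or (hb(i, j - 1) and hb(j + 1, i))
            anti = (hb(j, i) and hb(i, j)) or (hb(j + 1, i - 1) and hb(i + 1, j - 1))
            if parallel or anti:
                strand[i] = True
                strand[j] = True
    # close single-residue gaps inside strand ladders (beta bulge smoothing)
    for i in range(1, n - 1):
        if not strand[i] and strand[i - 1] and strand[i + 1]:
            strand[i] = True
    # ladder-edge extension: a residue flanking a strand run that itself
    # takes part in a long-range backbone H-bond belongs to the ladder even
    # when its own bridge pattern is truncated at the sheet edge
    longrange = np.zeros(n, dtype=bool)
    for d, a, _ in bonds:
        if abs(d - a) >= 3:
            longrange[d] = True
            longrange[a] = True
    for _ in range(2):
        grow = []
        for i in range(n):
            if strand[i] or helix[i] or not longrange[i]:
                continue
            if (i > 0 and strand[i - 1]) or (i + 1 < n and strand[i + 1]):
                grow.append(i)
        if not grow:
            break
        strand[grow] = True

    states = np.full(n, "L", dtype="<U1")
    states[strand] = "E"
    states[helix] = "H"  # helix has priority at overlaps
    states = _enforce_min_runs(states)
    return SSAssignment(states="".join(states), hbonds=bonds)


def _enforce_min_runs(states: np.ndarray) -> np.ndarray:
    out = states.copy()
    n = len(out)
    i = 0
    while i < n:
        j = i
        while j < n and out[j] == out[i]:
            j += 1
        run = j - i
        if out[i] == "H" and run < MIN_HELIX_RUN:
            out[i:j] = "L"
        if out[i] == "E" and run < MIN_STRAND_RUN:
            out[i:j] = "L"
        i = j
    return out


def predict_ss(sequence: str, window: int = 7) -> SSPrediction:
    """Propensity-based three-state prediction (sliding-window average of
    packaged per-residue propensity triples, renormalized per residue).

    A built-in stand-in for an external neural-network predictor; real
    predictions can be supplied through :func:`read_prediction`.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and positive")
    if not sequence:
        raise ValueError("empty sequence")
    base = np.array([SS_PROPENSITY.get(a, (1 / 3, 1 / 3, 1 / 3)) for a in sequence])
    n = len(sequence)
    half = window // 2
    out = np.empty_like(base)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = base[lo:hi].mean(axis=0)
    out /= out.sum(axis=1, keepdims=True)
    return SSPrediction(probs=out)


def read_prediction(path, expected_sequence: str | None = None) -> SSPrediction:
    """Read an ss2-style file: idx, residue, state, P_H, P_E, P_C columns.

    Rows are renormalized to sum exactly 1.  Comment lines (#) and blank
    lines are skipped; a malformed row raises with its line number.
    """
    rows = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
        try:
            triple = [float(parts[3]), float(parts[4]), float(parts[5])]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric probability") from exc
        if min(triple) < 0:
            raise ValueError(f"{path}:{lineno}: negative probability")
        s = sum(triple)
        if s <= 0:
            raise ValueError(f"{path}:{lineno}: zero probability row")
        rows.append((parts[1], [t / s for t in triple]))
    if not rows:
        raise ValueError(f"{path}: no data rows")
    if expected_sequence is not None and len(rows) != len(expected_sequence):
        raise ValueError(
            f"{path}: {len(rows)} rows but expected sequence has "
            f"{len(expected_sequence)} residues"
        )
    return SSPrediction(probs=np.array([r[1] for r in rows]))


def write_prediction(pred: SSPrediction, sequence: str, path) -> None:
    """Write an ss2-style prediction file (idx, aa, state, P_H, P_E, P_C)."""
    if len(pred) != len(sequence):
        raise ValueError("prediction/sequence length mismatch")
    with open(path, "w") as fh:
        fh.write("# idx aa state pH pE pC\n")
        for i, (aa, p) in enumerate(zip(sequence, pred.probs), start=1):
            state = STATES[int(np.argmax(p))]
            fh.write(f"{i} {aa} {state} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
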