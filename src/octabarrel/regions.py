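"""Classification of barrel positions into core, pore and surface regions,
and the region-restricted design alphabets.

Strand positions whose side chain projects toward the barrel interior are
"pore" (the name is kept for historical reasons; the cavity is not an
actual channel), strand positions projecting outward into the sheet-helix
interface are "core", helix positions facing the sheet are "core" and the
remaining helix plus all loop positions are "surface".  The qualitative
inspection this emulates is operationalized as a parameter-free hemisphere
test: the sign of the cosine between the CA->CB direction and the inward
axis direction decides each position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import principal_axis
from .structmodel import StructureModel, StructureError, pseudo_cb_array

REGIONS = ("core", "pore", "surface")

CORE_ALPHABET = frozenset("MAFLIVWYGH")
NO_CYS_ALPHABET = frozenset("ADEFGHIKLMNPQRSTVWY")  # 19 letters, no cysteine
PATCH_REDESIGN_ALPHABET = frozenset("STNDG")  # small hydrophilic side chains


@dataclass(frozen=True)
class RegionAlphabet:
    region: str
    allowed: frozenset


@dataclass
class RegionAssignment:
    """Per-residue region labels plus the geometric rationale score
    (signed cosine of the CB direction against the inward direction)."""

    labels: list
    rationale: np.ndarray

    def __len__(self):
        return len(self.labels)

    def positions(self, region: str) -> list:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        return [i for i, lab in enumerate(self.labels) if lab == region]


def alphabet_for(region: str) -> RegionAlphabet:
    """Design alphabet for a region; cysteine is never allowed anywhere."""
    if region == "core":
        return RegionAlphabet("core", CORE_ALPHABET)
    if region in ("pore", "surface"):
        return RegionAlphabet(region, NO_CYS_ALPHABET)
    raise ValueError(f"unknown region {region!r}")


def barrel_axis(model: StructureModel) -> tuple[np.ndarray, np.ndarray]:
    """(axis unit vector, centroid) of the sheet.

    The axis is the normalized mean of the per-strand direction vectors
    (each strand's first principal axis, oriented N to C).  For parallel
    strands tilted by the shear angle the tangential components cancel
    around the ring, leaving the barrel axis; a plain principal axis of the
    pooled strand CAs would instead pick an in-plane direction for squat
    barrels.  Collinear pooled CAs (a single straight strand, no ring)
    leave the inward direction undefined and raise an error.
    """
    if model.ss3 is None:
        raise StructureError("model has no secondary-structure labels")
    strand_idx = [i for i, s in enumerate(model.ss3) if s == "E"]
    if len(strand_idx) < 3:
        raise StructureError("too few strand residues to define a barrel axis")
    ca_all = model.ca()
    centroid = ca_all[strand_idx].mean(axis=0)
    X = ca_all[strand_idx] - centroid
    _, svals, _ = np.linalg.svd(X, full_matrices=False)
    if svals[1] < 1e-6 * max(svals[0], 1.0):
        raise StructureError("strand CAs are collinear; barrel axis undefined")
    directions = []
    for start, end in _runs(model.ss3, "E"):
        if end - start >= 2:
            directions.append(principal_axis(ca_all[start:end]))
    if not directions:
        raise StructureError("no strand run long enough to define a direction")
    mean_dir = np.mean(directions, axis=0)
    norm = np.linalg.norm(mean_dir)
    if norm < 1e-6:
        raise StructureError("strand directions cancel; barrel axis undefined")
    return mean_dir / norm, centroid


def _runs(ss3: str, state: str):
    out = []
    i = 0
    n = len(ss3)
    while i < n:
        if ss3[i] == state:
            j = i
            while j < n and ss3[j] == state:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def classify_positions(model: StructureModel) -> RegionAssignment:
    """Hemisphere-rule region assignment; requires ss3 labels.

    The rationale score is cos(angle(CA->CB, CA->axis)); positive means the
    virtual CB points toward the barrel axis.
    """
    if model.ss3 is None:
        raise StructureError("model has no secondary-structure labels")
    if "E" not in model.ss3 and "H" not in model.ss3:
        # pure coil: every position is solvent-facing by rule
        return RegionAssignment(labels=["surface"] * len(model),
                                rationale=np.zeros(len(model)))
    cb = pseudo_cb_array(model)
    ca = model.ca()
    axis, centroid = barrel_axis(model)
    labels = []
    rationale = np.zeros(len(model))
    for i, ss in enumerate(model.ss3):
        # foot of the perpendicular from CA to the axis line
        rel = ca[i] - centroid
        foot = centroid + np.dot(rel, axis) * axis
        inward = foot - ca[i]
        nin = np.linalg.norm(inward)
        cbdir = cb[i] - ca[i]
        if nin < 1e-9:
            cos = 0.0
        else:
            cos = float(np.dot(cbdir, inward) / (np.linalg.norm(cbdir) * nin))
        rationale[i] = cos
        if ss == "E":
            labels.append("pore" if cos > 0 else "core")
        elif ss == "H":
            labels.append("core" if cos > 0 else "surface")
        else:
            labels.append("surface")
    return RegionAssignment(labels=labels, rationale=rationale)


def write_assignment_tsv(model: StructureModel, assignment: RegionAssignment,
                         path) -> None:
    with open(path, "w") as fh:
        fh.write("index\taa\tss3\tregion\trationale\n")
        for i in range(len(model)):
            fh.write(f"{i + 1}\t{model.seq[i]}\t{model.ss3[i]}\t"
                     f"{assignment.labels[i]}\t{assignment.rationale[i]:.4f}\n")
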