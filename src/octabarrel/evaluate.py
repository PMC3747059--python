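"""Model assessment battery: secondary-structure agreement (SS_score),
amino-acid composition and side-chain-nature categories against natural
TIM-barrel control statistics, solvent-accessible surface area and exposure
probabilities, hydrophobic surface patches, and a Ramachandran report.

SS_score convention
-------------------
Per residue, with P the predicted probability of the coordinate-assigned
state and P_ran = 0.33 the random three-state baseline,

    s_i = (P_i - P_ran) / (1 - P_ran),        score = -mean(s_i)

so perfect agreement scores -1 and a random predictor scores 0; the score
is energy-like (lower is better) and lives in [-1, P_ran / (1 - P_ran)].
The formula is isolated in :func:`ss_score` so the convention can be
amended in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from . import reference as ref
from ._sasa import atom_sasa
from .geometry import build_backbone, dihedral
from .secstruct import SSAssignment, SSPrediction, assign_ss, predict_ss
from .structmodel import (
    CANONICAL_AA,
    StructureModel,
    StructureError,
    pseudo_cb_array,
)
from .tables import (
    AA_ORDER,
    ATOM_RADIUS,
    EXPOSURE_BIN_EDGES,
    EXPOSURE_TABLE,
    HYDROPHOBIC_AA,
    RAMA_FAVORED,
    RAMA_MARGIN,
    SIDECHAIN_RADIUS,
)

P_RAN = 0.33


@dataclass
class SSAgreementScore:
    p_per_residue: np.ndarray
    score: float
    p_ran: float = P_RAN


def ss_score(pred: SSPrediction, assign: SSAssignment) -> SSAgreementScore:
    """Energy-like agreement between a three-state prediction and the
    coordinate-derived assignment (see module docstring for the form)."""
    if len(pred) != len(assign.states):
        raise ValueError(
            f"prediction has {len(pred)} residues, assignment "
            f"{len(assign.states)}"
        )
    state_idx = {"H": 0, "E": 1, "L": 2}
    p = np.array([pred.probs[i, state_idx[s]]
                  for i, s in enumerate(assign.states)])
    s = (p - P_RAN) / (1.0 - P_RAN)
    return SSAgreementScore(p_per_residue=p, score=float(-np.mean(s)))


# ---------------------------------------------------------------------------
# composition and categories

@dataclass
class CompositionProfile:
    fractions: dict  # aa -> percent of chain
    n_res: int


@dataclass
class CategoryProfile:
    values: dict  # category -> percent


def composition(sequence: str) -> CompositionProfile:
    """Percentage of each amino acid in the chain."""
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - set(CANONICAL_AA)
    if bad:
        raise ValueError(f"invalid letters in sequence: {sorted(bad)}")
    n = len(sequence)
    fractions = {aa: 100.0 * sequence.count(aa) / n for aa in AA_ORDER}
    return CompositionProfile(fractions=fractions, n_res=n)


def category_profile(comp: CompositionProfile) -> CategoryProfile:
    """Side-chain-nature category percentages (sums of member amino acids,
    one decimal).  Categories overlap, so they do not sum to 100."""
    values = {}
    for cat, members in ref.CATEGORY_MEMBERS.items():
        values[cat] = round(sum(comp.fractions.get(a, 0.0) for a in members), 1)
    return CategoryProfile(values=values)


def compare_to_control(profile) -> list[dict]:
    """z-scores of a composition or category profile against the packaged
    control statistics; |z| > 2 is flagged."""
    if isinstance(profile, CompositionProfile):
        items = profile.fractions
        stats = ref.CONTROL_COMPOSITION
    elif isinstance(profile, CategoryProfile):
        items = profile.values
        stats = ref.CONTROL_CATEGORIES
    else:
        raise TypeError("expected a CompositionProfile or CategoryProfile")
    out = []
    for name, value in items.items():
        if name not in stats:
            continue
        mean, sd = stats[name]
        if sd == 0:
            out.append({"name": name, "value": value, "mean": mean, "sd": sd,
                        "z": None, "flagged": False, "note": "sd is zero"})
            continue
        z = (value - mean) / sd
        out.append({"name": name, "value": value, "mean": mean, "sd": sd,
                    "z": round(float(z), 3), "flagged": bool(abs(z) > 2)})
    return out


# ---------------------------------------------------------------------------
# solvent accessibility

@dataclass
class SASAProfile:
    absolute: np.ndarray   # per-residue A^2
    relative: np.ndarray   # absolute / per-aa isolated-residue maximum
    per_atom: np.ndarray
    probe: float
    points: int


_MAX_SASA_CACHE: dict = {}


def _residue_atoms(model: StructureModel, sequence: str):
    """Atom centers, radii and residue indices for the reduced
    representation (backbone + one side-chain sphere at the pseudo-CB)."""
    cb = pseudo_cb_array(model)
    centers = []
    radii = []
    res_idx = []
    for i in range(len(model)):
        for j, name in enumerate(("N", "CA", "C", "O")):
            centers.append(model.coords[i, j])
            radii.append(ATOM_RADIUS[name])
            res_idx.append(i)
        r_sc = SIDECHAIN_RADIUS.get(sequence[i], 0.0)
        if r_sc > 0:
            centers.append(cb[i])
            radii.append(r_sc)
            res_idx.append(i)
    return np.array(centers), np.array(radii), np.array(res_idx)


def max_sasa_reference(aa: str, probe: float = 1.4, points: int = 960) -> float:
    """Accessible area of an isolated residue of type ``aa`` in the reduced
    representation; computed once and cached."""
    key = (aa, probe, points)
    if key not in _MAX_SASA_CACHE:
        coords = build_backbone(np.array([-120.0]), np.array([130.0]))
        model = StructureModel(coords=coords, seq=aa)
        centers, radii, _ = _residue_atoms(model, aa)
        _MAX_SASA_CACHE[key] = float(atom_sasa(centers, radii, probe, points).sum())
    return _MAX_SASA_CACHE[key]


def sasa(model: StructureModel, sequence: str | None = None,
         probe: float = 1.4, points: int = 960) -> SASAProfile:
    """Per-residue absolute and relative SASA (deterministic point set)."""
    sequence = sequence if sequence is not None else model.seq
    if len(sequence) != len(model):
        raise ValueError("sequence length does not match model")
    centers, radii, res_idx = _residue_atoms(model, sequence)
    per_atom = atom_sasa(centers, radii, probe, points)
    absolute = np.zeros(len(model))
    np.add.at(absolute, res_idx, per_atom)
    relative = np.array([
        absolute[i] / max_sasa_reference(sequence[i], probe, points)
        for i in range(len(model))
    ])
    relative = np.clip(relative, 0.0, 1.2)
    return SASAProfile(absolute=absolute, relative=relative, per_atom=per_atom,
                       probe=probe, points=points)


def sasa_probability(profile: SASAProfile, sequence: str,
                     table: np.ndarray | None = None) -> dict:
    """Exposure-propensity probabilities from a packaged joint table
    P(aa, bin) over 5 relative-SASA bins.

    Returns per-residue P(aa | bin) and P(bin | aa) plus their means over
    the chain (the two aggregate probabilities reported alongside the
    control statistics).
    """
    table = EXPOSURE_TABLE if table is None else np.asarray(table, dtype=float)
    p_bin = table.sum(axis=0)          # P(bin)
    p_aa = table.sum(axis=1)           # P(aa)
    bins = np.clip(
        np.searchsorted(EXPOSURE_BIN_EDGES[1:-1],
                        np.clip(profile.relative, 0.0, 1.0), side="right"),
        0, len(EXPOSURE_BIN_EDGES) - 2,
    )
    aa_idx = np.array([AA_ORDER.index(a) for a in sequence])
    joint = table[aa_idx, bins]
    p_aa_given_bin = joint / p_bin[bins]
    p_bin_given_aa = joint / p_aa[aa_idx]
    return {
        "bins": bins,
        "p_aa_given_bin": p_aa_given_bin,
        "p_bin_given_aa": p_bin_given_aa,
        "mean_p_aa_given_bin": float(p_aa_given_bin.mean()),
        "mean_p_bin_given_aa": float(p_bin_given_aa.mean()),
    }


# ---------------------------------------------------------------------------
# hydrophobic patches

@dataclass
class PatchReport:
    patches: list          # list of (sorted residue indices, area A^2)
    total_area: float


def hydrophobic_patches(model: StructureModel, sequence: str,
                        sasa_profile: SASAProfile,
                        rel_threshold: float = 0.25,
                        contact_dist: float = 8.0,
                        min_area: float = 50.0) -> PatchReport:
    """Connected clusters of exposed hydrophobic residues.

    Nodes are residues with a hydrophobic side chain and relative SASA
    above ``rel_threshold``; edges join pseudo-CB pairs closer than
    ``contact_dist``; components whose summed exposed area reaches
    ``min_area`` are reported, largest first.
    """
    nodes = [i for i in range(len(model))
             if sequence[i] in HYDROPHOBIC_AA
             and sasa_profile.relative[i] > rel_threshold]
    if not nodes:
        return PatchReport(patches=[], total_area=0.0)
    cb = pseudo_cb_array(model)[nodes]
    d = np.linalg.norm(cb[:, None, :] - cb[None, :, :], axis=2)
    adj = (d < contact_dist) & ~np.eye(len(nodes), dtype=bool)
    n_comp, labels = connected_components(coo_matrix(adj), directed=False)
    patches = []
    for c in range(n_comp):
        members = [nodes[i] for i in range(len(nodes)) if labels[i] == c]
        area = float(sum(sasa_profile.absolute[m] for m in members))
        if area >= min_area:
            patches.append((sorted(members), area))
    patches.sort(key=lambda p: (-p[1], p[0]))
    return PatchReport(patches=patches,
                       total_area=float(sum(a for _, a in patches)))


# ---------------------------------------------------------------------------
# Ramachandran

@dataclass
class RamachandranReport:
    phi: np.ndarray
    psi: np.ndarray
    classes: list          # per scored residue: favored/allowed/outlier
    residue_indices: list  # 0-based indices of scored residues
    counts: dict
    percentages: dict
    note: str = ""


def _in_box(phi, psi, box, margin=0.0):
    _, p0, p1, q0, q1 = box
    return (p0 - margin <= phi <= p1 + margin) and (q0 - margin <= psi <= q1 + margin)


def _rama_class(phi: float, psi: float, is_gly: bool) -> str:
    boxes = list(RAMA_FAVORED)
    if is_gly:
        boxes += [(name + "_mirror", -p1, -p0, -q1, -q0)
                  for name, p0, p1, q0, q1 in RAMA_FAVORED]
    for box in boxes:
        if _in_box(phi, psi, box):
            return "favored"
    for box in boxes:
        if _in_box(phi, psi, box, RAMA_MARGIN):
            return "allowed"
    return "outlier"


def ramachandran(model: StructureModel) -> RamachandranReport:
    """phi/psi dihedrals and coarse-box classification; termini excluded,
    chain-break neighbours skipped."""
    n = len(model)
    empty = RamachandranReport(
        phi=np.zeros(0), psi=np.zeros(0), classes=[], residue_indices=[],
        counts={}, percentages={}, note="fewer than 3 residues; nothing to score",
    )
    if n < 3:
        return empty
    from .secstruct import chain_breaks

    breaks = chain_breaks(model)
    phis, psis, classes, indices = [], [], [], []
    skipped = 0
    for i in range(1, n - 1):
        if i in breaks or (i + 1) in breaks:
            skipped += 1
            continue
        phi = dihedral(model.coords[i - 1, 2], model.coords[i, 0],
                       model.coords[i, 1], model.coords[i, 2])
        psi = dihedral(model.coords[i, 0], model.coords[i, 1],
                       model.coords[i, 2], model.coords[i + 1, 0])
        phis.append(phi)
        psis.append(psi)
        classes.append(_rama_class(phi, psi, model.seq[i] == "G"))
        indices.append(i)
    if not classes:
        empty.note = "all residues adjacent to chain breaks"
        return empty
    counts = {c: classes.count(c) for c in ("favored", "allowed", "outlier")}
    total = len(classes)
    percentages = {c: round(100.0 * v / total, 1) for c, v in counts.items()}
    note = f"{skipped} residues skipped at chain breaks" if skipped else ""
    return RamachandranReport(
        phi=np.array(phis), psi=np.array(psis), classes=classes,
        residue_indices=indices, counts=counts, percentages=percentages,
        note=note,
    )


# ---------------------------------------------------------------------------
# misc published arithmetic

def helix_segment_count(density_per100: float, n_res: int) -> float:
    """Expected helix segments from a per-100-residue density estimate."""
    if density_per100 < 0 or n_res < 0:
        raise ValueError("inputs must be non-negative")
    return round(n_res * density_per100 / 100.0, 1)


# ---------------------------------------------------------------------------
# aggregate report

REPORT_SCHEMA_VERSION = 1
REPORT_SECTIONS = ("energy", "secondary_structure", "composition",
                   "control_comparison", "sasa", "patches", "ramachandran")


def evaluate_model(model: StructureModel, sequence: str | None = None,
                   prediction: SSPrediction | None = None,
                   probe: float = 1.4, points: int = 960) -> dict:
    """Full assessment report (JSON-serializable dict with all sections)."""
    from .design import DesignConfig, energy  # deferred: avoids import cycle

    sequence = sequence if sequence is not None else model.seq
    if len(sequence) != len(model):
        raise ValueError("sequence length does not match model")
    report = {"schema_version": REPORT_SCHEMA_VERSION, "n_res": len(model)}

    eb = energy(model, sequence, DesignConfig())
    report["energy"] = {
        "e_env": round(eb.e_env, 4), "e_pair": round(eb.e_pair, 4),
        "e_ss": round(eb.e_ss, 4), "e_hb": round(eb.e_hb, 4),
        "e_clash": round(eb.e_clash, 4), "total": round(eb.total, 4),
        "per_residue": round(eb.per_residue, 4),
    }

    assignment = assign_ss(model)
    builtin = prediction is None
    pred = predict_ss(sequence) if builtin else prediction
    agree = ss_score(pred, assignment)
    report["secondary_structure"] = {
        "assigned": assignment.states,
        "n_hbonds": len(assignment.hbonds),
        "ss_score": round(agree.score, 4),
        "p_ran": P_RAN,
        "builtin_predictor": builtin,
    }

    comp = composition(sequence)
    cats = category_profile(comp)
    report["composition"] = {
        "fractions": {a: round(v, 1) for a, v in comp.fractions.items()},
        "categories": cats.values,
        "n_res": comp.n_res,
    }
    report["control_comparison"] = {
        "composition": compare_to_control(comp),
        "categories": compare_to_control(cats),
    }

    prof = sasa(model, sequence, probe=probe, points=points)
    probs = sasa_probability(prof, sequence)
    report["sasa"] = {
        "mean_absolute": round(float(prof.absolute.mean()), 2),
        "mean_relative": round(float(prof.relative.mean()), 4),
        "mean_p_aa_given_bin": round(probs["mean_p_aa_given_bin"], 4),
        "mean_p_bin_given_aa": round(probs["mean_p_bin_given_aa"], 4),
        "probe": probe, "points": points,
    }

    patches = hydrophobic_patches(model, sequence, prof)
    report["patches"] = {
        "n_patches": len(patches.patches),
        "total_area": round(patches.total_area, 2),
        "patches": [{"residues": [m + 1 for m in members],
                     "area": round(area, 2)}
                    for members, area in patches.patches],
    }

    rama = ramachandran(model)
    report["ramachandran"] = {
        "counts": rama.counts,
        "percentages": rama.percentages,
        "note": rama.note,
    }
    return report


def report_to_json(report: dict) -> str:
    """Deterministic JSON encoding (sorted keys, fixed float handling)."""
    import json

    return json.dumps(report, sort_keys=True, indent=2)


def report_to_tsv(report: dict) -> str:
    """Flat key/value TSV rendering of the scalar report entries."""
    lines = ["key\tvalue"]

    def walk(prefix, obj):
        if isinstance(obj, dict):
            for k in sorted(obj):
                walk(f"{prefix}.{k}" if prefix else str(k), obj[k])
        elif isinstance(obj, (list, tuple)):
            lines.append(f"{prefix}\t{len(obj)} entries")
        else:
            lines.append(f"{prefix}\t{obj}")

    walk("", report)
    return "\n".join(lines) + "\n"
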