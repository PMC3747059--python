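"""Hierarchical region-restricted Monte-Carlo sequence design with a
surrogate knowledge-based energy, loop relaxation, filter cascade and the
iterative design campaign.

The energy is intentionally not an all-atom force field: side chains are a
single pseudo-CB sphere and the terms are a burial-hydropathy environment
term, a pairwise contact term from a packaged 20x20 table, a
secondary-structure propensity term, the Kabsch-Sander backbone
hydrogen-bond energy and a soft-sphere clash penalty.  Absolute values are
therefore in surrogate units; only comparisons between sequences and
conformations on the same scale are meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .barrel import (
    BarrelParams,
    CCD_MAX_SWEEPS,
    CCD_TOL,
    build_loops,
    build_scaffold,
    generate_ensemble,
)
from ._ccd import close_loop
from .evaluate import sasa
from .geometry import dihedral
from .regions import (
    PATCH_REDESIGN_ALPHABET,
    RegionAssignment,
    alphabet_for,
    classify_positions,
)
from .secstruct import backbone_hbonds
from .structmodel import StructureModel, pseudo_cb_array
from .tables import AA_INDEX, AA_ORDER, CONTACT_TABLE, HYDROPATHY, ss_propensity_matrix

NEIGHBOR_RADIUS = 10.0   # A, pseudo-CB burial sphere
NEIGHBOR_SATURATION = 20  # neighbor count treated as fully buried
CONTACT_RADIUS = 8.0      # A, pseudo-CB contact cutoff
CLASH_RADIUS = 3.0        # A, soft-sphere clash onset

_HYDRO = np.array([HYDROPATHY[a] for a in AA_ORDER])
_LOGP_SS = np.log(np.clip(ss_propensity_matrix(), 1e-9, None))  # (20, 3) H,E,L
_SS_IDX = {"H": 0, "E": 1, "L": 2}


@dataclass
class EnergyBreakdown:
    e_env: float
    e_pair: float
    e_ss: float
    e_hb: float
    e_clash: float
    total: float
    per_residue: float


@dataclass
class DesignConfig:
    """Knobs of the design loop; counts mirror the published campaign
    (hundred kept backbones, ten designs each, five cycles, six-thousand
    member loop ensemble)."""

    weights: dict = field(default_factory=lambda: {
        "env": 1.0, "pair": 1.0, "ss": 0.5, "hb": 1.0, "clash": 10.0,
    })
    mc_steps: int = 1200
    kt_start: float = 2.0
    kt_end: float = 0.3
    seed: int = 0
    n_backbones_kept: int = 100
    n_designs_per_backbone: int = 10
    n_cycles: int = 5
    ensemble_size: int = 6000
    relax_iters: int = 8
    sasa_points: int = 120  # reduced sampling for in-campaign filtering

    def __post_init__(self):
        for name in ("mc_steps", "relax_iters"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_backbones_kept", "n_designs_per_backbone",
                     "n_cycles", "ensemble_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.kt_start <= 0 or self.kt_end <= 0:
            raise ValueError("temperatures must be positive")


@dataclass
class FilterThresholds:
    """Filter cascade: (i) intact barrel hydrogen-bond network, (ii) solvent
    excluded from the core, (iii) lowest total surrogate energy."""

    hb_max: float = -40.0        # kcal/mol, summed Kabsch-Sander energy
    core_sasa_max: float = 0.35  # mean relative SASA over core positions
    selection: int = 100


@dataclass
class DesignRecord:
    record_id: int
    backbone_id: int
    cycle: int
    sequence: str
    energy: EnergyBreakdown
    core_rel_sasa: float
    flags: dict = field(default_factory=dict)
    model: StructureModel | None = None


# ---------------------------------------------------------------------------
# energy

class _Geometry:
    """Sequence-independent precomputation for one backbone."""

    def __init__(self, model: StructureModel):
        self.n = len(model)
        self.cb = pseudo_cb_array(model)
        d = np.linalg.norm(self.cb[:, None, :] - self.cb[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        counts = (d < NEIGHBOR_RADIUS).sum(axis=1)
        self.burial = np.minimum(1.0, counts / NEIGHBOR_SATURATION)
        iu, ju = np.triu_indices(self.n, k=1)
        contact = d[iu, ju] < CONTACT_RADIUS
        self.pairs_i = iu[contact]
        self.pairs_j = ju[contact]
        self.neighbors = [[] for _ in range(self.n)]
        for a, b in zip(self.pairs_i, self.pairs_j):
            self.neighbors[a].append(b)
            self.neighbors[b].append(a)
        nonadj = np.abs(iu - ju) >= 2
        overlap = np.maximum(0.0, CLASH_RADIUS - d[iu, ju])
        self.e_clash = float(np.sum((overlap[nonadj]) ** 2))
        self.e_hb = float(sum(e for _, _, e in backbone_hbonds(model)))
        self.ss_idx = np.array([_SS_IDX[s] for s in model.ss3]) if model.ss3 \
            else np.full(self.n, 2)


def _seq_terms(geom: _Geometry, seq_idx: np.ndarray) -> tuple[float, float, float]:
    h = _HYDRO[seq_idx]
    e_env = float(-np.sum(h * (2.0 * geom.burial - 1.0)))
    e_pair = float(np.sum(CONTACT_TABLE[seq_idx[geom.pairs_i],
                                        seq_idx[geom.pairs_j]]))
    e_ss = float(-np.sum(_LOGP_SS[seq_idx, geom.ss_idx]))
    return e_env, e_pair, e_ss


def energy(model: StructureModel, sequence: str, cfg: DesignConfig,
           geom: _Geometry | None = None) -> EnergyBreakdown:
    """Surrogate design energy of a sequence threaded on a backbone.

    Sign conventions: burial of hydrophobic residues lowers the environment
    term; favorable contacts are negative in the packaged table.  Every
    residue carries a virtual CB (glycine included) so the geometric terms
    depend only on the backbone.
    """
    if len(sequence) != len(model):
        raise ValueError("sequence length does not match model")
    bad = set(sequence) - set(AA_ORDER)
    if bad:
        raise ValueError(f"invalid letters: {sorted(bad)}")
    geom = geom or _Geometry(model)
    seq_idx = np.array([AA_INDEX[a] for a in sequence])
    e_env, e_pair, e_ss = _seq_terms(geom, seq_idx)
    w = cfg.weights
    total = (w["env"] * e_env + w["pair"] * e_pair + w["ss"] * e_ss
             + w["hb"] * geom.e_hb + w["clash"] * geom.e_clash)
    return EnergyBreakdown(
        e_env=e_env, e_pair=e_pair, e_ss=e_ss, e_hb=geom.e_hb,
        e_clash=geom.e_clash, total=total, per_residue=total / geom.n,
    )


def backbone_energy(model: StructureModel, cfg: DesignConfig) -> float:
    """Sequence-independent ranking energy (H-bond + clash terms)."""
    geom = _Geometry(model)
    w = cfg.weights
    return w["hb"] * geom.e_hb + w["clash"] * geom.e_clash


# ---------------------------------------------------------------------------
# Monte-Carlo design

def _mc_design(geom: _Geometry, seq_idx: np.ndarray, positions: list,
               allowed_idx: list, cfg: DesignConfig,
               rng: np.random.Generator, trace: list | None = None) -> np.ndarray:
    """Metropolis MC over single-position substitutions; returns the best
    sequence (by the sequence-dependent energy terms) encountered."""
    if cfg.mc_steps == 0 or not positions:
        return seq_idx
    w = cfg.weights
    e_env, e_pair, e_ss = _seq_terms(geom, seq_idx)
    current = w["env"] * e_env + w["pair"] * e_pair + w["ss"] * e_ss
    best = current
    best_seq = seq_idx.copy()
    if trace is not None:
        trace.append(best)
    kts = cfg.kt_start * (cfg.kt_end / cfg.kt_start) ** (
        np.arange(cfg.mc_steps) / max(cfg.mc_steps - 1, 1))
    pos_choice = rng.integers(0, len(positions), size=cfg.mc_steps)
    for step in range(cfg.mc_steps):
        p = positions[pos_choice[step]]
        old = seq_idx[p]
        cand = allowed_idx[pos_choice[step]]
        new = cand[rng.integers(0, len(cand))]
        if new == old:
            continue
        d_env = -w["env"] * (_HYDRO[new] - _HYDRO[old]) * (2.0 * geom.burial[p] - 1.0)
        d_ss = -w["ss"] * (_LOGP_SS[new, geom.ss_idx[p]]
                           - _LOGP_SS[old, geom.ss_idx[p]])
        d_pair = 0.0
        for q in geom.neighbors[p]:
            d_pair += CONTACT_TABLE[new, seq_idx[q]] - CONTACT_TABLE[old, seq_idx[q]]
        d_pair *= w["pair"]
        delta = d_env + d_ss + d_pair
        if delta <= 0 or rng.random() < np.exp(-delta / kts[step]):
            seq_idx[p] = new
            current += delta
            if current < best:
                best = current
                best_seq = seq_idx.copy()
        if trace is not None:
            trace.append(best)
    return best_seq


def design_region(model: StructureModel, regions: RegionAssignment,
                  region: str, sequence: str, cfg: DesignConfig,
                  rng: np.random.Generator | None = None,
                  geom: _Geometry | None = None,
                  trace: list | None = None) -> str:
    """Design one region, leaving every other position untouched."""
    positions = regions.positions(region)
    if not positions:
        warnings.warn(f"region {region!r} has no positions; sequence unchanged")
        return sequence
    geom = geom or _Geometry(model)
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    allowed = sorted(AA_INDEX[a] for a in alphabet_for(region).allowed)
    seq_idx = np.array([AA_INDEX[a] for a in sequence])
    out = _mc_design(geom, seq_idx.copy(), positions,
                     [np.array(allowed)] * len(positions), cfg, rng, trace)
    return "".join(AA_ORDER[i] for i in out)


def design_sequence(model: StructureModel, regions: RegionAssignment,
                    cfg: DesignConfig,
                    rng: np.random.Generator | None = None,
                    geom: _Geometry | None = None) -> DesignRecord:
    """Hierarchical design: core first, then pore, then surface.

    The working sequence starts as all-glycine (loops included); the final
    record carries the full energy breakdown.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    geom = geom or _Geometry(model)
    seq = "G" * len(model)
    for region in ("core", "pore", "surface"):
        if regions.positions(region):
            seq = design_region(model, regions, region, seq, cfg,
                                rng=rng, geom=geom)
    eb = energy(model, seq, cfg, geom=geom)
    return DesignRecord(
        record_id=0, backbone_id=int(model.meta.get("member", 0)), cycle=0,
        sequence=seq, energy=eb, core_rel_sasa=float("nan"), model=model,
    )


# ---------------------------------------------------------------------------
# relaxation

def _loop_torsions(model: StructureModel, start: int, end: int) -> tuple[np.ndarray, np.ndarray]:
    phis = np.empty(end - start)
    psis = np.empty(end - start)
    co = model.coords
    for k, i in enumerate(range(start, end)):
        phis[k] = dihedral(co[i - 1, 2], co[i, 0], co[i, 1], co[i, 2])
        if i + 1 < len(model):
            psis[k] = dihedral(co[i, 0], co[i, 1], co[i, 2], co[i + 1, 0])
        else:
            psis[k] = 130.0
    return phis, psis


def relax(model: StructureModel, sequence: str, cfg: DesignConfig,
          rng: np.random.Generator | None = None,
          max_move_deg: float = 5.0) -> StructureModel:
    """Greedy loop-only relaxation.

    Each iteration perturbs the torsions of one loop by at most
    ``max_move_deg`` per angle, re-closes it, and keeps the move only when
    the total energy decreases and the chain stays continuous.  Strand and
    helix atoms never move.
    """
    if cfg.relax_iters == 0:
        return model
    spans = model.meta.get("loop_spans")
    if not spans:
        return model
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    work = model.copy()
    accepted = False
    current = energy(work, sequence, cfg).total
    for _ in range(cfg.relax_iters):
        si = rng.integers(0, len(spans))
        start, end = spans[si]
        if start == 0 or end >= len(work):  # tail or leading loop: skip
            continue
        phis, psis = _loop_torsions(work, start, end)
        phis = np.deg2rad(phis + rng.uniform(-max_move_deg, max_move_deg, len(phis)))
        psis = np.deg2rad(psis + rng.uniform(-max_move_deg, max_move_deg, len(psis)))
        anchor = work.coords[start - 1]
        start_n = work.coords[start, 0]
        target = work.coords[end, :3]
        atoms, err, attempt = close_loop(anchor, start_n, phis[None, :],
                                         psis[None, :], target,
                                         tol=CCD_TOL, max_sweeps=CCD_MAX_SWEEPS)
        if attempt < 0:
            continue
        trial = work.copy()
        L = end - start
        for r in range(L):
            trial.coords[start + r, 0] = atoms[3 * r]
            trial.coords[start + r, 1] = atoms[3 * r + 1]
            trial.coords[start + r, 2] = atoms[3 * r + 2]
        if not trial.validate_chain():
            continue
        e_new = energy(trial, sequence, cfg).total
        if e_new < current:
            work = trial
            current = e_new
            accepted = True
    return work if accepted else model


# ---------------------------------------------------------------------------
# filtering and the campaign

def filter_models(records: list, thresholds: FilterThresholds) -> list:
    """Apply the three filter criteria and keep the ``selection`` lowest
    total energies (stable tie-break by record id).  Every record's flags
    are annotated with the criterion it failed, if any."""
    survivors = []
    for rec in records:
        rec.flags.pop("hb", None)
        rec.flags.pop("core_sasa", None)
        ok = True
        if rec.energy.e_hb > thresholds.hb_max:
            rec.flags["hb"] = "hydrogen-bond network too weak"
            ok = False
        if np.isfinite(rec.core_rel_sasa) and \
                rec.core_rel_sasa > thresholds.core_sasa_max:
            rec.flags["core_sasa"] = "core not solvent-excluded"
            ok = False
        if ok:
            survivors.append(rec)
    survivors.sort(key=lambda r: (r.energy.total, r.record_id))
    return survivors[:thresholds.selection]


def _core_rel_sasa(model: StructureModel, sequence: str,
                   regions: RegionAssignment, points: int) -> float:
    core = regions.positions("core")
    if not core:
        return float("nan")
    prof = sasa(model, sequence, points=points)
    return float(prof.relative[core].mean())


def run_campaign(cfg: DesignConfig, params: BarrelParams | None = None,
                 thresholds: FilterThresholds | None = None,
                 fragment_library=None) -> tuple[list, dict]:
    """Full iterative design campaign.

    Per cycle: rank backbones by backbone-only energy and keep the best,
    run independent seeded designs on each, relax, filter, and re-seed the
    loop conformations of the survivors for the next cycle.  Returns the
    final records and a manifest with the stage counts of every cycle.
    """
    params = params or BarrelParams()
    thresholds = thresholds or FilterThresholds(selection=cfg.n_backbones_kept)
    scaffold = build_scaffold(params)
    ensemble = generate_ensemble(params, cfg.ensemble_size, cfg.seed,
                                 fragment_library=fragment_library)
    backbones = ensemble.members
    manifest = {
        "config": {
            "ensemble_size": cfg.ensemble_size,
            "n_backbones_kept": cfg.n_backbones_kept,
            "n_designs_per_backbone": cfg.n_designs_per_backbone,
            "n_cycles": cfg.n_cycles,
            "mc_steps": cfg.mc_steps,
            "seed": cfg.seed,
        },
        "cycles": [],
    }
    sequences_seen = set()
    records: list = []
    rid = 0
    for cycle in range(1, cfg.n_cycles + 1):
        ranked = sorted(backbones,
                        key=lambda m: (backbone_energy(m, cfg),
                                       m.meta.get("member", 0)))
        kept = ranked[:cfg.n_backbones_kept]
        candidates = []
        for b in kept:
            regions = classify_positions(b)
            geom_b = _Geometry(b)
            for d in range(cfg.n_designs_per_backbone):
                rng = np.random.default_rng(
                    [cfg.seed, cycle, int(b.meta.get("member", 0)), d])
                rec = design_sequence(b, regions, cfg, rng=rng, geom=geom_b)
                relaxed = relax(rec.model, rec.sequence, cfg, rng=rng)
                eb = energy(relaxed, rec.sequence, cfg,
                            geom=geom_b if relaxed is b else None)
                rec = replace(rec, record_id=rid, cycle=cycle, energy=eb,
                              model=relaxed,
                              core_rel_sasa=_core_rel_sasa(
                                  relaxed, rec.sequence, regions,
                                  cfg.sasa_points))
                rid += 1
                candidates.append(rec)
                sequences_seen.add(rec.sequence)
        passed = filter_models(candidates, thresholds)
        manifest["cycles"].append({
            "cycle": cycle,
            "backbones_ranked": len(backbones),
            "kept": len(kept),
            "candidates": len(candidates),
            "passed_filter": len(passed),
        })
        records = passed
        if cycle < cfg.n_cycles:
            # re-seed the loop conformations of the surviving backbones
            backbones = []
            for i, rec in enumerate(passed):
                reseed = build_loops(scaffold,
                                     rng_seed=(cfg.seed + 100000 * cycle + i),
                                     fragment_library=fragment_library)
                reseed.meta["member"] = rec.backbone_id
                backbones.append(reseed)
            if not backbones:
                break
    manifest["distinct_sequences"] = len(sequences_seen)
    manifest["total_candidates"] = rid
    return records, manifest


def rank_models(records: list, regions_by_backbone: dict | None = None,
                require_aromatic_core: bool = False,
                aromatic_bonus: float = 5.0) -> list:
    """Post-campaign ranking: lowest energy first, with a bonus for models
    carrying at least one aromatic residue in the core (or a hard
    requirement when ``require_aromatic_core`` is set)."""
    def has_aromatic_core(rec: DesignRecord) -> bool:
        if rec.model is None:
            return False
        regions = (regions_by_backbone or {}).get(rec.backbone_id)
        if regions is None:
            regions = classify_positions(rec.model)
        return any(rec.sequence[i] in "FWYH" for i in regions.positions("core"))

    scored = []
    for rec in records:
        arom = has_aromatic_core(rec)
        if require_aromatic_core and not arom:
            continue
        scored.append((rec.energy.total - (aromatic_bonus if arom else 0.0),
                       rec.record_id, rec))
    scored.sort(key=lambda t: (t[0], t[1]))
    return [rec for _, _, rec in scored]


def redesign_patches(model: StructureModel, sequence: str, patches,
                     cfg: DesignConfig,
                     rng: np.random.Generator | None = None) -> str:
    """Redesign the residues inside reported hydrophobic patches with the
    small-hydrophilic alphabet {S, T, N, D, G}; everything else is fixed."""
    if not patches.patches:
        return sequence
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    positions = sorted({i for members, _ in patches.patches for i in members})
    geom = _Geometry(model)
    allowed = np.array(sorted(AA_INDEX[a] for a in PATCH_REDESIGN_ALPHABET))
    seq_idx = np.array([AA_INDEX[a] for a in sequence])
    # start patch positions from a neutral small-polar residue
    for p in positions:
        seq_idx[p] = AA_INDEX["S"]
    out = _mc_design(geom, seq_idx, positions, [allowed] * len(positions),
                     cfg, rng)
    return "".join(AA_ORDER[i] for i in out)
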