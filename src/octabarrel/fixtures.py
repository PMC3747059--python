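"""Deterministic fixture generation: every structure and data file the test
suite or an offline user needs, regenerable bit-identically from a seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import reference as ref
from .barrel import BarrelParams, build_loops, build_scaffold
from .design import DesignConfig, design_sequence
from .geometry import build_backbone
from .regions import classify_positions
from .secstruct import predict_ss, write_prediction
from .structmodel import StructureModel, write_fasta, write_pdb


@dataclass
class FixtureSet:
    paths: dict       # name -> Path
    checksums: dict   # name -> sha256 hex digest


def ideal_helix_model(n_res: int = 20) -> StructureModel:
    coords = build_backbone(np.full(n_res, -57.0), np.full(n_res, -47.0))
    return StructureModel(coords=coords, seq="A" * n_res, ss3="H" * n_res)


def strand_pair_model() -> StructureModel:
    """Two adjacent parallel strands cut from the default barrel scaffold
    (single chain with a break between the strands)."""
    scaffold = build_scaffold(BarrelParams())
    segs = [(s, e) for kind, s, e in scaffold.meta["segments"] if kind == "E"]
    (s0, e0), (s1, e1) = segs[0], segs[1]
    coords = np.concatenate([scaffold.coords[s0:e0], scaffold.coords[s1:e1]])
    n = coords.shape[0]
    return StructureModel(coords=coords, seq="G" * n, ss3="E" * n)


def mini_barrel_model(seed: int = 0) -> StructureModel:
    """Full 216-residue barrel with a quickly designed sequence."""
    model = build_loops(build_scaffold(BarrelParams()), rng_seed=seed)
    regions = classify_positions(model)
    cfg = DesignConfig(mc_steps=200, seed=seed)
    rec = design_sequence(model, regions, cfg,
                          rng=np.random.default_rng([seed, 77]))
    model.seq = rec.sequence
    return model


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixtures(out_dir, seed: int = 0) -> FixtureSet:
    """Write the full fixture set and a checksum manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    helix = ideal_helix_model()
    paths["ideal_helix.pdb"] = out / "ideal_helix.pdb"
    write_pdb(helix, paths["ideal_helix.pdb"])

    pair = strand_pair_model()
    paths["strand_pair.pdb"] = out / "strand_pair.pdb"
    write_pdb(pair, paths["strand_pair.pdb"])

    barrel = mini_barrel_model(seed)
    paths["mini_barrel.pdb"] = out / "mini_barrel.pdb"
    write_pdb(barrel, paths["mini_barrel.pdb"])
    paths["mini_barrel.fasta"] = out / "mini_barrel.fasta"
    write_fasta(barrel.seq, paths["mini_barrel.fasta"], header="mini_barrel")

    paths["composition.tsv"] = out / "composition.tsv"
    with open(paths["composition.tsv"], "w") as fh:
        fh.write("aa\tpercent\n")
        for aa, pct in sorted(ref.OCTARELLIN_VI_COMPOSITION.items()):
            fh.write(f"{aa}\t{pct}\n")

    paths["control_reference.json"] = out / "control_reference.json"
    with open(paths["control_reference.json"], "w") as fh:
        json.dump({
            "pdb_codes": list(ref.CONTROL_PDB_CODES),
            "composition": {a: list(v) for a, v in ref.CONTROL_COMPOSITION.items()},
            "categories": {c: list(v) for c, v in ref.CONTROL_CATEGORIES.items()},
            "scores": {k: list(v) for k, v in ref.CONTROL_SCORES.items()},
        }, fh, indent=2, sort_keys=True)
        fh.write("\n")

    pred = predict_ss(barrel.seq)
    paths["sample.ss2"] = out / "sample.ss2"
    write_prediction(pred, barrel.seq, paths["sample.ss2"])

    checksums = {name: _sha256(p) for name, p in sorted(paths.items())}
    with open(out / "checksums.txt", "w") as fh:
        for name, digest in checksums.items():
            fh.write(f"{digest}  {name}\n")
    paths["checksums.txt"] = out / "checksums.txt"
    return FixtureSet(paths=paths, checksums=checksums)
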