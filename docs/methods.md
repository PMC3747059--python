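# Methods

## Scope and representation

octabarrel re-creates, at desk scale, a de novo (β/α)₈ design workflow:
parametric backbone generation, region-restricted hierarchical sequence
design with an iterative relax/filter loop, and a statistical assessment
battery against natural TIM-barrel controls.  Proteins are represented by
their backbone (N, CA, C, O per residue) plus an idealized pseudo-CB; there
are no rotamers, no hydrogens in files (the amide H is rebuilt
geometrically where hydrogen bonds are evaluated), and no all-atom force
field.  Energies are surrogate units: only differences between sequences
or conformations on the same backbone scale are meaningful, and the
package never claims to reproduce any published absolute energy.

## Barrel geometry

The sheet is a closed barrel of `n_strands` (N) parallel strands with
shear number `shear` (S).  Unrolling the barrel surface, one residue step
advances a = `rise_per_res_strand` along the strand and one strand step
advances b = `interstrand_dist` perpendicular to it; closing the surface
after N strands with a register offset of S residues fixes

    tilt      α = atan(S·a / (N·b))
    circumference C = √((S·a)² + (N·b)²)

`barrel_radius` reports the standard chord-polygon radius
R = C / (2·N·sin(π/N)) (7.19 Å at defaults); the generator itself wraps
the lattice onto the smooth cylinder of radius C/2π (7.00 Å), the only
choice that closes the seam arc-length exactly.  Both values agree with a
brute-force cylinder fit of the generated CAs to well under 0.5 Å.

The CA zigzag (amplitude √(d² − a²)/2 ≈ 0.94 Å, d the ideal CA–CA
distance) is placed **radially** — i.e. the pleat is perpendicular to the
sheet surface.  This is load-bearing: it keeps the carbonyls in the sheet
surface pointing at the neighbouring strands, and during development the
in-surface alternative was measured to destroy the interstrand
hydrogen-bond network (3 marginal Kabsch–Sander bonds versus 36 with the
radial pleat; zero roll of the stamped strand about its own axis is within
a few percent of the energetic optimum, so no roll parameter is exposed).
Register offset between adjacent strands is exactly S/N residues, which
makes the per-pair axial shift vanish and lets the 8→1 seam close with the
same bonding pattern as every other pair.

Strand backbones are "stamped": a reference strand is built from uniform
torsions (φ = −120°, ψ solved by root finding so the axial rise equals a),
the offsets of C, O and N within each local CA-triple frame are measured
once, and applied to the curved barrel lattice.  Helices (φ = −57°,
ψ = −47°) are placed rigidly on a concentric cylinder `helix_offset`
(default 10 Å) outside the sheet, antiparallel to their flanking strands.
Ideal bond lengths and angles follow standard Engh/Huber-style values
collected in one table (`geometry.IDEAL_GEOMETRY`).

Default segmentation: 6-residue strands, 9-residue helices, 6-residue
loops — 8 × (6 + 9 + 12) = 216 residues.  The helix length sits at the
short end of natural TIM helices; it is the unique choice that reaches a
216-residue chain with six-residue loops, and both lengths are plain
config fields.

## Loops

Loops follow the [E,E/L,L,L,L,L,L/H,H] (βα) and [H,H/L,L,L,L,L,L/E,E]
(αβ) patterns; the working sequence sets loop residues to glycine.  Each
loop is sampled from an internal coil (φ,ψ) library (β, polyproline-II,
α_R, α_L and bridge bins with Gaussian jitter; an external TSV of
φ ψ weight sd rows can replace it) and closed by cyclic coordinate descent
on the 13 loop torsions to an RMS anchor error ≤ 0.3 Å, with batch
resampling on failure (up to 4 × 30 attempts; in practice the first batch
closes > 99% of gaps).  The αβ loop after the last helix has no landing
strand and is left as an open, sampled C-terminal tail.  The closure
kernel is numba-compiled with a pure-NumPy fallback and is verified
sweep-for-sweep against an independent pure-Python CCD implementation.

Ensembles share one scaffold: members differ only in loop atoms, member i
uses seed `master + i`, and identical seeds reproduce ensembles
bit-identically.

## Region classification and alphabets

The barrel axis is the normalized mean of per-strand principal directions
(the tangential tilt components cancel around the ring).  A pooled
principal axis of all strand CAs is *not* used: for a squat barrel the
ring variance exceeds the axial variance and the first principal component
lies in the ring plane.  Each position is then classified by a
parameter-free hemisphere rule on the cosine between CA→CB and the inward
radial direction: strand positions pointing inward are **pore**, outward
**core**; helix positions pointing toward the sheet are **core**, the rest
and all loops are **surface**.  The cosine is stored per residue as the
classification rationale.  ("Pore" is retained as the historical name for
inward strand positions; the cavity is not a channel.)

Alphabets: core `MAFLIVWYGH`; pore and surface all amino acids except
cysteine.  No designed sequence can ever contain cysteine.

Glycine carries a *virtual* CB in all internal geometry (burial, contacts,
clash, classification) so these depend only on the backbone; the public
`idealized_cb` returns `None` for glycine.  CB placement uses the
L-chirality improper (C–N–CA–CB = −122.6°, angle N–CA–CB = 110.5°,
1.53 Å); note that any fixed-chirality construction is equivariant under
rotations and translations but necessarily not under mirror reflection.

## Surrogate energy

    E = w_env·E_env + w_pair·E_pair + w_ss·E_ss + w_hb·E_hb + w_clash·E_clash
    weights: w_env = 1, w_pair = 1, w_ss = 0.5, w_hb = 1, w_clash = 10

* `E_env = −Σ h(aaᵢ)·(2·burialᵢ − 1)`, h the Kyte–Doolittle hydropathy
  scaled to [−1, 1] with glycine pinned at 0, burial = min(1, n₁₀Å/20)
  from pseudo-CB neighbour counts.  The sign makes buried hydrophobics
  favorable and exposed hydrophobics unfavorable.
* `E_pair`: Σ over CB–CB pairs < 8 Å of the packaged 20×20 table
  e(a,b) = −h(a)h(b) + 0.5·q(a)q(b) (hydrophobic–hydrophobic favorable,
  like charges unfavorable).  A constructed smooth surrogate, not a PDB
  statistic.
* `E_ss = −Σ log P(ss3ᵢ | aaᵢ)` from renormalized Chou–Fasman propensities.
* `E_hb`: summed Kabsch–Sander energies of all backbone hydrogen bonds,
  E = 27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bond declared
  below −0.5 kcal/mol, |i − j| ≥ 2, H rebuilt 1 Å from N anti to the
  preceding C=O.
* `E_clash = Σ max(0, 3.0 − d_CB)²` over non-adjacent pairs.

Known behaviour: with the default weights the pair term dominates at high
contact density and designed chains are hydrophobic-rich overall, surface
included — mirroring the known tendency of aggressive hydrophobic-packing
objectives.  The workflow's answer is the same as the published one: the
patch-detection + redesign stage.  The robust, tested property is
*relative*: cores always come out more hydrophobic than surfaces.

## Design, relaxation, filters, campaign

Design is sequential per region (core → pore → surface) from an
all-glycine start, Metropolis single-position substitutions with a
geometric kT anneal (2.0 → 0.3 over `mc_steps` per region, default 1200),
best-so-far sequence returned, incremental energy updates over the
precomputed contact graph.

Relaxation is deliberately minimal: loop-torsion perturbations ≤ 5° per
angle followed by re-closure, accepted only if the total energy decreases
and the chain stays continuous; strand/helix atoms are frozen to machine
precision.  Bounded by `relax_iters` (default 8).

Filters mirror the three published criteria: (i) summed barrel backbone
hydrogen-bond energy ≤ `hb_max` (default −40 kcal/mol; generated barrels
score around −300, so this rejects only genuinely broken networks),
(ii) mean relative SASA over core positions ≤ `core_sasa_max` (default
0.35; generated designs measure ≈ 0.2), (iii) rank by total energy and
keep `selection` (default 100), ties broken stably by record id.

The campaign: generate `ensemble_size` (default 6000) loop variants; per
cycle rank backbones by the sequence-independent terms (E_hb + w·E_clash),
keep `n_backbones_kept` (100), run `n_designs_per_backbone` (10)
independently seeded designs each — 1000 candidates per cycle — relax,
filter, and re-seed the survivors' loop conformations for the next cycle;
`n_cycles` = 5 by default, so a full campaign evaluates ≥ 5000 distinct
sequences.  One master seed and per-task derived RNG streams make the
whole campaign manifest bit-reproducible.  A post-campaign ranking adds a
bonus (or hard requirement, by flag) for designs with at least one
aromatic residue in the core; patch redesign restricts reported patch
positions to `STNDG`.

## Assessment battery

* **Secondary structure**: Kabsch–Sander hydrogen bonds; n→n+4 turn
  ladders → helix, bridge ladders → strand, reduced to three states with
  minimum runs 4 (H) and 2 (E).  Two documented smoothing rules handle
  ideal-geometry edges: single-residue bulge closure inside ladders, and
  extension of a strand run onto a flanking residue that itself makes a
  long-range backbone hydrogen bond.  On generated scaffolds label
  recovery is ≈ 97% (criterion ≥ 90%).
* **SS_score** = −mean[(P − 0.33)/(1 − 0.33)], isolated in one function;
  bounds [−1, 0.33/0.67].  The built-in predictor is a propensity
  sliding-window stand-in (window 7); real predictions are supplied as
  ss2 files.
* **Composition/categories**: exact percentage arithmetic; the ten
  overlapping side-chain-nature categories use the memberships
  aliphatic AGILMPV, aromatic FWYH, small AGS, long-flexible RKEQM,
  β-branched ITV, negative DE, positive RK, charged DERK, polar NQSTH,
  polar-charged = polar ∪ charged.  Control means ± SD for 18 natural
  TIM barrels are packaged verbatim; z-scores beyond ±2 are flagged.
* **SASA**: Shrake–Rupley on backbone spheres plus one per-residue
  side-chain sphere at the pseudo-CB (radius from mean residue volumes),
  probe 1.4 Å, deterministic golden-spiral sampling (default 960 points;
  campaigns use reduced counts).  Relative SASA normalizes by the
  isolated-residue value in the same representation; the implementation
  was cross-checked against an independent library SASA (r > 0.999).
  Exposure probabilities use a packaged 20×5 joint table built from a
  Boltzmann hydropathy model (documented surrogate, not PDB-mined).
* **Patches**: exposed (relative SASA > 0.25) hydrophobic (AVLIMFWY)
  residues, pseudo-CB edges < 8 Å, connected components with summed area
  ≥ 50 Å² reported largest-first.
* **Ramachandran**: φ/ψ classes from documented coarse boxes (β with its
  wrap, α_R, α_L) with a 20° "allowed" margin; glycine adds the mirrored
  boxes; termini and chain-break neighbours are excluded.

## Numerical and reproducibility choices

Tolerances: loop closure RMS ≤ 0.3 Å (fallback acceptance ≤ 0.5 Å plus a
junction CA–CA continuity check 2.8–4.2 Å); PDB round-trips preserve
coordinates to the 10⁻³ Å format precision; report JSON uses sorted keys
and rounded floats so re-runs are byte-identical.  All RNGs are
numpy Generators seeded from explicit integer lists; no global state.
Problem sizes used by the test suite and acceptance script — a
6000-member ensemble, a 1-cycle campaign of 100 × 10 candidates at
`mc_steps` = 30, and 20 seeded designs at `mc_steps` = 150 — were chosen
as the smallest sizes at which the counted quantities are exact and the
statistical properties are far from their thresholds.

## What the generator does and does not emulate

Generated barrels have ideal, uniform geometry: perfectly parallel
strands, identical helices, glycine loops, no β-bulges, no bent helices,
no side-chain packing detail.  Passing tests therefore demonstrate the
correctness of the geometry, bookkeeping, and statistical machinery on
idealized inputs — not that the surrogate energy would rank real
structures the way an all-atom potential does, nor that designed
sequences would fold.  Published wet-lab observables (CD spectra, melting,
light scattering) and external analyses (fold-recognition servers,
molecular dynamics, Anolea/ProsaII profiles) are explicitly out of scope.

## Known limitations

* The surrogate energy has no explicit solvation; surface polarity relies
  on the patch-redesign stage rather than emerging from the optimizer.
* The built-in secondary-structure predictor is propensity-based; its
  SS_score values are not comparable to those from neural-network
  predictors and the published score magnitudes are not reproduction
  targets.
* Loop conformations sample a coil library rather than real PDB
  fragments; the external fragment-file hook exists for higher fidelity.
* Backbone ranking before any sequence exists uses the only
  sequence-independent terms available (hydrogen bonds + clashes); the
  original workflow's criterion at this stage is underspecified.
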