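"""Packaged reference statistics for natural TIM-barrel proteins.

The control set is a published collection of eighteen natural (beta/alpha)8
proteins (resolution better than 2.2 A, monomeric, under 500 residues, under
70% mutual sequence identity).  The per-amino-acid and per-category
composition means +/- SD and the score statistics are packaged verbatim so
that designed models can be compared offline; recomputing them from the PDB
entries would require network access and is deliberately not done here.

``OCTARELLIN_VI_COMPOSITION`` is the published per-amino-acid composition of
the 216-residue design this package's workflow emulates; it is used as a
worked input for the category arithmetic and control comparison.
"""

from __future__ import annotations

CONTROL_PDB_CODES = (
    "1A53", "1AJ2", "1B54", "1BQC", "1CNV", "1EDG", "1EOK", "1G0C", "1I1W",
    "1J6O", "1NQ6", "1O1Z", "1PYF", "1UJP", "1VFL", "1WDP", "2CYG", "7A3H",
)

#: per-amino-acid composition of the reference design (percent of chain)
OCTARELLIN_VI_COMPOSITION = {
    "A": 8.8, "R": 5.1, "N": 7.9, "D": 1.9, "C": 0.0, "Q": 7.4, "E": 6.0,
    "G": 18.1, "H": 5.1, "I": 3.2, "L": 8.3, "K": 3.7, "M": 0.5, "F": 6.0,
    "P": 0.9, "S": 4.2, "T": 1.9, "W": 5.6, "Y": 3.7, "V": 1.9,
}
OCTARELLIN_VI_N_RES = 216

#: control-set composition, percent: amino acid -> (mean, sd)
CONTROL_COMPOSITION = {
    "A": (8.0, 2.4), "R": (4.2, 1.5), "N": (6.1, 2.0), "D": (6.1, 1.4),
    "C": (1.0, 1.0), "Q": (3.4, 1.4), "E": (7.0, 3.2), "G": (7.4, 1.7),
    "H": (2.2, 1.3), "I": (6.3, 2.1), "L": (8.4, 2.5), "K": (5.6, 2.6),
    "M": (1.8, 1.1), "F": (3.9, 1.0), "P": (4.3, 1.5), "S": (6.6, 1.5),
    "T": (4.6, 1.4), "W": (1.7, 1.1), "Y": (3.9, 1.5), "V": (7.1, 1.8),
}

#: side-chain-nature categories, percent: category -> (mean, sd)
CONTROL_CATEGORIES = {
    "aliphatic": (43.5, 3.7),
    "aromatic": (11.8, 2.4),
    "small": (21.9, 4.6),
    "long_flexible": (22.0, 4.4),
    "beta_branched": (20.3, 3.3),
    "charged": (22.8, 6.2),
    "negative": (13.0, 3.6),
    "positive": (9.8, 3.4),
    "polar": (23.9, 3.8),
    "polar_charged": (46.7, 3.3),
}

#: published category values for the reference design (percent)
OCTARELLIN_VI_CATEGORIES = {
    "aliphatic": 41.7,
    "aromatic": 20.4,
    "small": 31.0,
    "long_flexible": 22.7,
    "beta_branched": 12.0,
    "charged": 16.7,
    "negative": 7.9,
    "positive": 8.8,
    "polar": 26.4,
    "polar_charged": 43.1,
}

#: score statistics: name -> (design value, control mean, control sd)
CONTROL_SCORES = {
    "energy_per_residue": (-2.43, -2.29, 0.18),
    "normalized_sasa": (3.80, 1.49, 1.09),
    "sasa_probability": (0.34, 0.46, 0.05),
    "ss_propensity_energy": (-0.62, -0.55, 0.10),
}

#: category memberships used by the category arithmetic; categories overlap
CATEGORY_MEMBERS = {
    "aliphatic": set("AGILMPV"),
    "aromatic": set("FWYH"),
    "small": set("AGS"),
    "long_flexible": set("RKEQM"),
    "beta_branched": set("ITV"),
    "negative": set("DE"),
    "positive": set("RK"),
    "charged": set("DERK"),
    "polar": set("NQSTH"),
    "polar_charged": set("NQSTHDERK"),
}
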