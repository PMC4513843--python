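"""Published benchmark activities for selected variants of the shipped designs.

These are the reported sequencing-assay activity values for selected variants
of the twister library (Lib-Tw, fraction cleaved in a single condition) and
the guanine-aptazyme library Lib-J1/2 (fraction cleaved without / with 500 uM
guanine), from the original experimental characterization of these library
designs.  They serve as fixed inputs for ranking, pattern, gating and
correlation analyses — nothing in the package fits to them.
"""

from __future__ import annotations

#: Lib-Tw: variant (5 randomized bases, RNA sense) -> fraction cleaved.
#: GUUAC is the wild-type twister sequence.
TWISTER_BENCHMARK: dict[str, float] = {
    "GUUAC": 0.92,
    "GUUGC": 0.86,
    "GUUUC": 0.85,
    "GUUCC": 0.80,
    "GUCAC": 0.79,
    "UUUAC": 0.60,
    "GCUAC": 0.59,
    "AUUAC": 0.57,
    "GUUAU": 0.53,
    "GUAAC": 0.28,
    "GAUAC": 0.12,
    "ACUAC": 0.07,
    "AUCUA": 0.0013,
}

#: Lib-J1/2: variant (4 randomized connector bases) ->
#: (fraction cleaved -guanine, fraction cleaved +guanine).
APTAZYME_J12_BENCHMARK: dict[str, tuple[float, float]] = {
    "AAGU": (0.13, 0.80),
    "GAGU": (0.12, 0.76),
    "UAGU": (0.13, 0.74),
    "CAGU": (0.13, 0.70),
    "UGGU": (0.10, 0.61),
    "GGGU": (0.09, 0.53),
    "UUGU": (0.11, 0.51),
}

#: Lib-P4:AUAC — the one constitutively active Lib-P4 variant
#: (f without guanine, f with guanine).
P4_CONSTITUTIVE: dict[str, tuple[float, float]] = {"AUAC": (0.71, 0.92)}

WILD_TYPE_TWISTER = "GUUAC"
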