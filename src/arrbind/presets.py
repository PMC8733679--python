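"""Default analysis presets for deposited receptor/arrestin structures.

These presets name, for each supported PDB entry, the receptor and arrestin
chains, the Calpha pair of the ionic lock (the generic 3.50/6.30 positions
of the receptor in that entry's own numbering), the transmembrane helix
ranges used for the bundle selection, the four membrane-proximal N-lobe
beta-strands of the arrestin, and the ICL2 segment.

They are starting points, not ground truth: residue ranges for TM helices
and N-lobe strands follow the common annotations for each receptor family
and arrestin isoform and are deliberately config-overridable -- the
structure-metrics pipeline accepts per-entry overrides, and insertion-depth
results should always be read together with their sensitivity to the strand
selection.
"""

from __future__ import annotations

__all__ = ["DEPOSITED_PRESETS", "tm_selection", "strand_selection",
           "structure_entry"]


DEPOSITED_PRESETS: dict[str, dict] = {
    # beta2AR / Gs complex (receptor chain R)
    "3SN6": {
        "receptor_chain": "R",
        "lock": (131, 268),
        "tm_ranges": [(29, 60), (67, 96), (103, 136), (147, 171),
                      (197, 229), (267, 298), (305, 328)],
        "icl2": (137, 146),
    },
    # rhodopsin / visual arrestin-1 fusion
    "5DGY": {
        "receptor_chain": "A",
        "arrestin_chain": "B",
        "lock": (135, 247),
        "tm_ranges": [(34, 64), (71, 100), (106, 139), (150, 173),
                      (200, 225), (244, 277), (285, 309)],
        "nlobe_strands": [(9, 16), (21, 28), (33, 40), (45, 52)],
        "clobe": (230, 310),
        "icl2": (140, 152),
    },
    # M2 muscarinic receptor core (V2R C-terminus) / beta-arrestin1
    "6U1N": {
        "receptor_chain": "R",
        "arrestin_chain": "A",
        "lock": (121, 386),
        "tm_ranges": [(20, 50), (57, 85), (92, 125), (136, 160),
                      (185, 216), (383, 412), (419, 443)],
        "nlobe_strands": [(6, 13), (17, 24), (29, 36), (41, 48)],
        "clobe": (225, 305),
        "icl2": (126, 136),
    },
    # beta1AR core (V2R C-terminus) / beta-arrestin1
    "6TKO": {
        "receptor_chain": "A",
        "arrestin_chain": "B",
        "lock": (139, 285),
        "tm_ranges": [(40, 71), (78, 107), (114, 147), (158, 182),
                      (211, 243), (284, 315), (322, 345)],
        "nlobe_strands": [(6, 13), (17, 24), (29, 36), (41, 48)],
        "clobe": (225, 305),
        "icl2": (148, 158),
    },
}


def tm_selection(accession: str) -> str:
    p = DEPOSITED_PRESETS[accession]
    ranges = " ".join(f"{a}:{b}" for a, b in p["tm_ranges"])
    return f"chain {p['receptor_chain']} and name CA and resid {ranges}"


def strand_selection(accession: str, shift: int = 0) -> str:
    """N-lobe strand selection; ``shift`` moves every range for sensitivity
    checks."""
    p = DEPOSITED_PRESETS[accession]
    ranges = " ".join(f"{a + shift}:{b + shift}"
                      for a, b in p["nlobe_strands"])
    return f"chain {p['arrestin_chain']} and name CA and resid {ranges}"


def structure_entry(accession: str, path) -> dict:
    """Entry for the structure-metrics pipeline with this preset applied."""
    p = DEPOSITED_PRESETS[accession]
    entry = {
        "path": str(path),
        "receptor_chain": p["receptor_chain"],
        "lock_res_a": p["lock"][0],
        "lock_res_b": p["lock"][1],
        "tm_bundle": tm_selection(accession),
        "icl2_resids": list(p["icl2"]),
        "icl2_chain": p["receptor_chain"],
    }
    if "nlobe_strands" in p:
        entry["nlobe"] = strand_selection(accession)
    return entry
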