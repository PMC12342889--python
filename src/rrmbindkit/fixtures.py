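"""Packaged fixture propensity model and MSI-1-like profiles (synthetic).

The trained preference matrices behind the published Musashi-1 analysis are
not redistributable, so this module ships a *synthetic* propensity model,
hand-calibrated only to reproduce the qualitative design outcomes of the
study on MSI-1-like profiles:

* both domains' top unconstrained 3-mer is UAG;
* the top N-UAG-N 5-mers are CUAGU (RRM1-like) and CUAGG (RRM2-like);
* the RNA specificity switch (drop RRM1, keep RRM2) selects the CAG core,
  with CCAGG and GCAGG as the two best 5-mers;
* the protein specificity switch at the two pyrimidine-contact positions of
  RRM2 (author numbering 180 and 182) selects N and M — the E180N / K182M
  pair — with A and S as runners-up.

Absolute score values from this model are NOT comparable to any published
score; only the rankings above are meaningful.  The profile sequences are
likewise synthetic scaffolds (not the human MSI-1 sequence) carrying the
correct residues at the mapped author positions.

Master-position layout (six positions contacting a 5-nt window)::

    master position   10   11   12   13   14   15
    window slot        0    1    1    2    3    4

Positions 11 and 12 both contact slot 1 — the first pyrimidine of the
UAG/CAG core — mirroring how two residues of an RRM read one base.
"""

from __future__ import annotations

from .scoring import AMINO_ACIDS, PropensityModel, RRMProfile, build_profile

__all__ = [
    "SLOT_MAP_5",
    "SLOT_MAP_3",
    "fixture_model",
    "rrm1_profile",
    "rrm2_profile",
    "E180_MASTER_POSITION",
    "K182_MASTER_POSITION",
]

#: master position -> window slot, 5-nt window (flank, core, core, core, flank)
SLOT_MAP_5: dict[int, int] = {10: 0, 11: 1, 12: 1, 13: 2, 14: 3, 15: 4}
#: core-only map for 3-nt windows (UAG/CAG class)
SLOT_MAP_3: dict[int, int] = {11: 0, 12: 0, 13: 1, 14: 2}

E180_MASTER_POSITION = 11
K182_MASTER_POSITION = 12

# Propensity vectors are (A, C, G, U) and sum to 1.
# Profile residues: RRM1-like uses F/R/D/F/K/E at positions 10..15,
# RRM2-like uses W/E/K/Y/R/Q.
_PROFILE_VECTORS: dict[tuple[int, str], tuple[float, float, float, float]] = {
    (10, "F"): (0.20, 0.35, 0.25, 0.20),
    (10, "W"): (0.14, 0.42, 0.29, 0.15),
    (13, "F"): (0.65, 0.13, 0.12, 0.10),
    (13, "Y"): (0.70, 0.10, 0.10, 0.10),
    (14, "K"): (0.10, 0.10, 0.70, 0.10),
    (14, "R"): (0.08, 0.07, 0.75, 0.10),
    (15, "E"): (0.20, 0.15, 0.25, 0.40),
    (15, "Q"): (0.20, 0.15, 0.40, 0.25),
}

# Full 20-residue tables at the two pyrimidine-contact positions, so the
# protein-design search can rank every substitution.  Calibration: at
# position 11, N has the uniquely lowest P(U) with high P(C) (then A, then S);
# at position 12, M is lowest-P(U) with high P(C) (then S, then A).
_POS11_TABLE: dict[str, tuple[float, float, float, float]] = {
    "A": (0.17, 0.45, 0.30, 0.08),
    "C": (0.25, 0.25, 0.30, 0.20),
    "D": (0.25, 0.20, 0.25, 0.30),
    "E": (0.10, 0.35, 0.10, 0.45),  # RRM2-like wild type (author 180)
    "F": (0.25, 0.20, 0.25, 0.30),
    "G": (0.30, 0.20, 0.30, 0.20),
    "H": (0.20, 0.25, 0.25, 0.30),
    "I": (0.30, 0.20, 0.30, 0.20),
    "K": (0.20, 0.25, 0.20, 0.35),
    "L": (0.30, 0.20, 0.30, 0.20),
    "M": (0.25, 0.30, 0.25, 0.20),
    "N": (0.25, 0.40, 0.30, 0.05),
    "P": (0.25, 0.25, 0.30, 0.20),
    "Q": (0.20, 0.30, 0.20, 0.30),
    "R": (0.22, 0.08, 0.15, 0.55),  # RRM1-like wild type
    "S": (0.28, 0.32, 0.30, 0.10),
    "T": (0.27, 0.28, 0.30, 0.15),
    "V": (0.30, 0.20, 0.30, 0.20),
    "W": (0.25, 0.20, 0.25, 0.30),
    "Y": (0.25, 0.20, 0.25, 0.30),
}
_POS12_TABLE: dict[str, tuple[float, float, float, float]] = {
    "A": (0.30, 0.25, 0.30, 0.15),
    "C": (0.25, 0.25, 0.30, 0.20),
    "D": (0.20, 0.10, 0.20, 0.50),  # RRM1-like wild type
    "E": (0.25, 0.20, 0.25, 0.30),
    "F": (0.25, 0.20, 0.25, 0.30),
    "G": (0.30, 0.20, 0.30, 0.20),
    "H": (0.20, 0.25, 0.25, 0.30),
    "I": (0.30, 0.20, 0.30, 0.20),
    "K": (0.15, 0.30, 0.10, 0.45),  # RRM2-like wild type (author 182)
    "L": (0.30, 0.20, 0.30, 0.20),
    "M": (0.28, 0.37, 0.30, 0.05),
    "N": (0.25, 0.30, 0.25, 0.20),
    "P": (0.25, 0.25, 0.30, 0.20),
    "Q": (0.20, 0.30, 0.20, 0.30),
    "R": (0.20, 0.15, 0.25, 0.40),
    "S": (0.25, 0.38, 0.30, 0.07),
    "T": (0.27, 0.28, 0.30, 0.15),
    "V": (0.30, 0.20, 0.30, 0.20),
    "W": (0.25, 0.20, 0.25, 0.30),
    "Y": (0.25, 0.20, 0.25, 0.30),
}


def fixture_model() -> PropensityModel:
    """The packaged synthetic propensity model (see module docstring)."""
    entries: dict[tuple[int, str], tuple[float, ...]] = dict(_PROFILE_VECTORS)
    for res in AMINO_ACIDS:
        entries[(11, res)] = _POS11_TABLE[res]
        entries[(12, res)] = _POS12_TABLE[res]
    return PropensityModel(
        {k: list(v) for k, v in entries.items()},
        alpha=1.0,
        positions=sorted(SLOT_MAP_5),
    )


def _scaffold(length: int, placements: dict[int, str], offset: int) -> str:
    """Glycine scaffold with specific residues planted at author positions."""
    seq = ["G"] * length
    for author, res in placements.items():
        seq[author - offset - 1] = res
    return "".join(seq)


def rrm1_profile() -> RRMProfile:
    """Synthetic RRM1-like profile: author positions 20..32 on a 1..103 scaffold."""
    position_map = {10: 20, 11: 24, 12: 26, 13: 28, 14: 30, 15: 32}
    placements = {20: "F", 24: "R", 26: "D", 28: "F", 30: "K", 32: "E"}
    seq = _scaffold(103, placements, offset=0)
    return build_profile(seq, position_map, offset=0, domain_name="RRM1")


def rrm2_profile() -> RRMProfile:
    """Synthetic RRM2-like profile covering author residues 104..200, with the
    two pyrimidine-contact residues at author numbers 180 (E) and 182 (K)."""
    position_map = {10: 176, 11: 180, 12: 182, 13: 184, 14: 186, 15: 188}
    placements = {176: "W", 180: "E", 182: "K", 184: "Y", 186: "R", 188: "Q"}
    seq = _scaffold(97, placements, offset=103)
    return build_profile(seq, position_map, offset=103, domain_name="RRM2")
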