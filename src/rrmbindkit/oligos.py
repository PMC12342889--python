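"""Catalog of the MSI-1 study RNA oligonucleotides (5'→3').

Linear oligos (L) carry one or two consensus sites on an unstructured strand;
hairpin oligos (HP) fold back on themselves, placing sites in the loop and/or
stem.  The ``.1``/``.2`` variants replace UAG-class sites with the CAG switch
motif.  Dot-bracket annotations are provided only where the stem register is
unambiguous from base complementarity (a 5-bp stem for oligo-HP4).
"""

OLIGOS: dict[str, str] = {
    "oligo-L2": "UUGUUAGUUACCCCUU",
    "oligo-L2.1": "UUGUCAGUUACCCCUU",
    "oligo-L3": "UUGUUAGUUAUUAGUU",
    "oligo-L3.2": "UUGAUAGUUAGCAGGU",
    "oligo-HP4": "AAGCGUUAGUUAUUUAGUCGCUU",
    "oligo-HP4.2": "AAGCGAUAGUUAUGCAGGCGCUU",
    "oligo-HP5": "CACUCUGUAGUAUGUAGGGUUUAUUU",
}

# 5-bp stem (A-U, A-U, G-C, C-G, G-C), 13-nt loop.
HP4_DOTBRACKET = "(((((.............)))))"

__all__ = ["OLIGOS", "HP4_DOTBRACKET"]
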