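"""Count consensus binding sites on the study oligos and classify hairpin context.

Scans each oligo for the RRM1 consensus (G/A)U(1-3)AGU and the minimal UAG,
merges overlapping hits into maximal binding sites, and — for the hairpin
oligo with an unambiguous 5-bp stem — reports where each site sits relative
to the stem/loop.
"""

from rrmbindkit.motifs import (
    DEFAULT_PATTERNS,
    HairpinStructure,
    classify_site_context,
    find_motifs,
    merge_sites,
    validate_hairpin,
)
from rrmbindkit.oligos import HP4_DOTBRACKET, OLIGOS

rrm1_pat, uag_pat, cag_pat = DEFAULT_PATTERNS

for name in ("oligo-L2", "oligo-L2.1", "oligo-L3", "oligo-HP4", "oligo-HP5"):
    seq = OLIGOS[name]
    hits = find_motifs(seq, [rrm1_pat, uag_pat])
    sites = merge_sites(hits)
    spans = ", ".join(f"{s.start}-{s.end}" for s in sites)
    print(f"{name:12s} {seq:26s} {len(sites)} merged site(s): {spans or '-'}")

print("\noligo-HP4 hairpin (5-bp stem):")
structure = HairpinStructure(OLIGOS["oligo-HP4"], HP4_DOTBRACKET)
report = validate_hairpin(structure)
print(f"  {report.n_pairs} base pairs, loop {report.loop[0]}-{report.loop[1]}, "
      f"valid={report.valid}")
sites = merge_sites(find_motifs(OLIGOS["oligo-HP4"], [rrm1_pat, uag_pat]))
for site, label in classify_site_context(sites, structure).items():
    print(f"  site {site.start}-{site.end} ({'+'.join(site.members)}): {label}")

print("\nA single-site oligo carries one merged site (the UAG is embedded in")
print("the longer consensus); the two-site oligos carry two, and the CAG-")
print("substituted oligo has no UAG at all.")
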