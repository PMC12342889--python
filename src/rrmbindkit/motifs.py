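"""Consensus-motif scanning, binding-site merging, and hairpin annotation.

Musashi-1's two RRM domains recognise overlapping RNA sequence classes: the
longer (G/A)U(1-3)AGU consensus (RRM1) and the minimal UAG (RRM2); designed
"switch" RNAs replace UAG by CAG.  This module locates all such sites on an
oligo, merges overlapping hits into maximal binding sites (a UAG embedded in
a (G/A)U(1-3)AGU match is one site, not two), and — for hairpin oligos —
validates a user-supplied dot-bracket structure and classifies each site as
sitting in the loop, the stem, or both.

Coordinates in all reports are 1-based inclusive; internally everything is
0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import InputError, StructureError
from .scoring import RNA_ALPHABET

# Watson-Crick plus G-U wobble (unordered)
_CANONICAL_PAIRS = {
    frozenset(("A", "U")),
    frozenset(("G", "C")),
    frozenset(("G", "U")),
}

__all__ = [
    "MotifPattern",
    "MotifHit",
    "Site",
    "SiteSet",
    "HairpinStructure",
    "HairpinReport",
    "DEFAULT_PATTERNS",
    "find_motifs",
    "merge_sites",
    "validate_hairpin",
    "classify_site_context",
]


@dataclass(frozen=True)
class MotifPattern:
    """A named restricted regular expression over {A,C,G,U}.

    Supports alternation and bounded repetition, e.g. ``(G|A)U{1,3}AGU``.
    """

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if re.search(r"[^ACGU(){}|,0-9\[\]]", self.pattern):
            raise InputError(
                f"pattern {self.name!r} uses characters outside the restricted "
                "RNA regular-expression alphabet"
            )
        try:
            object.__setattr__(self, "_compiled", re.compile(self.pattern))
        except re.error as exc:
            raise InputError(f"pattern {self.name!r} does not compile: {exc}") from exc

    @property
    def compiled(self) -> re.Pattern:
        return self._compiled  # type: ignore[attr-defined]


DEFAULT_PATTERNS: tuple[MotifPattern, ...] = (
    MotifPattern("RRM1_consensus", "(G|A)U{1,3}AGU"),
    MotifPattern("RRM2_minimal", "UAG"),
    MotifPattern("CAG_switch", "CAG"),
)


@dataclass(frozen=True)
class MotifHit:
    """One pattern match; ``start``/``end`` are 1-based inclusive."""

    start: int
    end: int
    matched: str
    pattern_name: str

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise InputError("hit coordinates must satisfy 1 <= start <= end")


def _check_rna(rna: str) -> None:
    bad = set(rna) - set(RNA_ALPHABET)
    if bad:
        raise InputError(
            f"sequence contains characters outside A/C/G/U: {sorted(bad)}"
        )


def find_motifs(rna: str, patterns: list[MotifPattern] | None = None) -> list[MotifHit]:
    """All matches of each pattern on ``rna``.

    Matching is leftmost-longest within a pattern, anchored at every start
    position, so overlapping occurrences of the same pattern are all
    reported (and patterns never mask each other).  Hits are ordered by
    (start, pattern order).
    """
    _check_rna(rna)
    patterns = list(DEFAULT_PATTERNS) if patterns is None else patterns
    hits: list[MotifHit] = []
    for pat in patterns:
        for i in range(len(rna)):
            m = pat.compiled.match(rna, i)
            if m is not None and m.end() > i:
                hits.append(MotifHit(i + 1, m.end(), rna[i : m.end()], pat.name))
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


@dataclass(frozen=True)
class Site:
    """A maximal merged binding site (1-based inclusive coordinates)."""

    start: int
    end: int
    members: tuple[str, ...]  # pattern names of the merged hits


@dataclass(frozen=True)
class SiteSet:
    sites: tuple[Site, ...]

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)


def merge_sites(hits: list[MotifHit]) -> SiteSet:
    """Merge hits that overlap by at least one nucleotide into maximal sites.

    Idempotent and independent of input order.  Adjacent (but not
    overlapping) hits remain separate sites.
    """
    if not hits:
        return SiteSet(())
    ordered = sorted(hits, key=lambda h: (h.start, h.end))
    sites: list[tuple[int, int, list[str]]] = []
    for h in ordered:
        if sites and h.start <= sites[-1][1]:
            start, end, members = sites[-1]
            sites[-1] = (start, max(end, h.end), members + [h.pattern_name])
        else:
            sites.append((h.start, h.end, [h.pattern_name]))
    return SiteSet(tuple(Site(s, e, tuple(sorted(set(m)))) for s, e, m in sites))


@dataclass(frozen=True)
class HairpinStructure:
    """An RNA sequence with its dot-bracket secondary structure."""

    sequence: str
    dotbracket: str

    def __post_init__(self) -> None:
        _check_rna(self.sequence)
        if len(self.sequence) != len(self.dotbracket):
            raise StructureError(
                f"sequence ({len(self.sequence)} nt) and dot-bracket "
                f"({len(self.dotbracket)} chars) lengths differ"
            )
        bad = set(self.dotbracket) - set("().")
        if bad:
            raise StructureError(f"dot-bracket contains invalid characters {sorted(bad)}")


@dataclass(frozen=True)
class HairpinReport:
    """Validation report: paired indices, stem size, loop span, violations."""

    pairs: tuple[tuple[int, int], ...]  # 1-based (i, j), i < j
    n_pairs: int
    loop: tuple[int, int] | None  # 1-based inclusive span of the apical loop
    violations: tuple[str, ...]
    valid: bool


def validate_hairpin(structure: HairpinStructure) -> HairpinReport:
    """Pair up the dot-bracket and check base-pair chemistry.

    Unbalanced brackets raise :class:`StructureError`; non-canonical pairs
    (anything other than Watson-Crick or G-U wobble) are *listed* as
    violations and flip ``valid`` to False.  The loop is the unpaired span
    enclosed by the innermost base pair (None if there are no pairs or the
    enclosed region contains further pairs).
    """
    seq, db = structure.sequence, structure.dotbracket
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {i + 1}")
            pairs.append((stack.pop(), i))
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1] + 1}")
    pairs.sort()
    violations = []
    for i, j in pairs:
        if frozenset((seq[i], seq[j])) not in _CANONICAL_PAIRS:
            violations.append(
                f"non-canonical pair {seq[i]}{i + 1}-{seq[j]}{j + 1}"
            )
    loop = None
    if pairs:
        inner_i, inner_j = max(pairs, key=lambda p: p[0])
        if inner_j - inner_i > 1 and all(
            db[k] == "." for k in range(inner_i + 1, inner_j)
        ):
            loop = (inner_i + 2, inner_j)  # 1-based inclusive
    return HairpinReport(
        pairs=tuple((i + 1, j + 1) for i, j in pairs),
        n_pairs=len(pairs),
        loop=loop,
        violations=tuple(violations),
        valid=not violations,
    )


def classify_site_context(sites: SiteSet, structure: HairpinStructure) -> dict[Site, str]:
    """Label each site 'loop' (all nucleotides unpaired), 'stem' (all paired),
    or 'mixed'."""
    report = validate_hairpin(structure)
    paired = {i for ij in report.pairs for i in ij}  # 1-based
    n = len(structure.sequence)
    labels: dict[Site, str] = {}
    for site in sites:
        if site.end > n:
            raise InputError(
                f"site {site.start}-{site.end} extends beyond the "
                f"{n}-nt structure"
            )
        span = site.end - site.start + 1
        n_paired = sum(1 for p in range(site.start, site.end + 1) if p in paired)
        if n_paired == 0:
            labels[site] = "loop"
        elif n_paired == span:
            labels[site] = "stem"
        else:
            labels[site] = "mixed"
    return labels
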