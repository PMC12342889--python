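"""Position-specific residue→nucleotide contact propensities for RRM domains.

RRM (RNA recognition motif) domains read single-stranded RNA through a small
set of conserved binding positions on their β-sheet face.  Across solved
RRM–RNA complexes, the residue occupying such a *master position* contacts a
nucleotide at a fixed slot of the bound RNA window.  Pooling those contacts
gives, for every (master position, residue) pair, a propensity vector
P(n | position, residue) over the four bases — a per-position preference
matrix.  A candidate RNA window is then scored additively on a log scale:

    score(window) = Σ_positions log10( P(n_slot | pos, res) / background(n_slot) )

so that 0 means "indistinguishable from background" and positive values mean
the profiled domain prefers the window.  On top of the scorer sit two design
searches: ranking RNA motifs for a profile (optionally with fixed slots, e.g.
N-UAG-N), and ranking residue substitutions at one position so as to switch
the preferred nucleotide (e.g. away from uracil, toward cytosine).

The master alignment itself is *not* re-derived here: master positions and
the position→window-slot map are explicit inputs, and training data are
contact records (one row per observed residue–nucleotide contact).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError, UnobservedPairError

RNA_ALPHABET = "ACGU"
_NT_INDEX = {n: i for i, n in enumerate(RNA_ALPHABET)}
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
UNIFORM_BACKGROUND = np.full(4, 0.25)

__all__ = [
    "RNA_ALPHABET",
    "AMINO_ACIDS",
    "UNIFORM_BACKGROUND",
    "ContactRecord",
    "PropensityModel",
    "RRMProfile",
    "ScoredMotif",
    "RnaCandidate",
    "ResidueCandidate",
    "DesignResult",
    "train_propensities",
    "build_profile",
    "score_window",
    "scan_rna",
    "rank_motifs",
    "design_rna_switch",
    "design_protein_switch",
]


def _check_rna(s: str, what: str = "RNA string") -> None:
    bad = set(s) - set(RNA_ALPHABET)
    if bad:
        raise InputError(
            f"{what} contains characters outside A/C/G/U: {sorted(bad)} "
            "(T is accepted only at the I/O layer, where it is converted to U)"
        )


@dataclass(frozen=True)
class ContactRecord:
    """One observed residue–nucleotide contact in a structure.

    ``master_position`` indexes the fixed master RRM alignment;
    ``window_slot`` indexes the contacted nucleotide inside the RNA window.
    """

    complex_id: str
    master_position: int
    residue: str
    window_slot: int
    nucleotide: str

    def __post_init__(self) -> None:
        if self.residue not in AMINO_ACIDS:
            raise InputError(f"unknown residue code {self.residue!r}")
        if self.nucleotide not in RNA_ALPHABET:
            raise InputError(f"unknown nucleotide {self.nucleotide!r}")
        if self.master_position < 0:
            raise InputError("master_position must be >= 0")
        if self.window_slot < 0:
            raise InputError("window_slot must be >= 0")


class PropensityModel:
    """Per (master position, residue) nucleotide propensities with pseudocount.

    Vectors are ordered (A, C, G, U) and sum to 1.  With pseudocount
    ``alpha > 0`` every pair is defined, unseen pairs falling back to the
    pseudocount-only vector (uniform for a flat prior); with ``alpha == 0``
    querying an unobserved pair raises :class:`UnobservedPairError` rather
    than returning a silent zero.
    """

    def __init__(
        self,
        entries: dict[tuple[int, str], np.ndarray],
        alpha: float = 1.0,
        background: np.ndarray | None = None,
        positions: list[int] | None = None,
    ) -> None:
        if alpha < 0:
            raise InputError("pseudocount alpha must be >= 0")
        self.alpha = float(alpha)
        self.background = (
            UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)
        )
        if self.background.shape != (4,) or abs(self.background.sum() - 1.0) > 1e-9:
            raise InputError("background must be a length-4 probability vector summing to 1")
        self.entries: dict[tuple[int, str], np.ndarray] = {}
        for key, vec in entries.items():
            v = np.asarray(vec, float)
            if v.shape != (4,) or abs(v.sum() - 1.0) > 1e-9 or (v < 0).any():
                raise InputError(f"propensity vector for {key} is not a probability vector")
            if self.alpha > 0 and (v <= 0).any():
                raise InputError(f"propensity vector for {key} has a zero entry despite alpha > 0")
            self.entries[(int(key[0]), key[1])] = v
        observed = sorted({p for p, _ in self.entries})
        declared = sorted(set(positions or []))
        self.positions = sorted(set(observed) | set(declared))

    def probability(self, position: int, residue: str) -> np.ndarray:
        """Propensity vector (A, C, G, U) for one (position, residue) pair."""
        key = (position, residue)
        if key in self.entries:
            return self.entries[key]
        if self.alpha > 0:
            # zero observed counts: (0 + alpha) / (0 + 4 alpha)
            return UNIFORM_BACKGROUND.copy()
        raise UnobservedPairError(
            f"(position={position}, residue={residue}) was never observed and alpha=0"
        )

    def prob(self, position: int, residue: str, nucleotide: str) -> float:
        if nucleotide not in _NT_INDEX:
            raise InputError(f"unknown nucleotide {nucleotide!r}")
        return float(self.probability(position, residue)[_NT_INDEX[nucleotide]])

    def log_odds(self, position: int, residue: str) -> np.ndarray:
        """log10(P(n|pos,res) / background(n)) for the four nucleotides."""
        p = self.probability(position, residue)
        with np.errstate(divide="ignore"):
            return np.log10(p / self.background)


def train_propensities(
    contacts: list[ContactRecord],
    alpha: float = 1.0,
    background: np.ndarray | None = None,
    positions: list[int] | None = None,
) -> PropensityModel:
    """Estimate P(n | position, residue) from contact records.

    Additive smoothing:  P = (count + alpha) / (total + 4*alpha).
    ``positions`` may declare master positions a priori (kept in the model's
    position list even if unobserved).
    """
    if alpha < 0:
        raise InputError("pseudocount alpha must be >= 0")
    if not contacts and alpha == 0:
        raise InputError("no contacts and alpha=0: every propensity would be undefined")
    counts: dict[tuple[int, str], np.ndarray] = {}
    for rec in contacts:
        key = (rec.master_position, rec.residue)
        counts.setdefault(key, np.zeros(4))[_NT_INDEX[rec.nucleotide]] += 1
    entries = {
        key: (c + alpha) / (c.sum() + 4 * alpha) for key, c in counts.items()
    }
    return PropensityModel(entries, alpha=alpha, background=background, positions=positions)


@dataclass(frozen=True)
class RRMProfile:
    """Mapping of one domain sequence onto master binding positions.

    ``residue_at`` maps master position → (residue, author_number) where the
    author number is the human-protein residue numbering; the residue is
    always read off ``source_sequence`` at ``author_number - numbering_offset``
    (1-based), so substitutions are made by editing the sequence, never the map.
    """

    domain_name: str
    residue_at: dict[int, tuple[str, int]]
    source_sequence: str
    numbering_offset: int = 0

    @property
    def positions(self) -> list[int]:
        return sorted(self.residue_at)

    def residue(self, master_position: int) -> str:
        try:
            return self.residue_at[master_position][0]
        except KeyError:
            raise InputError(
                f"master position {master_position} is not mapped in profile "
                f"{self.domain_name!r}"
            ) from None

    def with_substitution(self, author_number: int, new_residue: str) -> "RRMProfile":
        """Return a new profile with the residue at ``author_number`` replaced."""
        if new_residue not in AMINO_ACIDS:
            raise InputError(f"unknown residue code {new_residue!r}")
        idx = author_number - self.numbering_offset - 1
        if not 0 <= idx < len(self.source_sequence):
            raise InputError(
                f"author residue number {author_number} falls outside the sequence "
                f"of {self.domain_name!r}"
            )
        seq = self.source_sequence[:idx] + new_residue + self.source_sequence[idx + 1 :]
        name = f"{self.domain_name}-{self.source_sequence[idx]}{author_number}{new_residue}"
        return build_profile(
            seq,
            {p: a for p, (_, a) in self.residue_at.items()},
            offset=self.numbering_offset,
            domain_name=name,
        )


def build_profile(
    sequence: str,
    position_map: dict[int, int],
    offset: int = 0,
    domain_name: str = "RRM",
) -> RRMProfile:
    """Read profile residues off ``sequence`` via author numbering.

    ``position_map`` maps master position → author residue number; the
    residue at author number ``a`` is ``sequence[a - offset - 1]``.
    """
    residue_at: dict[int, tuple[str, int]] = {}
    for pos, author in position_map.items():
        idx = author - offset - 1
        if not 0 <= idx < len(sequence):
            raise InputError(
                f"author residue number {author} (master position {pos}) is outside "
                f"the {len(sequence)}-residue sequence (offset {offset})"
            )
        res = sequence[idx]
        if res not in AMINO_ACIDS:
            raise InputError(f"sequence position {author} holds non-residue {res!r}")
        residue_at[int(pos)] = (res, int(author))
    return RRMProfile(domain_name, residue_at, sequence, offset)


@dataclass(frozen=True)
class ScoredMotif:
    """A scored RNA window: total log10-odds plus its per-position addends."""

    window: str
    score: float
    contributions: tuple[tuple[int, float], ...]  # (master_position, addend)
    profile_name: str
    start: int | None = None  # 1-based, set by scan_rna
    missing_positions: tuple[int, ...] = ()


def _slot_log_odds(
    model: PropensityModel,
    profile: RRMProfile,
    slot_map: dict[int, int],
) -> tuple[list[tuple[int, int, np.ndarray]], tuple[int, ...]]:
    """Per mapped master position: (position, slot, log-odds vector).

    Positions absent from the profile contribute nothing and are returned as
    flagged ``missing``.
    """
    per_position = []
    missing = []
    for pos in sorted(slot_map):
        slot = slot_map[pos]
        if slot < 0:
            raise InputError(f"window slot for master position {pos} must be >= 0")
        if pos not in profile.residue_at:
            missing.append(pos)
            continue
        per_position.append((pos, slot, model.log_odds(pos, profile.residue(pos))))
    return per_position, tuple(missing)


def score_window(
    model: PropensityModel,
    profile: RRMProfile,
    window: str,
    slot_map: dict[int, int],
) -> ScoredMotif:
    """Score one RNA window for a profiled domain.

    score = Σ over mapped master positions of
            log10(P(window[slot] | position, residue) / background(window[slot])).
    """
    _check_rna(window, "window")
    per_position, missing = _slot_log_odds(model, profile, slot_map)
    needed = max((slot for _, slot, _ in per_position), default=-1)
    if len(window) <= needed:
        raise InputError(
            f"window of length {len(window)} does not cover slot {needed}"
        )
    contributions = []
    for pos, slot, lo in per_position:
        contributions.append((pos, float(lo[_NT_INDEX[window[slot]]])))
    return ScoredMotif(
        window=window,
        score=float(sum(c for _, c in contributions)),
        contributions=tuple(contributions),
        profile_name=profile.domain_name,
        missing_positions=missing,
    )


def scan_rna(
    model: PropensityModel,
    profile: RRMProfile,
    rna: str,
    k: int,
    slot_map: dict[int, int],
) -> list[ScoredMotif]:
    """Score every length-k window of ``rna`` (step 1), ordered by start."""
    if k < 1:
        raise InputError("window length k must be >= 1")
    _check_rna(rna)
    out = []
    for i in range(len(rna) - k + 1):
        sm = score_window(model, profile, rna[i : i + k], slot_map)
        out.append(
            ScoredMotif(sm.window, sm.score, sm.contributions, sm.profile_name,
                        start=i + 1, missing_positions=sm.missing_positions)
        )
    return out


def _slot_contributions(
    model: PropensityModel, profile: RRMProfile, k: int, slot_map: dict[int, int]
) -> np.ndarray:
    """Summed log-odds per (slot, nucleotide) — windows score additively."""
    table = np.zeros((k, 4))
    per_position, _ = _slot_log_odds(model, profile, slot_map)
    for _, slot, lo in per_position:
        if slot >= k:
            raise InputError(f"slot map references slot {slot} but k={k}")
        table[slot] += lo
    return table


def _enumerate_windows(k: int, constraints: dict[int, str] | None):
    constraints = constraints or {}
    for slot, nt in constraints.items():
        if not 0 <= slot < k:
            raise InputError(f"constraint slot {slot} is outside the window (k={k})")
        if nt not in _NT_INDEX:
            raise InputError(f"constraint nucleotide {nt!r} is not one of A/C/G/U")
    choices = [
        (constraints[s],) if s in constraints else tuple(RNA_ALPHABET) for s in range(k)
    ]
    for combo in itertools.product(*choices):
        yield "".join(combo)


@dataclass(frozen=True)
class RnaCandidate:
    window: str
    objective: float
    score_on: float | None = None
    score_off: float | None = None


@dataclass(frozen=True)
class ResidueCandidate:
    residue: str
    score_off: float  # log10-odds toward the nucleotide being designed away from
    score_on: float  # log10-odds toward the target nucleotide
    is_reference: bool = False


@dataclass(frozen=True)
class DesignResult:
    """Deterministically ranked design candidates (ties broken lexicographically)."""

    kind: str  # "rna" | "protein"
    candidates: tuple = ()
    message: str = ""

    def __bool__(self) -> bool:
        return bool(self.candidates)


def rank_motifs(
    model: PropensityModel,
    profile: RRMProfile,
    k: int,
    constraints: dict[int, str] | None = None,
    slot_map: dict[int, int] | None = None,
) -> list[ScoredMotif]:
    """Exhaustively score all 4^(free slots) windows, sorted descending.

    Ties are broken lexicographically on the window (A<C<G<U).  ``k`` is
    capped at 8 to keep enumeration exact and cheap.
    """
    if not 1 <= k <= 8:
        raise InputError("rank_motifs enumerates exhaustively and requires 1 <= k <= 8")
    if slot_map is None:
        raise InputError("rank_motifs requires a slot_map (master position -> window slot)")
    table = _slot_contributions(model, profile, k, slot_map)
    scored = []
    for window in _enumerate_windows(k, constraints):
        s = float(sum(table[slot][_NT_INDEX[nt]] for slot, nt in enumerate(window)))
        scored.append((window, s))
    scored.sort(key=lambda ws: (-ws[1], ws[0]))
    return [score_window(model, profile, window, slot_map) for window, _ in scored]


def design_rna_switch(
    model: PropensityModel,
    profile_off: RRMProfile,
    profile_on: RRMProfile,
    k: int,
    constraints: dict[int, str] | None = None,
    slot_map: dict[int, int] | None = None,
    floor: float = -math.inf,
) -> DesignResult:
    """Rank RNA windows by (score_on − score_off), largest first.

    The search looks for motifs that *drop* the score of ``profile_off`` while
    keeping ``profile_on`` high; candidates with score_on below ``floor`` are
    discarded.  An empty result (floor too high) is returned with a
    diagnostic message, not raised.
    """
    if not 1 <= k <= 8:
        raise InputError("design_rna_switch enumerates exhaustively and requires 1 <= k <= 8")
    if slot_map is None:
        raise InputError("design_rna_switch requires a slot_map")
    t_off = _slot_contributions(model, profile_off, k, slot_map)
    t_on = _slot_contributions(model, profile_on, k, slot_map)
    cands = []
    n_total = 0
    for window in _enumerate_windows(k, constraints):
        n_total += 1
        idx = [_NT_INDEX[nt] for nt in window]
        s_on = float(sum(t_on[s][i] for s, i in enumerate(idx)))
        s_off = float(sum(t_off[s][i] for s, i in enumerate(idx)))
        if s_on < floor:
            continue
        cands.append(RnaCandidate(window, s_on - s_off, score_on=s_on, score_off=s_off))
    cands.sort(key=lambda c: (-c.objective, c.window))
    if not cands:
        return DesignResult(
            "rna",
            (),
            message=f"no candidate of {n_total} enumerated reached the floor {floor}",
        )
    return DesignResult("rna", tuple(cands))


def design_protein_switch(
    model: PropensityModel,
    profile: RRMProfile,
    master_position: int,
    on_nt: str,
    off_nt: str,
) -> DesignResult:
    """Rank the 19 substitutions (plus the current residue as reference) at one
    master position by a lexicographic objective: first minimize the log-odds
    toward ``off_nt``, then maximize the log-odds toward ``on_nt``; residue
    code breaks remaining ties alphabetically.
    """
    if master_position not in model.positions:
        raise InputError(f"master position {master_position} is not in the model")
    if master_position not in profile.residue_at:
        raise InputError(
            f"master position {master_position} is not mapped in profile "
            f"{profile.domain_name!r}"
        )
    for nt, name in ((on_nt, "on_nt"), (off_nt, "off_nt")):
        if nt not in _NT_INDEX:
            raise InputError(f"{name}={nt!r} is not one of A/C/G/U")
    current = profile.residue(master_position)
    cands = []
    for res in AMINO_ACIDS:
        lo = model.log_odds(master_position, res)
        cands.append(
            ResidueCandidate(
                residue=res,
                score_off=float(lo[_NT_INDEX[off_nt]]),
                score_on=float(lo[_NT_INDEX[on_nt]]),
                is_reference=(res == current),
            )
        )
    cands.sort(key=lambda c: (c.score_off, -c.score_on, c.residue))
    return DesignResult("protein", tuple(cands))
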