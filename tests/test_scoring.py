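"""Propensity training, window scoring, and the two design searches."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rrmbindkit import fixtures
from rrmbindkit.errors import InputError, UnobservedPairError
from rrmbindkit.scoring import (
    AMINO_ACIDS,
    RNA_ALPHABET,
    ContactRecord,
    PropensityModel,
    build_profile,
    design_protein_switch,
    design_rna_switch,
    rank_motifs,
    scan_rna,
    score_window,
    train_propensities,
)
from rrmbindkit.synth import gen_contact_table


def rec(pos, res, nt, cid="c0"):
    return ContactRecord(cid, pos, res, 0, nt)


def oracle_score(model, profile, window, slot_map):
    """Independent brute-force re-summation of per-position log-odds."""
    total = 0.0
    for pos, slot in slot_map.items():
        if pos not in profile.residue_at:
            continue
        p = model.prob(pos, profile.residue(pos), window[slot])
        total += math.log10(p / model.background["ACGU".index(window[slot])])
    return total


def tv_distance(p, q):
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


class TestTraining:
    def test_pseudocount_only_limit(self):
        """With no contacts and alpha=1 every queried vector is uniform."""
        m = train_propensities([], alpha=1.0)
        assert np.allclose(m.probability(3, "K"), [0.25] * 4)

    def test_hand_counted_frequencies(self):
        """{U,U,C} at one (pos,res) with alpha=1 -> P(U)=3/7, P(C)=2/7,
        P(A)=P(G)=1/7."""
        m = train_propensities([rec(2, "N", "U"), rec(2, "N", "U"), rec(2, "N", "C")])
        assert np.allclose(m.probability(2, "N"), [1 / 7, 2 / 7, 1 / 7, 3 / 7])

    def test_vectors_normalised_for_any_alpha(self):
        contacts = [rec(1, "R", nt) for nt in "AAUGC"] + [rec(2, "K", "G")]
        for alpha in (0.0, 0.5, 1.0, 10.0):
            m = train_propensities(contacts, alpha=alpha)
            for v in m.entries.values():
                assert abs(v.sum() - 1.0) < 1e-9

    def test_alpha_zero_unobserved_pair_raises(self):
        m = train_propensities([rec(1, "R", "U")], alpha=0.0)
        with pytest.raises(UnobservedPairError):
            m.probability(1, "K")

    def test_recovery_from_sampled_contacts(self, model):
        """Retraining on 1e4 sampled records per pair recovers the planted
        vectors to TV < 0.02; TV shrinks from n=1e2 to n=1e4."""
        tv_by_n = {}
        for n in (100, 10_000):
            records = gen_contact_table(model, n, seed=7)
            refit = train_propensities(records, alpha=1.0)
            tv_by_n[n] = max(
                tv_distance(refit.probability(pos, res), model.probability(pos, res))
                for pos, res in model.entries
            )
        assert tv_by_n[10_000] < 0.02
        assert tv_by_n[10_000] < tv_by_n[100]

    def test_declared_positions_kept(self):
        m = train_propensities([rec(1, "R", "U")], positions=[1, 9])
        assert m.positions == [1, 9]


class TestProfiles:
    def test_pyrimidine_contact_residues(self, rrm2):
        """The RRM2-like profile reads E at author 180 and K at 182."""
        assert rrm2.residue_at[fixtures.E180_MASTER_POSITION] == ("E", 180)
        assert rrm2.residue_at[fixtures.K182_MASTER_POSITION] == ("K", 182)

    def test_substitution_edits_sequence_not_map(self, rrm2):
        mutant = rrm2.with_substitution(180, "N")
        assert mutant.residue_at[fixtures.E180_MASTER_POSITION] == ("N", 180)
        # untouched positions identical
        assert mutant.residue_at[fixtures.K182_MASTER_POSITION] == ("K", 182)
        assert mutant.source_sequence != rrm2.source_sequence

    def test_empty_position_map_scores_zero(self, model):
        prof = build_profile("GGGG", {}, domain_name="empty")
        sm = score_window(model, prof, "ACGUA", fixtures.SLOT_MAP_5)
        assert sm.score == 0.0 and sm.contributions == ()

    def test_out_of_range_author_number(self):
        with pytest.raises(InputError, match="42"):
            build_profile("GGG", {1: 42})


class TestScoreWindow:
    def test_uniform_model_scores_zero(self, rrm2):
        """A model equal to background carries no information: score 0."""
        uniform = PropensityModel(
            {(p, r): [0.25] * 4 for p in fixtures.SLOT_MAP_5 for r in AMINO_ACIDS},
            alpha=1.0,
        )
        for window in ("ACGUA", "UUUUU", "CUAGG"):
            assert score_window(uniform, rrm2, window, fixtures.SLOT_MAP_5).score == pytest.approx(0.0, abs=1e-12)

    def test_two_position_hand_arithmetic(self):
        """P(U|p1,R)=0.5, P(A|p2,K)=0.4, uniform background ->
        log10(0.5/0.25) + log10(0.4/0.25) = 0.50515."""
        m = PropensityModel(
            {(1, "R"): [0.2, 0.2, 0.1, 0.5], (2, "K"): [0.4, 0.2, 0.2, 0.2]},
            alpha=1.0,
        )
        prof = build_profile("RK", {1: 1, 2: 2}, domain_name="toy")
        sm = score_window(m, prof, "UA", {1: 0, 2: 1})
        assert sm.score == pytest.approx(0.30103 + 0.20412, abs=1e-5)

    def test_score_equals_contribution_sum_and_oracle(self, model, rrm1):
        rng = np.random.default_rng(11)
        for _ in range(25):
            w = "".join(rng.choice(list(RNA_ALPHABET), 5))
            sm = score_window(model, rrm1, w, fixtures.SLOT_MAP_5)
            assert sm.score == pytest.approx(sum(c for _, c in sm.contributions), abs=1e-9)
            assert sm.score == pytest.approx(
                oracle_score(model, rrm1, w, fixtures.SLOT_MAP_5), abs=1e-9
            )

    def test_unmapped_positions_flagged(self, model):
        prof = build_profile("R", {11: 1}, domain_name="partial")
        sm = score_window(model, prof, "ACGUA", fixtures.SLOT_MAP_5)
        assert set(sm.missing_positions) == {10, 12, 13, 14, 15}

    def test_invalid_nucleotide_rejected(self, model, rrm1):
        with pytest.raises(InputError):
            score_window(model, rrm1, "ACGTT", fixtures.SLOT_MAP_5)


class TestScanAndRank:
    def test_scan_window_count_and_order(self, model, rrm2):
        hits = scan_rna(model, rrm2, "UUGUUAGUUACCCCUU", 5, fixtures.SLOT_MAP_5)
        assert len(hits) == 12
        assert [h.start for h in hits] == list(range(1, 13))

    def test_scan_shorter_than_k_is_empty(self, model, rrm2):
        assert scan_rna(model, rrm2, "ACG", 5, fixtures.SLOT_MAP_5) == []

    def test_scan_best_matches_rank_restricted_to_substrings(self, model, rrm1):
        rna = "UUGUUAGUUACCCCUU"
        scanned = scan_rna(model, rrm1, rna, 3, fixtures.SLOT_MAP_3)
        best_scan = max(h.score for h in scanned)
        substrings = {rna[i : i + 3] for i in range(len(rna) - 2)}
        ranked = rank_motifs(model, rrm1, 3, slot_map=fixtures.SLOT_MAP_3)
        best_rank = max(m.score for m in ranked if m.window in substrings)
        assert best_scan == pytest.approx(best_rank, abs=1e-12)

    def test_rank_k1_orders_single_position(self):
        m = PropensityModel({(1, "R"): [0.1, 0.4, 0.3, 0.2]}, alpha=1.0)
        prof = build_profile("R", {1: 1})
        ranked = rank_motifs(m, prof, 1, slot_map={1: 0})
        assert [r.window for r in ranked] == ["C", "G", "U", "A"]

    def test_rank_agrees_with_enumeration_oracle(self, model, rrm2):
        """k=3 exhaustive ranking equals a naive enumerate-and-sort."""
        ranked = rank_motifs(model, rrm2, 3, slot_map=fixtures.SLOT_MAP_3)
        naive = sorted(
            (
                (w, oracle_score(model, rrm2, w, fixtures.SLOT_MAP_3))
                for w in ("".join(t) for t in itertools.product(RNA_ALPHABET, repeat=3))
            ),
            key=lambda ws: (-round(ws[1], 12), ws[0]),
        )
        assert [m.window for m in ranked] == [w for w, _ in naive]

    def test_constraint_slot_out_of_window(self, model, rrm2):
        with pytest.raises(InputError):
            rank_motifs(model, rrm2, 3, {5: "U"}, fixtures.SLOT_MAP_3)


class TestDesign:
    def test_identical_profiles_give_zero_objective(self, model, rrm2):
        res = design_rna_switch(model, rrm2, rrm2, 3, slot_map=fixtures.SLOT_MAP_3)
        assert all(c.objective == pytest.approx(0.0, abs=1e-12) for c in res.candidates)
        assert [c.window for c in res.candidates] == sorted(c.window for c in res.candidates)

    def test_switch_objective_matches_independent_scores(self, model, rrm1, rrm2):
        res = design_rna_switch(model, rrm1, rrm2, 5, slot_map=fixtures.SLOT_MAP_5)
        for c in res.candidates[:50]:
            s_on = score_window(model, rrm2, c.window, fixtures.SLOT_MAP_5).score
            s_off = score_window(model, rrm1, c.window, fixtures.SLOT_MAP_5).score
            assert c.objective == pytest.approx(s_on - s_off, abs=1e-9)

    def test_unreachable_floor_returns_diagnostic(self, model, rrm1, rrm2):
        res = design_rna_switch(
            model, rrm1, rrm2, 3, slot_map=fixtures.SLOT_MAP_3, floor=1e6
        )
        assert not res and "floor" in res.message

    def test_protein_switch_matches_enumeration(self, model, rrm2):
        res = design_protein_switch(model, rrm2, 11, on_nt="C", off_nt="U")
        naive = sorted(
            AMINO_ACIDS,
            key=lambda r: (model.prob(11, r, "U"), -model.prob(11, r, "C"), r),
        )
        assert [c.residue for c in res.candidates] == naive
        assert any(c.is_reference and c.residue == "E" for c in res.candidates)

    def test_protein_switch_locality(self, model, rrm2):
        """Substituting one position changes only that position's addend."""
        mutant = rrm2.with_substitution(180, "N")
        for w in ("CUAGG", "CCAGG"):
            before = dict(score_window(model, rrm2, w, fixtures.SLOT_MAP_5).contributions)
            after = dict(score_window(model, mutant, w, fixtures.SLOT_MAP_5).contributions)
            for pos in before:
                if pos == fixtures.E180_MASTER_POSITION:
                    continue
                assert after[pos] == before[pos]

    def test_position_missing_from_profile(self, model):
        prof = build_profile("R", {11: 1})
        with pytest.raises(InputError, match="13"):
            design_protein_switch(model, prof, 13, "C", "U")


class TestStudyDesignOutcomes:
    """The packaged synthetic model reproduces the study's qualitative picks."""

    def test_uag_is_top_3mer_for_both_domains(self, model, rrm1, rrm2):
        for prof in (rrm1, rrm2):
            ranked = rank_motifs(model, prof, 3, slot_map=fixtures.SLOT_MAP_3)
            assert ranked[0].window == "UAG"

    def test_top_constrained_5mers(self, model, rrm1, rrm2):
        """N-UAG-N search: CUAGU for RRM1-like, CUAGG for RRM2-like."""
        c = {1: "U", 2: "A", 3: "G"}
        assert rank_motifs(model, rrm1, 5, c, fixtures.SLOT_MAP_5)[0].window == "CUAGU"
        assert rank_motifs(model, rrm2, 5, c, fixtures.SLOT_MAP_5)[0].window == "CUAGG"

    def test_cag_switch_motifs_beat_uag(self, model, rrm1, rrm2):
        res = design_rna_switch(model, rrm1, rrm2, 5, slot_map=fixtures.SLOT_MAP_5)
        order = [c.window for c in res.candidates]
        assert order[:2] == ["CCAGG", "GCAGG"]
        first_uag = next(i for i, w in enumerate(order) if "UAG" in w)
        assert first_uag > order.index("GCAGG")

    def test_e180n_and_k182m_top_substitutions(self, model, rrm2):
        top180 = design_protein_switch(model, rrm2, 11, "C", "U").candidates[0]
        top182 = design_protein_switch(model, rrm2, 12, "C", "U").candidates[0]
        assert (top180.residue, top182.residue) == ("N", "M")

    def test_scan_places_best_core_window_on_uag_site(self, model, rrm2):
        """On the single-site oligo the best 3-mer window sits on the UAG of
        its GUUAGU consensus site (positions 5-7)."""
        hits = scan_rna(model, rrm2, "UUGUUAGUUACCCCUU", 3, fixtures.SLOT_MAP_3)
        best = max(hits, key=lambda h: h.score)
        assert (best.start, best.window) == (5, "UAG")


@settings(max_examples=40, deadline=None)
@given(
    counts=st.lists(
        st.tuples(st.integers(0, 3), st.integers(0, 50)), min_size=1, max_size=8
    ),
    alpha=st.floats(0.01, 10.0),
)
def test_training_normalisation_property(counts, alpha):
    """Trained vectors always sum to 1 regardless of counts and alpha."""
    contacts = [
        rec(pos, "R", RNA_ALPHABET[nt_idx], cid=f"c{i}")
        for i, (nt_idx, n) in enumerate(counts)
        for pos in [i % 3]
        for _ in range(n % 5 + 1)
    ]
    m = train_propensities(contacts, alpha=alpha)
    for v in m.entries.values():
        assert abs(v.sum() - 1.0) < 1e-9
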