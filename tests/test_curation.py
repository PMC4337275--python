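"""Diagnostic-motif curation: alignment anchoring, screening, filtering."""

import random
from functools import lru_cache

import pytest

from portrace.curation import (
    ReferenceAnchor,
    align_to_reference,
    apply_curation,
    pairwise_identity,
    screen_motifs,
)
from portrace.records import AMINO_ACIDS, ConfigurationError, InputError, SequenceRecord


def linear_alignment_oracle(a: str, b: str, match=1.0, mismatch=-1.0, gap=-1.0):
    """Exhaustive optimum over all monotone alignments (linear gap cost)."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            options.append(s + best(i + 1, j + 1))
        if i < len(a):
            options.append(gap + best(i + 1, j))
        if j < len(b):
            options.append(gap + best(i, j + 1))
        return max(options)

    return best(0, 0)


class TestAlignToReference:
    def test_self_alignment_is_identity(self, toy_anchor, unit_matrix):
        ref = toy_anchor.reference.residues
        pair = align_to_reference(ref, toy_anchor, unit_matrix, -1, -1)
        assert pair.score == float(len(ref))
        assert pair.column_map == {i: i for i in range(1, len(ref) + 1)}

    def test_known_small_example(self, unit_matrix):
        pair = align_to_reference("ACD", "AD", unit_matrix, -1, -1)
        assert pair.score == 1.0  # +1 -1 +1 for A-D vs ACD
        assert pair.query_aligned.replace("-", "") == "ACD"
        assert pair.reference_aligned.replace("-", "") == "AD"

    def test_column_map_strictly_increasing(self, unit_matrix):
        pair = align_to_reference("ACDEFGHIK", "ADEGIK", unit_matrix, -1, -1)
        ref_cols = sorted(pair.column_map)
        query_cols = [pair.column_map[r] for r in ref_cols]
        assert query_cols == sorted(query_cols)
        assert len(set(query_cols)) == len(query_cols)

    def test_matches_enumeration_oracle_on_random_pairs(self, unit_matrix):
        rng = random.Random(42)
        for _ in range(100):
            a = "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(1, 8)))
            b = "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(1, 8)))
            got = align_to_reference(a, b, unit_matrix, -1, -1).score
            assert got == pytest.approx(linear_alignment_oracle(a, b))

    def test_rejects_bad_characters(self, toy_anchor, unit_matrix):
        with pytest.raises(InputError, match="B"):
            align_to_reference("ABD", toy_anchor, unit_matrix, -1, -1)


class TestScreenMotifs:
    def test_reference_screens_as_accept(self, toy_anchor):
        rep = screen_motifs(toy_anchor.reference, toy_anchor)
        assert rep.verdict == "accept"
        assert rep.rossman.position == toy_anchor.rossman_start
        assert rep.yk.tyr_position == toy_anchor.tyr_pos
        assert rep.yk.lys_position == toy_anchor.lys_pos
        assert rep.cys.position == toy_anchor.cys_pos
        assert not rep.n_truncated

    def test_broken_catalytic_cysteine_rejects(self, toy_anchor):
        seq = list(toy_anchor.reference.residues)
        seq[toy_anchor.cys_pos - 1] = "S"
        rep = screen_motifs("".join(seq), toy_anchor)
        assert not rep.cys.found
        assert rep.verdict == "reject"

    def test_n_terminal_fragment_is_rescued(self, toy_anchor):
        # remove everything through the Rossman region; Y-x-x-x-K and C intact
        fragment = toy_anchor.reference.residues[30:]
        rep = screen_motifs(fragment, toy_anchor)
        assert rep.n_truncated
        assert rep.yk.found and rep.cys.found
        assert rep.verdict == "accept_fragment"

    def test_accept_reports_literal_residues(self, toy_anchor, labelled_family):
        for rec in labelled_family.records:
            rep = screen_motifs(rec, labelled_family.anchor)
            if rep.verdict != "accept":
                continue
            q = rec.residues
            assert q[rep.cys.position - 1] == "C"
            assert q[rep.yk.tyr_position - 1] == "Y"
            assert q[rep.yk.lys_position - 1] == "K"
            assert rep.yk.lys_position - rep.yk.tyr_position == 4

    def test_verdict_invariant_under_c_terminal_extension(self, toy_anchor):
        # a poorly conserved C-terminal extension (POR2-style) must not
        # change the screening outcome
        base = toy_anchor.reference.residues
        rng = random.Random(7)
        extension = "".join(rng.choice("ALVISPTE") for _ in range(150))
        variants = [base, base[30:]]
        seq = list(base)
        seq[toy_anchor.cys_pos - 1] = "S"
        variants.append("".join(seq))
        for variant in variants:
            plain = screen_motifs(variant, toy_anchor)
            extended = screen_motifs(variant + extension, toy_anchor)
            assert plain.verdict == extended.verdict

    def test_x_never_satisfies_a_motif_position(self, toy_anchor):
        seq = list(toy_anchor.reference.residues)
        seq[toy_anchor.cys_pos - 1] = "X"
        rep = screen_motifs("".join(seq), toy_anchor)
        assert not rep.cys.found
        assert rep.verdict == "reject"

    def test_anchor_positions_validated(self):
        ref = SequenceRecord(id="r", residues="GAAAGAG" + "YAAAK" + "C")
        with pytest.raises(ConfigurationError):
            ReferenceAnchor(ref, 1, 8, 12, 99)


class TestApplyCuration:
    def test_exact_duplicate_removed(self, toy_anchor):
        ref = toy_anchor.reference.residues
        a = SequenceRecord(id="a", residues=ref, taxon_name="t1")
        b = SequenceRecord(id="b", residues=ref, taxon_name="t1")
        accepted, rejected = apply_curation([a, b], toy_anchor, min_length=10)
        assert [r.seq_id for r in accepted] == ["a"]
        assert [(r.report.seq_id, r.reason) for r in rejected] == [("b", "duplicate")]

    def test_same_sequence_different_taxa_both_kept(self, toy_anchor):
        ref = toy_anchor.reference.residues
        a = SequenceRecord(id="a", residues=ref, taxon_name="t1")
        b = SequenceRecord(id="b", residues=ref, taxon_name="t2")
        accepted, _ = apply_curation([a, b], toy_anchor, min_length=10)
        assert {r.seq_id for r in accepted} == {"a", "b"}

    def test_short_sequence_rejected_at_boundary(self, toy_anchor):
        ref = toy_anchor.reference.residues
        rec = SequenceRecord(id="a", residues=ref)
        accepted, rejected = apply_curation(
            [rec], toy_anchor, min_length=len(ref) + 1
        )
        assert not accepted
        assert rejected[0].reason == "too_short"

    def test_undetermined_heavy_sequence_rejected(self, toy_anchor):
        seq = list(toy_anchor.reference.residues)
        for i in range(64, 80):
            seq[i] = "X"
        rec = SequenceRecord(id="a", residues="".join(seq))
        _, rejected = apply_curation(
            [rec], toy_anchor, min_length=10, max_unknown_fraction=0.05
        )
        assert rejected[0].reason == "too_many_X"

    def test_synthetic_family_separation(self, labelled_family):
        accepted, rejected = apply_curation(
            labelled_family.records, labelled_family.anchor,
            min_length=150, max_unknown_fraction=0.05, dedup_identity=0.999,
        )
        truth = labelled_family.truth.labels
        accepted_ids = {r.seq_id for r in accepted}
        for seq_id, label in truth.items():
            if label in ("por_true", "fragment"):
                assert seq_id in accepted_ids, seq_id
            else:
                assert seq_id not in accepted_ids, seq_id

    def test_idempotent_on_accepted_set(self, labelled_family):
        records = labelled_family.records
        accepted, _ = apply_curation(
            records, labelled_family.anchor, dedup_identity=0.999
        )
        keep = {r.seq_id for r in accepted}
        survivors = [r for r in records if r.id in keep]
        again, rejected = apply_curation(
            survivors, labelled_family.anchor, dedup_identity=0.999
        )
        assert {r.seq_id for r in again} == keep
        assert not rejected

    def test_empty_input_is_fine(self, toy_anchor):
        accepted, rejected = apply_curation([], toy_anchor)
        assert accepted == [] and rejected == []


def test_pairwise_identity_of_identical_sequences(toy_anchor, unit_matrix):
    ref = toy_anchor.reference.residues
    assert pairwise_identity(ref, ref, unit_matrix, -1, -1) == pytest.approx(1.0)
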