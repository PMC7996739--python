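from __future__ import annotations

import numpy as np
import pytest

import mirscout.structure as structure
from mirscout.config import Thresholds
from mirscout.formats_io import StockholmAlignment, reverse_complement
from mirscout.structure import (
    FoldResult,
    check_arm_consistency,
    consensus_with_candidate,
    dotbracket_to_tree,
    evaluate_candidate,
    fold_mfe,
    hairpin_loops,
    pair_table,
    set_fold_engine,
    structure_distance,
    tree_edit_distance,
)

from ._ted_oracle import all_balanced_strings, oracle_distance, random_tree


class TestFolding:
    def test_simple_hairpin_folds_as_expected(self):
        fold = fold_mfe("GGGGAAAACCCC")
        assert fold.dotbracket == "((((....))))"
        assert fold.mfe < 0

    def test_homopolymer_cannot_pair(self):
        fold = fold_mfe("AAAAAAAAAA")
        assert fold.dotbracket == "." * 10
        assert fold.mfe == 0.0

    def test_reverse_complement_folds_to_mirrored_structure(self):
        seq = "GGGGAAAACCCC"
        mirrored = fold_mfe(reverse_complement(seq.replace("U", "T")))
        assert mirrored.dotbracket == "((((....))))"

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="short"):
            fold_mfe("ACGUA")

    def test_engine_is_pluggable(self):
        try:
            set_fold_engine(lambda seq: ("." * len(seq), -1.5))
            fold = fold_mfe("GGGGAAAACCCC")
            assert fold == FoldResult("." * 12, -1.5)
        finally:
            set_fold_engine(None)


class TestDotbracketUtilities:
    def test_pair_table_and_unbalanced_errors(self):
        assert pair_table("(.)") == [2, -1, 0]
        with pytest.raises(ValueError, match="position 0"):
            pair_table(")..")
        with pytest.raises(ValueError):
            pair_table("(..")

    @pytest.mark.parametrize(
        "db, loops",
        [
            ("((((....))))", [(4, 8)]),
            ("((..))((..))", [(2, 4), (8, 10)]),
            ("........", []),
        ],
    )
    def test_hairpin_loop_detection(self, db, loops):
        assert hairpin_loops(db) == loops


class TestStructureTree:
    @pytest.mark.parametrize(
        "db, rep",
        [
            ("()", "R(P)"),
            ("(.)", "R(P(U))"),
            (".().", "R(U,P,U)"),
            ("(())", "R(P(P))"),
        ],
    )
    def test_encoding(self, db, rep):
        assert repr(dotbracket_to_tree(db)) == rep

    def test_unbalanced_input_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            dotbracket_to_tree("()(")
        with pytest.raises(ValueError, match="position 2"):
            dotbracket_to_tree("..)")

    def test_leaf_and_pair_count_covers_sequence(self):
        db = "((..))..(.)"
        tree = dotbracket_to_tree(db)
        n_pairs = db.count("(")
        n_unpaired = db.count(".")
        assert tree.size() == 1 + n_pairs + n_unpaired


class TestTreeEditDistance:
    def test_identity_and_single_deletion(self):
        assert structure_distance("(((...)))", "(((...)))") == 0
        assert structure_distance("(.)", "()") == 1

    def test_exhaustive_agreement_with_oracle_on_small_structures(self):
        strings = all_balanced_strings(4)
        trees = [dotbracket_to_tree(s) for s in strings]
        for i, t1 in enumerate(trees):
            for t2 in trees[i:]:
                assert tree_edit_distance(t1, t2) == oracle_distance(t1, t2)

    def test_random_trees_agree_with_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(150):
            t1 = random_tree(rng, int(rng.integers(1, 13)))
            t2 = random_tree(rng, int(rng.integers(1, 13)))
            assert tree_edit_distance(t1, t2) == oracle_distance(t1, t2)

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            a, b, c = (random_tree(rng, int(rng.integers(1, 11))) for _ in range(3))
            dab = tree_edit_distance(a, b)
            assert dab == tree_edit_distance(b, a)
            assert tree_edit_distance(a, a) == 0
            assert dab <= tree_edit_distance(a, c) + tree_edit_distance(c, b)


class TestArmConsistency:
    def test_canonical_stem_loop_is_valid(self):
        db = "((((((((((....))))))))))"
        assert check_arm_consistency((0, 8), (16, 24), db) == "valid"

    def test_mature_centered_on_loop(self):
        db = "((((((((((........))))))))))"
        assert check_arm_consistency((8, 20), (21, 27), db) == "loop_overlap"

    def test_branched_structure_between_arms_is_multiloop(self):
        db = "((((..))))((((..))))"
        assert check_arm_consistency((0, 4), (16, 20), db) == "multiloop"

    def test_both_matures_on_one_arm(self):
        db = "((((((((((....))))))))))"
        assert check_arm_consistency((0, 4), (5, 9), db) == "same_arm"

    def test_flanking_structure_does_not_disqualify(self):
        # small extra hairpin in the 5' flank, matures on the main stem
        db = "((..))..((((((((....))))))))"
        assert check_arm_consistency((8, 14), (22, 28), db) == "valid"


class TestConsensusComparison:
    def test_duplicate_member_changes_nothing(self, hairpin_and_family):
        _, family = hairpin_and_family
        aln = family.precursor_alignment
        member = next(iter(aln.rows.values())).replace("-", "")
        css_default, css_with = consensus_with_candidate(aln, member)
        assert css_with == css_default
        assert structure_distance(css_default, css_with) == 0

    def test_anti_complementary_candidate_breaks_the_consensus(self, hairpin_and_family):
        hairpin, family = hairpin_and_family
        # purine-only candidate: cannot form any Watson-Crick/GU pair pattern
        candidate = "A" * len(hairpin.sequence)
        css_default, css_with = consensus_with_candidate(
            family.precursor_alignment, candidate
        )
        assert structure_distance(css_default, css_with) > 7

    def test_empty_alignment_is_an_error(self):
        aln = StockholmAlignment("empty", {}, "")
        with pytest.raises(ValueError, match="empty"):
            consensus_with_candidate(aln, "ACGU" * 10)


class TestEvaluation:
    def _placement(self, family):
        from mirscout.mature import locate_mature

        member = next(iter(family.precursor_alignment.rows.values())).replace("-", "")
        return member, locate_mature(member, family)

    def test_overlong_precursor_discarded(self, hairpin_and_family):
        _, family = hairpin_and_family
        member, placement = self._placement(family)
        result = evaluate_candidate(member + "A" * 200, placement, family.precursor_alignment)
        assert result.final_status == "discarded" and result.reject_reason == "length"

    def test_weak_fold_discarded_at_mfe_boundary(self, hairpin_and_family):
        _, family = hairpin_and_family
        member, placement = self._placement(family)
        db = fold_mfe(member).dotbracket
        try:
            set_fold_engine(lambda seq: (db, -9.5))
            result = evaluate_candidate(member, placement, family.precursor_alignment)
            assert result.final_status == "discarded" and result.reject_reason == "mfe"
            set_fold_engine(lambda seq: (db, -10.0))
            result = evaluate_candidate(member, placement, family.precursor_alignment)
            assert result.final_status == "accepted"  # <= -10 is inclusive
        finally:
            set_fold_engine(None)

    def test_missing_placement_is_no_mature_anchor(self, hairpin_and_family):
        _, family = hairpin_and_family
        member, _ = self._placement(family)
        result = evaluate_candidate(member, None, family.precursor_alignment)
        assert result.final_status == "discarded"
        assert result.reject_reason == "no mature anchor"

    @pytest.mark.parametrize("ted, expected", [(7, "High"), (8, "Medium")])
    def test_confidence_boundary_at_ted_seven(
        self, monkeypatch, hairpin_and_family, ted, expected
    ):
        _, family = hairpin_and_family
        member, placement = self._placement(family)
        css = "(((((...)))))" + "." * 10
        monkeypatch.setattr(
            structure,
            "consensus_with_candidate",
            lambda aln, cand, thr=None: (css, css[: len(css) - ted]),
        )
        result = evaluate_candidate(member, placement, family.precursor_alignment)
        assert result.final_status == "accepted"
        assert result.ted == ted
        assert result.confidence == expected

    def test_true_family_member_is_high_confidence(self, hairpin_and_family):
        hairpin, family = hairpin_and_family
        placement_seq = hairpin.sequence.replace("T", "U")
        from mirscout.mature import locate_mature

        placement = locate_mature(placement_seq, family)
        result = evaluate_candidate(placement_seq, placement, family.precursor_alignment)
        assert result.final_status == "accepted"
        assert result.confidence == "High"
        assert result.ted == 0
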