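"""Direct optimization: pairwise DP, tree costs vs the exact oracle,
implied alignments, combined scoring."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import QuartetTreeAlignmentOracle, enumerate_pairwise_cost
from rnaphylo import trees
from rnaphylo.alignments import FragmentSet
from rnaphylo.annotation import classify_regions
from rnaphylo.direct_opt import (CostRegime, DoScore, combined_score,
                                 implied_alignment, mask_to_states,
                                 morphology_weight, pairwise_do_cost,
                                 rescore_implied, tree_do_cost)
from rnaphylo.partitions import build_partitions

R111 = CostRegime.from_label("111")
R121 = CostRegime.from_label("121")


class TestCostRegime:
    def test_label_digits_in_printed_order(self):
        r = CostRegime.from_label("412")
        assert (r.gap_extension, r.transversion, r.transition) == (4, 1, 2)

    def test_bad_labels_rejected(self):
        for bad in ("41", "4121", "ab1", "101"):
            with pytest.raises(ValueError):
                CostRegime.from_label(bad)


class TestPairwise:
    def test_single_indel(self):
        cost, trace, median = pairwise_do_cost("AC", "AGC", R111)
        assert cost == 1
        assert [sorted(mask_to_states(m)) for m in median] == \
            [["A"], ["-", "G"], ["C"]]

    def test_substitution_classes(self):
        assert pairwise_do_cost("A", "G", R121)[0] == 1  # transition
        assert pairwise_do_cost("A", "C", R121)[0] == 2  # transversion

    def test_identical_sequences_cost_zero(self):
        for regime in (R111, R121, CostRegime.from_label("421")):
            assert pairwise_do_cost("ACGUACGU", "ACGUACGU", regime)[0] == 0

    def test_ambiguity_codes_cost_minimum_over_members(self):
        # R = {A, G}: against G a transition is avoidable
        assert pairwise_do_cost("R", "G", R121)[0] == 0

    def test_empty_sequences(self):
        assert pairwise_do_cost("", "ACG", R111)[0] == 3
        assert pairwise_do_cost("", "", R111)[0] == 0

    @settings(deadline=None, max_examples=60)
    @given(st.text(alphabet="ACGU", max_size=5),
           st.text(alphabet="ACGU", max_size=5),
           st.sampled_from(["111", "121", "211", "412"]))
    def test_dp_equals_alignment_enumeration(self, a, b, label):
        regime = CostRegime.from_label(label)
        expected = enumerate_pairwise_cost(
            a, b, regime.gap_extension, regime.transversion,
            regime.transition)
        assert pairwise_do_cost(a, b, regime)[0] == expected


class TestTreeDo:
    def test_two_leaf_tree_equals_pairwise(self):
        tree = trees.from_newick("(x,y);")
        frag = FragmentSet("f", {"x": "ACGUA", "y": "AGUA"})
        assert tree_do_cost(tree, frag, R111) == \
            pairwise_do_cost("ACGUA", "AGUA", R111)[0]

    def test_single_scoped_taxon_costs_zero(self, quartet):
        frag = FragmentSet("f", {"a": "ACGU"}, frozenset(["a"]))
        assert tree_do_cost(quartet, frag, R111) == 0.0

    def test_out_of_scope_leaves_ignored(self, quartet):
        frag = FragmentSet("f", {"a": "ACG", "b": "ACG"},
                           frozenset(["a", "b"]))
        assert tree_do_cost(quartet, frag, R111) == 0.0

    def test_oracle_bracket_on_random_quartets(self, rng):
        """Heuristic cost equals the exact tree alignment on >= 90% of 100
        random 4-leaf toys and never beats it."""
        oracle = QuartetTreeAlignmentOracle(1, 1, 1)
        tree = trees.from_newick("((a,b),(c,d));")
        hits = 0
        for _ in range(100):
            leaves = ["".join(rng.choice(list("ACGU"),
                                         size=rng.integers(0, 4)))
                      for _ in range(4)]
            frag = FragmentSet("f", dict(zip("abcd", leaves)))
            h = tree_do_cost(tree, frag, R111)
            e = oracle.exact_cost(leaves)
            assert h >= e - 1e-9  # an upper-bound heuristic by construction
            hits += abs(h - e) < 1e-9
        assert hits >= 90

    def test_leaf_order_permutation_invariance(self):
        frag = FragmentSet("f", {"a": "ACGU", "b": "ACG", "c": "AAGU",
                                 "d": "ACGUU"})
        t1 = trees.from_newick("((a,b),(c,d));")
        t2 = trees.from_newick("((d,c),(b,a));")
        assert tree_do_cost(t1, frag, R111) == tree_do_cost(t2, frag, R111)

    def test_linear_cost_scaling(self):
        frag = FragmentSet("f", {"a": "ACGU", "b": "ACG", "c": "AAGU",
                                 "d": "ACGUU"})
        tree = trees.from_newick("((a,b),(c,d));")
        r333 = CostRegime(3, 3, 3, "333")
        assert tree_do_cost(tree, frag, r333) == \
            pytest.approx(3 * tree_do_cost(tree, frag, R111))


class TestImpliedAlignment:
    def test_identical_sequences_gapless(self, quartet):
        frag = FragmentSet("f", {t: "ACGU" for t in "abcd"})
        ia = implied_alignment(quartet, frag, R111)
        assert ia.columns == 4
        assert all("-" not in row for row in ia.as_strings().values())

    def test_indel_toy_one_gap_column(self):
        tree = trees.from_newick("(x,y);")
        frag = FragmentSet("f", {"x": "AC", "y": "AGC"})
        ia = implied_alignment(tree, frag, R111)
        assert ia.columns == 3
        assert ia.as_strings()["x"].count("-") == 1

    def test_rescoring_reproduces_do_cost(self, rng):
        """Scoring the implied alignment statically on the same tree gives
        exactly the reported fragment cost."""
        tree = trees.from_newick("((a,b),(c,d),e);")
        for _ in range(10):
            frag = FragmentSet("f", {
                t: "".join(rng.choice(list("ACGU"),
                                      size=rng.integers(0, 6)))
                for t in "abcde"})
            for regime in (R111, R121):
                ia = implied_alignment(tree, frag, regime)
                assert rescore_implied(tree, ia, regime) == \
                    pytest.approx(tree_do_cost(tree, frag, regime))


class TestCombined:
    def test_constrained_without_fragments_reduces_to_static(self, toy_alignment):
        ann = classify_regions(toy_alignment)
        parts = build_partitions(toy_alignment, ann, "constrained_do")
        parts.do_fragments = []
        tree = trees.from_newick("((a,b),(c,d));")
        from rnaphylo.parsimony import fitch_length, matrix_from_alignment
        static = matrix_from_alignment(toy_alignment, parts.static_columns)
        score = combined_score(tree, parts, R111)
        assert score.total == fitch_length(tree, static)

    def test_component_bookkeeping(self, toy_alignment):
        ann = classify_regions(toy_alignment)
        parts = build_partitions(toy_alignment, ann, "constrained_do")
        tree = trees.from_newick("((a,b),(c,d));")
        score = combined_score(tree, parts, R111)
        parts_sum = (sum(score.fragment_costs.values()) + score.static_cost
                     + score.structure_cost
                     + score.morphology_cost * score.morphology_weight)
        assert score.total == parts_sum
        frag = parts.do_fragments[0]
        assert score.fragment_costs[frag.name] == \
            tree_do_cost(tree, frag, R111)

    def test_regime_required_for_fragments(self, toy_alignment):
        ann = classify_regions(toy_alignment)
        parts = build_partitions(toy_alignment, ann, "constrained_do")
        tree = trees.from_newick("((a,b),(c,d));")
        with pytest.raises(ValueError, match="regime"):
            combined_score(tree, parts, None)


class TestMorphWeight:
    def test_self_ratio_is_one(self):
        assert morphology_weight(10_000, 10_000) == 1.0

    def test_ratio_arithmetic(self):
        assert morphology_weight(12_000, 10_000) == pytest.approx(1.2)

    def test_weight_multiplies_through_combined_score(self):
        s = DoScore(morphology_cost=10.0, morphology_weight=1.2)
        assert s.total == pytest.approx(12.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            morphology_weight(5.0, 0.0)
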