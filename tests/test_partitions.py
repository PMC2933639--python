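"""Partition assembly, splicing, region splitting and summary statistics."""
import numpy as np
import pytest

from rnaphylo.alignments import FragmentSet, StructuredAlignment
from rnaphylo.annotation import classify_regions, lump_terminal_raa
from rnaphylo.partitions import (build_partitions, residue_conservation_check,
                                 split_region_with_core, splice_at_anchors,
                                 summarize_alignment)
from rnaphylo.synthetic import SimulationConfig, simulate_dataset


def _toy():
    """10 PRE columns (4 paired) followed by a 3-column unpaired RAA."""
    seqs = {"a": "GGAUAAAUCCAAA", "b": "GGAUAAAUCCAAC",
            "c": "GGAUAAAUCC-AA", "d": "GGAUAAAUCCAAA"}
    mask = "((......))***"
    return StructuredAlignment(sorted(seqs), seqs, mask, [""] * 13)


class TestBuildPartitions:
    def test_constrained_splits_static_and_fragments(self):
        aln = _toy()
        ann = classify_regions(aln)
        parts = build_partitions(aln, ann, "constrained_do")
        assert len(parts.static_stem_columns) == 4
        assert len(parts.static_loop_columns) == 6
        assert len(parts.do_fragments) == 1
        # fragment rows are gap-stripped
        assert parts.do_fragments[0].sequences["c"] == "AA"

    def test_traditional_discards_ambiguous_regions(self):
        aln = _toy()
        parts = build_partitions(aln, classify_regions(aln), "traditional")
        assert parts.do_fragments == []
        assert len(parts.static_columns) == 10

    def test_bayesian_static_sets_match_traditional(self):
        aln = _toy()
        ann = classify_regions(aln)
        trad = build_partitions(aln, ann, "traditional")
        bayes = build_partitions(aln, ann, "bayesian")
        assert trad.static_stem_columns == bayes.static_stem_columns
        assert trad.static_loop_columns == bayes.static_loop_columns

    def test_standard_do_has_no_static_columns(self):
        aln = _toy()
        parts = build_partitions(aln, classify_regions(aln), "standard_do")
        assert parts.static_columns == []
        assert len(parts.do_fragments) >= 1

    def test_residue_conservation(self):
        ds = simulate_dataset(SimulationConfig(seed=4, n_taxa=8))
        aln = ds.alignment
        ann = lump_terminal_raa(aln, classify_regions(aln))
        parts = build_partitions(aln, ann, "constrained_do")
        assert residue_conservation_check(aln, parts, ann)


class TestSplicing:
    def test_k_anchors_give_k_plus_one_blocks(self):
        seqs = {"a": "AAAACGCGCGCGUUUU", "b": "AACGCGCGCGUU",
                "c": "AAAAACGCGCGCGU"}
        blocks = splice_at_anchors(seqs, ["CGCGCGCG"])
        assert len(blocks) == 2
        assert blocks[1].sequences["a"].startswith("CGCGCGCG")

    def test_no_anchors_single_block(self):
        blocks = splice_at_anchors({"a": "ACGU"}, [])
        assert len(blocks) == 1 and blocks[0].sequences["a"] == "ACGU"

    def test_motif_at_start_gives_empty_first_block(self):
        blocks = splice_at_anchors({"a": "CGCGCGCGAA"}, ["CGCGCGCG"])
        assert blocks[0].sequences["a"] == ""

    def test_absent_or_repeated_motif_names_taxon(self):
        with pytest.raises(ValueError, match="bb"):
            splice_at_anchors({"aa": "AACGCGCGCGAA", "bb": "AAAA"},
                              ["CGCGCGCG"])

    def test_short_motif_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            splice_at_anchors({"a": "ACGUACGU"}, ["ACG"])

    def test_coordinate_spec(self):
        blocks = splice_at_anchors({"a": "AAACCC", "b": "AACC"},
                                   {"a": [3], "b": [2]})
        assert blocks[0].sequences == {"a": "AAA", "b": "AA"}
        assert blocks[1].sequences == {"a": "CCC", "b": "CC"}


class TestRegionCoreSplit:
    def _aln(self):
        #          0123456789
        seqs = {"sc1": "AAGGCCCCUU",   # possesses the core helix (cols 2-7)
                "sc2": "ACGGCCCCUA",
                "ac1": "AA------UU",   # acariform-like: no helix
                "ac2": "AC------CA"}
        mask = "..((..)).."
        return StructuredAlignment(sorted(seqs), seqs, mask, [""] * 10)

    def test_scoped_taxa_get_three_pieces(self):
        aln = self._aln()
        core, frags = split_region_with_core(aln, 0, 10, range(2, 8),
                                             ["sc1", "sc2"])
        assert core is not None and core.taxa == ["sc1", "sc2"]
        assert core.n_columns == 6
        left, right = frags
        assert left.sequences["sc1"] == "AA"
        assert right.sequences["sc1"] == "UU"
        # helixless taxa route the whole region to the DO fragment
        assert left.sequences["ac1"] == "AAUU"
        assert right.sequences["ac1"] == ""

    def test_empty_core_everything_do(self):
        aln = self._aln()
        core, frags = split_region_with_core(aln, 0, 10, [], ["sc1"])
        assert core is None and len(frags) == 1

    def test_noncontiguous_core_demotes_with_warning(self):
        seqs = {"x": "AAGGACCCUU", "y": "AAGG-CCCUU"}
        aln = StructuredAlignment(["x", "y"], seqs, "." * 10, [""] * 10)
        core_cols = [2, 3, 5, 6]  # x has a residue at the skipped col 4
        with pytest.warns(UserWarning, match="demoted"):
            core, frags = split_region_with_core(aln, 0, 10, core_cols,
                                                 ["x", "y"])
        assert core is not None and core.taxa == ["y"]


class TestSummary:
    def test_counts_match_hand_example(self):
        # col0 invariant; col1 variable uninformative; col2 informative
        seqs = {"t1": "AAA", "t2": "AAA", "t3": "AAG", "t4": "AGG",
                "t5": "A-G"}
        aln = StructuredAlignment(sorted(seqs), seqs, "...", [""] * 3)
        s = summarize_alignment(aln)
        assert s.n_positions == 3
        assert s.n_conserved == 1
        assert s.n_variable == 2
        assert s.n_parsimony_informative == 1

    def test_all_gap_column_not_a_position(self):
        seqs = {"a": "A-", "b": "A-"}
        aln = StructuredAlignment(["a", "b"], seqs, "..", ["", ""])
        assert summarize_alignment(aln).n_positions == 1

    def test_gap_as_state_flag_changes_counts(self):
        seqs = {"a": "A", "b": "A", "c": "-", "d": "-"}
        aln = StructuredAlignment(sorted(seqs), seqs, ".", [""])
        assert summarize_alignment(aln).n_parsimony_informative == 0
        assert summarize_alignment(
            aln, gap_is_state=True).n_parsimony_informative == 1

    def test_empty_selection_rejected(self, toy_alignment):
        with pytest.raises(ValueError):
            summarize_alignment(toy_alignment, [])

    def test_loop_adenosine_enrichment_on_synthetic_default(self):
        ds = simulate_dataset(SimulationConfig(seed=6))
        ann = classify_regions(ds.alignment)
        from rnaphylo.annotation import PRE
        s = summarize_alignment(ds.alignment, ann.columns_of_kind(PRE))
        assert s.composition_loops["A"] > s.composition_stems["A"]
        for comp in (s.composition_overall, s.composition_stems,
                     s.composition_loops):
            assert sum(comp.values()) == pytest.approx(100.0, abs=0.1)
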