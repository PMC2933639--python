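"""Fitch scoring, tree search, fusing, and support measures."""
import math

import numpy as np
import pytest

from oracles import brute_force_fitch
from rnaphylo import trees
from rnaphylo.alignments import StructuredAlignment
from rnaphylo.parsimony import (ParsimonyMatrix, SearchConfig, bremer, ci_ri,
                                exhaustive_search, fitch_counts, fitch_length,
                                heuristic_search, jackknife,
                                matrix_from_alignment, strict_consensus,
                                tree_fuse)


def _nuc_matrix(taxa, columns):
    """columns: list of strings over ACGU-?"""
    seqs = {t: "".join(col[i] for col in columns)
            for i, t in enumerate(taxa)}
    aln = StructuredAlignment(list(taxa), seqs, "." * len(columns),
                              [""] * len(columns))
    return matrix_from_alignment(aln)


def _random_matrix(rng, n_taxa, n_cols, missing=0.1):
    taxa = [f"t{i}" for i in range(n_taxa)]
    data = (1 << rng.integers(0, 4, size=(n_taxa, n_cols))).astype(np.int64)
    miss = rng.random((n_taxa, n_cols)) < missing
    data[miss] = 31
    return ParsimonyMatrix(taxa, data, np.ones(n_cols),
                           np.full(n_cols, 31, dtype=np.int64))


class TestFitch:
    def test_grouping_column_steps(self):
        m = _nuc_matrix("abcd", ["AAGG"])
        assert fitch_length(trees.from_newick("((a,b),(c,d));"), m) == 1
        assert fitch_length(trees.from_newick("((a,c),(b,d));"), m) == 2

    def test_invariant_column_zero_steps(self):
        m = _nuc_matrix("abcd", ["AAAA"])
        for t in trees.enumerate_unrooted(list("abcd")):
            assert fitch_length(t, m) == 0

    def test_gap_fifth_state_adds_step(self):
        tree = trees.from_newick("((a,c),(b,d));")
        gap = _nuc_matrix("abcd", ["AA--"])
        nuc_only = _nuc_matrix("abcd", ["AAAA"])
        assert fitch_length(tree, gap) == 2
        assert fitch_length(tree, nuc_only) == 0

    def test_matrix_taxon_missing_from_tree_rejected(self):
        m = _nuc_matrix("abcd", ["AAGG"])
        with pytest.raises(ValueError, match="absent"):
            fitch_length(trees.from_newick("((a,b),c);"), m)

    def test_all_missing_column_never_changes_score(self, rng):
        m = _random_matrix(rng, 6, 8)
        extra = ParsimonyMatrix(m.taxa,
                                np.full((6, 1), 31, dtype=np.int64),
                                np.ones(1), np.full(1, 31, dtype=np.int64))
        both = m.concat(extra)
        for _ in range(5):
            t = trees.random_topology(m.taxa, rng)
            assert fitch_length(t, m) == fitch_length(t, both)

    def test_fitch_equals_brute_force_small_trees(self, rng):
        """Set-intersection Fitch equals exhaustive minimum labelling on
        random <= 6-taxon, 5-state (gap included) columns."""
        for rep in range(12):
            n = int(rng.integers(4, 7))
            taxa = [f"t{i}" for i in range(n)]
            tree = trees.random_topology(taxa, rng)
            states = rng.integers(0, 5, size=n)
            miss = rng.random(n) < 0.15
            column = {t: (set(range(5)) if m else {int(s)})
                      for t, s, m in zip(taxa, states, miss)}
            data = np.array([[sum(1 << s for s in column[t])] for t in taxa],
                            dtype=np.int64)
            pm = ParsimonyMatrix(taxa, data, np.ones(1),
                                 np.full(1, 31, dtype=np.int64))
            assert fitch_length(tree, pm) == brute_force_fitch(tree, column,
                                                               5)


class TestSearch:
    def test_heuristic_matches_exhaustive(self, rng):
        for rep in range(8):
            m = _random_matrix(rng, 7, 10)
            h = heuristic_search(
                m, config=SearchConfig(n_builds=3, ratchet_iterations=2),
                seed=rep)
            e = exhaustive_search(m)
            assert h.best_score == e.best_score

    def test_deterministic_under_seed(self, rng):
        m = _random_matrix(rng, 8, 15)
        r1 = heuristic_search(m, config=SearchConfig(n_builds=2), seed=42)
        r2 = heuristic_search(m, config=SearchConfig(n_builds=2), seed=42)
        assert r1.best_score == r2.best_score
        assert [trees.topology_id(t) for t in r1.trees] == \
            [trees.topology_id(t) for t in r2.trees]

    def test_ratchet_never_worsens(self, rng):
        m = _random_matrix(rng, 8, 20)
        plain = heuristic_search(m, config=SearchConfig(n_builds=1), seed=1)
        ratchet = heuristic_search(
            m, config=SearchConfig(n_builds=1, ratchet_iterations=3), seed=1)
        assert ratchet.best_score <= plain.best_score

    def test_all_optimal_topologies_share_best_score(self, rng):
        m = _random_matrix(rng, 6, 6)
        res = heuristic_search(m, config=SearchConfig(n_builds=3), seed=0)
        for t in res.trees:
            assert fitch_length(t, m) == res.best_score


class TestTreeFuse:
    def test_fusing_tree_with_itself_unchanged(self):
        m = _nuc_matrix("abcdef", ["AABBCC".replace("B", "G")
                                   .replace("C", "U")] * 3)
        t = trees.from_newick("((a,b),(c,d),(e,f));")
        res = tree_fuse([t, t], lambda x: fitch_length(x, m))
        assert res.best_score == fitch_length(t, m)
        assert trees.same_topology(res.trees[0], t)

    def test_complementary_signal_improves(self):
        """Two trees each optimal for half of the characters fuse into a
        tree at least as good as either."""
        cols = ["AAGGUU", "AAGGUU", "AGAGAG", "UUAAGG"]
        m = _nuc_matrix("abcdef", cols)
        t1 = trees.from_newick("((a,b),((c,d),(e,f)));")
        t2 = trees.from_newick("((a,c),((b,d),(e,f)));")
        score = lambda x: fitch_length(x, m)  # noqa: E731
        res = tree_fuse([t1, t2], score)
        assert res.best_score <= min(score(t1), score(t2))

    def test_leaf_set_mismatch_rejected(self):
        t1 = trees.from_newick("((a,b),(c,d));")
        t2 = trees.from_newick("((a,b),(c,e));")
        with pytest.raises(ValueError, match="mismatch"):
            tree_fuse([t1, t2], lambda x: 0.0)

    def test_subtree_exchange_finds_strictly_better_tree(self):
        """Each input tree resolves one half correctly; exchanging the
        correctly-resolved subtree yields a strictly better tree."""
        good = trees.from_newick("(((a,b),c),((d,e),f));")
        chars = ["AAGGGG", "AAAGGG", "GGGAAG", "GGGAAA"]  # support good
        m = _nuc_matrix("abcdef", chars)
        t1 = trees.from_newick("(((a,b),c),((d,f),e));")  # left half right
        t2 = trees.from_newick("(((a,c),b),((d,e),f));")  # right half right
        score = lambda x: fitch_length(x, m)  # noqa: E731
        res = tree_fuse([t1, t2], score)
        assert res.best_score < min(score(t1), score(t2))
        assert res.best_score == score(good)


class TestIndices:
    def test_homoplasy_free_matrix_ci_ri_one(self):
        m = _nuc_matrix("abcd", ["AAGG", "AAGG"])
        ci, ri = ci_ri(trees.from_newick("((a,b),(c,d));"), m)
        assert ci == 1.0 and ri == 1.0

    def test_single_column_worst_tree(self):
        m = _nuc_matrix("abcd", ["AAGG"])
        ci, ri = ci_ri(trees.from_newick("((a,c),(b,d));"), m)
        assert ci == 0.5
        assert ri == 0.0

    def test_all_invariant_degenerate_flagged_as_one(self):
        m = _nuc_matrix("abcd", ["AAAA"])
        ci, ri = ci_ri(trees.from_newick("((a,b),(c,d));"), m)
        assert ci == 1.0 and ri == 1.0


class TestSupports:
    def test_identical_trees_full_support(self, rng):
        m = _nuc_matrix("abcdef",
                        ["AAGGGG", "AAAGGG", "AAGGGG", "GGGGAA"] * 6)
        res = heuristic_search(m, config=SearchConfig(n_builds=2), seed=0)
        cons = strict_consensus(res.trees)
        supports = jackknife(m, reps=30, seed=1,
                             config=SearchConfig(n_builds=1))
        for split in trees.bipartitions(cons):
            assert supports.get(split, 0) > 50

    def test_consensus_of_conflicting_trees_is_polytomy(self):
        t1 = trees.from_newick("((a,b),(c,d));")
        t2 = trees.from_newick("((a,c),(b,d));")
        cons = strict_consensus([t1, t2])
        assert trees.bipartitions(cons, list("abcd")) == frozenset()

    def test_bremer_equals_supporting_character_count(self):
        """A clade backed by k homoplasy-free characters decays after
        exactly k extra steps."""
        k = 3
        cols = ["AAGG"] * k + ["AGAG"]  # k chars for {a,b}; one conflict
        m = _nuc_matrix("abcd", cols)
        res = exhaustive_search(m)
        decays = bremer(res.trees, m, config=SearchConfig(n_builds=2),
                        from_best=False)
        split = frozenset({"c", "d"})  # {a,b}|{c,d} normalised without 'a'
        assert decays[split] == k - 1

    def test_jackknife_requires_positive_reps(self, rng):
        m = _random_matrix(rng, 5, 5)
        with pytest.raises(ValueError):
            jackknife(m, reps=0)
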