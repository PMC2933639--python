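"""Substitution models: rate matrices, transition probabilities, parameter
bookkeeping, likelihood against exhaustive enumeration, simulation."""
import math

import numpy as np
import pytest

from oracles import enumerate_loglik, jc69_two_taxon_loglik
from rnaphylo import trees
from rnaphylo.models import (GTRIG, CANONICAL_PAIRS, Paired7A, Paired16A,
                             PartitionData, count_free_parameters,
                             encode_nucleotide_column, encode_pair_column,
                             pair16_rate_class, partitioned_loglik,
                             pruning_loglik)


def _random_gtr(rng):
    f = rng.dirichlet(np.ones(4) * 5)
    return GTRIG(exchangeabilities=tuple(0.2 + rng.random(6)),
                 frequencies=tuple(f), p_invariant=0.15, gamma_shape=0.9)


def _random_7a(rng):
    f = rng.dirichlet(np.ones(7) * 5)
    return Paired7A(exchangeabilities=tuple(0.2 + rng.random(21)),
                    frequencies=tuple(f))


def _random_16a(rng):
    f = rng.dirichlet(np.ones(16) * 5)
    return Paired16A(alpha_single=1.3, alpha_double_substitution=0.7,
                     alpha_double_transversion=0.2, kappa_to_mismatch=0.4,
                     kappa_within_mismatch=0.15, frequencies=tuple(f))


ALL_FACTORIES = [_random_gtr, _random_7a, _random_16a]


class TestRateMatrices:
    def test_pair16_rate_classes(self):
        assert pair16_rate_class("AU", "GC") == "double_substitution"
        assert pair16_rate_class("AU", "UA") == "double_transversion"
        assert pair16_rate_class("AU", "GU") == "single"
        assert pair16_rate_class("AU", "AA") == "to_mismatch"
        assert pair16_rate_class("AA", "AC") == "within_mismatch"
        assert pair16_rate_class("AA", "GC") is None  # double via mismatch

    @pytest.mark.parametrize("factory", ALL_FACTORIES)
    def test_rows_sum_to_zero_and_detailed_balance(self, factory, rng):
        m = factory(rng)
        q = m.rate_matrix()
        assert np.abs(q.sum(axis=1)).max() < 1e-12
        flux = m.freqs[:, None] * q
        assert np.abs(flux - flux.T).max() < 1e-12
        # normalised to one expected event per unit branch length
        assert -(m.freqs * np.diag(q)).sum() == pytest.approx(1.0)

    def test_bad_frequencies_rejected(self):
        with pytest.raises(ValueError):
            GTRIG(frequencies=(0.5, 0.5, 0.2, 0.2))


class TestTransitionProbabilities:
    @pytest.mark.parametrize("factory", ALL_FACTORIES)
    def test_semigroup_identity_and_ergodic_limit(self, factory, rng):
        m = factory(rng)
        assert np.abs(m.transition_probabilities(0.0)
                      - np.eye(m.n_states)).max() < 1e-12
        p1 = m.transition_probabilities(0.4)
        p2 = m.transition_probabilities(0.8)
        assert np.abs(p1 @ p1 - p2).max() < 1e-10
        plong = m.transition_probabilities(1000.0)
        assert np.abs(plong - m.freqs[None, :]).max() < 1e-6

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            GTRIG().transition_probabilities(-0.1)


class TestFreeParameters:
    def test_paired_models_printed_counts(self):
        assert count_free_parameters(Paired7A()) == 26
        assert count_free_parameters(Paired16A()) == 19

    def test_gtr_ig(self):
        # 5 exchangeabilities + 3 frequencies + p_inv + shape
        assert count_free_parameters(GTRIG()) == 10

    def test_optional_stem_rate_heterogeneity_adds_two(self):
        assert count_free_parameters(Paired7A(),
                                     with_rate_heterogeneity=True) == 28


class TestLikelihood:
    def test_jc_closed_form_two_taxa(self):
        jc = GTRIG()  # equal rates, equal frequencies = JC69
        tree = trees.from_newick("(x:0.1,y:0.1);")
        part = PartitionData(jc, {
            "x": encode_nucleotide_column(list("AAG")),
            "y": encode_nucleotide_column(list("ACG")),
        })
        expected = jc69_two_taxon_loglik(0.2, n_same=2, n_diff=1)
        assert pruning_loglik(tree, part) == pytest.approx(expected,
                                                           abs=1e-10)

    @pytest.mark.parametrize("factory", ALL_FACTORIES)
    def test_pruning_equals_enumeration(self, factory, rng):
        """Felsenstein pruning agrees with explicit summation over internal
        states on 4- and 5-taxon trees for all three model families."""
        m = factory(rng)
        for newick in ("((a:0.12,b:0.3):0.08,(c:0.25,d:0.1):0.15);",
                       "((a:0.2,b:0.1):0.1,(c:0.3,(d:0.1,e:0.2):0.1):0.2);"):
            tree = trees.from_newick(newick)
            k = m.n_states
            n_sites = 4
            partials = {}
            for leaf in tree.leaf_labels():
                rows = np.zeros((n_sites, k))
                for s in range(n_sites):
                    rows[s, rng.integers(k)] = 1.0
                partials[leaf] = rows
            partials["a"][0] = 1.0  # one fully ambiguous site
            part = PartitionData(m, partials)
            assert pruning_loglik(tree, part) == pytest.approx(
                enumerate_loglik(tree, m, partials), abs=1e-10)

    def test_all_missing_column_contributes_zero(self, rng):
        m = _random_gtr(rng)
        tree = trees.from_newick("((a:0.1,b:0.1):0.1,c:0.1);")
        part = PartitionData(m, {t: np.ones((1, 4)) for t in "abc"})
        assert pruning_loglik(tree, part) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("factory", ALL_FACTORIES)
    def test_rerooting_invariance(self, factory, rng):
        m = factory(rng)
        tree = trees.from_newick(
            "((a:0.12,b:0.3):0.08,(c:0.25,d:0.1):0.15);")
        k = m.n_states
        partials = {}
        for leaf in "abcd":
            rows = np.zeros((3, k))
            for s in range(3):
                rows[s, rng.integers(k)] = 1.0
            partials[leaf] = rows
        part = PartitionData(m, partials)
        base = pruning_loglik(tree, part)
        for leaf in "abcd":
            rerooted = trees.reroot_at_leaf_edge(tree, leaf)
            assert pruning_loglik(rerooted, part) == pytest.approx(
                base, abs=1e-9)

    def test_column_claimed_twice_rejected(self, rng):
        m = _random_gtr(rng)
        tree = trees.from_newick("((a:0.1,b:0.1):0.1,c:0.1);")
        partials = {t: np.ones((1, 4)) for t in "abc"}
        parts = [PartitionData(m, partials, column_ids=(0, 1)),
                 PartitionData(m, partials, column_ids=(1, 2))]
        with pytest.raises(ValueError, match="two partitions"):
            partitioned_loglik(tree, parts)

    def test_paired_model_beats_independent_gtr_on_wc_data(self, rng):
        """Perfect Watson-Crick covariation: a 7-state pair model fits
        better than two independent nucleotide columns."""
        tree = trees.yule_tree([f"t{i}" for i in range(8)], 1.0, rng)
        trees.scale_branches(tree, 0.3 / 1.0)
        model = Paired7A(frequencies=(0.23, 0.23, 0.23, 0.23, 0.03, 0.03,
                                      0.02))
        sim = model.simulate(tree, 500, rng)
        states = model.states
        pair7 = {t: np.eye(7)[sim[t]] for t in sim}
        l_pair = pruning_loglik(tree, PartitionData(model, pair7))
        # project onto the two nucleotide columns, fit nothing: use the
        # empirical per-position frequencies under an HKY-ish GTR
        NUC = "ACGU"
        cols = {t: [states[s] for s in sim[t]] for t in sim}
        first = {t: encode_nucleotide_column([d[0] for d in cols[t]])
                 for t in cols}
        second = {t: encode_nucleotide_column([d[1] for d in cols[t]])
                  for t in cols}
        gtr = GTRIG()
        l_indep = (pruning_loglik(tree, PartitionData(gtr, first))
                   + pruning_loglik(tree, PartitionData(gtr, second)))
        assert l_pair > l_indep


class TestSimulation:
    def test_stationary_frequencies_recovered(self, rng):
        m = GTRIG(frequencies=(0.4, 0.3, 0.2, 0.1))
        tree = trees.from_newick("(a:0.05,b:0.05);")
        sim = m.simulate(tree, 100_000, rng)
        freqs = np.bincount(sim["a"], minlength=4) / 100_000
        assert np.abs(freqs - m.freqs).max() < 0.01

    def test_zero_length_tree_copies_root(self, rng):
        m = GTRIG()
        tree = trees.from_newick("(a:0.0,b:0.0);")
        sim = m.simulate(tree, 50, rng)
        assert np.array_equal(sim["a"], sim["b"])

    def test_same_seed_same_output(self):
        m = Paired7A()
        tree = trees.from_newick("((a:0.1,b:0.1):0.1,c:0.2);")
        s1 = m.simulate(tree, 30, np.random.default_rng(5))
        s2 = m.simulate(tree, 30, np.random.default_rng(5))
        assert all(np.array_equal(s1[t], s2[t]) for t in s1)
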