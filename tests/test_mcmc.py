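"""MCMC sampling correctness, marginal-likelihood estimator, diagnostics,
and posterior summaries."""
import math

import numpy as np
import pytest

from oracles import direct_harmonic_mean_log
from rnaphylo import trees
from rnaphylo.mcmc import (McmcConfig, McmcTrace, bayes_factor,
                           consensus_and_pp, ess, gelman_diagnostic,
                           harmonic_mean_lnl, run_mcmc)
from rnaphylo.models import (GTRIG, PartitionData, encode_nucleotide_column,
                             partitioned_loglik)

NUC = "ACGU"


def _quartet_partition(rng, n_sites=25):
    model = GTRIG()
    true = trees.from_newick("((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.1);")
    sim = model.simulate(true, n_sites, rng)
    partials = {t: encode_nucleotide_column([NUC[s] for s in sim[t]])
                for t in "abcd"}
    return PartitionData(model, partials)


TOPOLOGIES = ["((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.1);",
              "((a:0.2,c:0.2):0.1,(b:0.2,d:0.2):0.1);",
              "((a:0.2,d:0.2):0.1,(b:0.2,c:0.2):0.1);"]


class TestSampler:
    def test_matches_enumerated_quartet_posterior(self):
        """With fixed branch lengths and parameters the topology posterior
        over the three quartet trees is enumerable; MCMC must match it."""
        rng = np.random.default_rng(8)
        part = _quartet_partition(rng, n_sites=25)
        lnls = np.array([partitioned_loglik(trees.from_newick(s), [part])
                         for s in TOPOLOGIES])
        post = np.exp(lnls - lnls.max())
        post /= post.sum()
        cfg = McmcConfig(n_generations=100_000, sample_every=20, n_runs=1,
                         update_model=False, update_branch_lengths=False)
        [trace] = run_mcmc([part], list("abcd"), cfg, seed=5,
                           fixed_tree=trees.from_newick(TOPOLOGIES[1]),
                           fixed_branch_lengths=True)
        sample = trace.post_burnin(0.2).topologies
        ids = [frozenset(trees.bipartitions(trees.from_newick(s)))
               for s in TOPOLOGIES]
        freqs = np.array([sum(1 for x in sample if x == i) for i in ids],
                         float)
        freqs /= freqs.sum()
        assert np.abs(freqs - post).max() < 0.03

    def test_uniform_prior_without_data_is_uniform(self):
        """With no data every topology has equal posterior probability:
        the sampler's acceptance must reduce to the symmetric proposal."""
        model = GTRIG()
        part = PartitionData(model, {t: np.ones((1, 4)) for t in "abcd"})
        cfg = McmcConfig(n_generations=30_000, sample_every=10, n_runs=1,
                         update_model=False, update_branch_lengths=False)
        [trace] = run_mcmc([part], list("abcd"), cfg, seed=9,
                           fixed_tree=trees.from_newick(TOPOLOGIES[0]),
                           fixed_branch_lengths=True)
        sample = trace.post_burnin(0.1).topologies
        ids = [frozenset(trees.bipartitions(trees.from_newick(s)))
               for s in TOPOLOGIES]
        freqs = np.array([sum(1 for x in sample if x == i) for i in ids],
                         float) / len(sample)
        assert np.abs(freqs - 1 / 3).max() < 0.05

    def test_same_seed_identical_trace(self):
        rng = np.random.default_rng(2)
        part = _quartet_partition(rng)
        cfg = McmcConfig(n_generations=2000, sample_every=100, n_runs=1)
        [t1] = run_mcmc([part], list("abcd"), cfg, seed=3)
        [t2] = run_mcmc([part], list("abcd"), cfg, seed=3)
        assert t1.lnl == t2.lnl
        assert t1.topologies == t2.topologies

    def test_trace_invariants(self):
        rng = np.random.default_rng(2)
        part = _quartet_partition(rng)
        cfg = McmcConfig(n_generations=1000, sample_every=50, n_runs=2)
        for trace in run_mcmc([part], list("abcd"), cfg, seed=1):
            trace.validate()
            assert all(np.isfinite(trace.lnl))
            gens = trace.generations
            assert all(b > a for a, b in zip(gens, gens[1:]))


class TestHarmonicMean:
    def test_constant_trace(self):
        tr = McmcTrace(generations=list(range(20)), lnl=[-100.0] * 20)
        assert harmonic_mean_lnl(tr, burn_in=0.0) == pytest.approx(-100.0)

    def test_two_constant_traces_difference(self):
        a = McmcTrace(generations=list(range(10)), lnl=[-100.0] * 10)
        b = McmcTrace(generations=list(range(10)), lnl=[-110.0] * 10)
        assert bayes_factor(a, b, burn_in=0.0) == pytest.approx(10.0)

    def test_two_term_log_sum_exp(self):
        tr = McmcTrace(generations=[1, 2], lnl=[-1.0, -3.0])
        assert harmonic_mean_lnl(tr, burn_in=0.0) == pytest.approx(
            direct_harmonic_mean_log([-1.0, -3.0]), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            harmonic_mean_lnl(McmcTrace(), burn_in=0.0)


class TestEss:
    def test_iid_draws(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10_000)
        assert abs(ess(x) - 10_000) / 10_000 < 0.15

    def test_ar1_closed_form(self):
        rng = np.random.default_rng(1)
        rho, n = 0.9, 20_000
        x = np.empty(n)
        x[0] = 0.0
        for i in range(1, n):
            x[i] = rho * x[i - 1] + rng.normal()
        expected = n * (1 - rho) / (1 + rho)
        assert abs(ess(x) - expected) / expected < 0.25

    def test_antithetic_sequence_super_efficient(self):
        x = np.tile([1.0, -1.0], 50)
        assert ess(x) >= 100  # negative correlation: ESS > n permitted

    def test_constant_trace_degenerate(self):
        assert ess(np.ones(50)) == 50

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ess(np.arange(5))


class TestGelman:
    def test_identical_runs_psrf_one(self):
        x = list(np.sin(np.arange(200)))
        assert gelman_diagnostic([x, x]) == pytest.approx(1.0, abs=0.01)

    def test_same_distribution_converged(self):
        rng = np.random.default_rng(3)
        runs = [rng.normal(size=4000), rng.normal(size=4000)]
        assert gelman_diagnostic(runs) < 1.05

    def test_disjoint_runs_diverged(self):
        rng = np.random.default_rng(3)
        runs = [rng.normal(size=200), rng.normal(size=200) + 10]
        assert gelman_diagnostic(runs) > 2

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            gelman_diagnostic([[1.0, 2.0]])


class TestConsensus:
    def _trace_from(self, topo_indices):
        topos = [frozenset(trees.bipartitions(trees.from_newick(s)))
                 for s in TOPOLOGIES]
        n = len(topo_indices)
        return McmcTrace(generations=list(range(1, n + 1)),
                         lnl=[-1.0] * n,
                         parameters=[np.zeros(1)] * n,
                         topologies=[topos[i] for i in topo_indices])

    def test_unanimous_sample(self):
        trace = self._trace_from([0] * 20)
        summary = consensus_and_pp(trace, list("abcd"), burn_in=0.0)
        assert all(p == 1.0 for p in summary.clade_probabilities.values())
        assert trees.same_topology(summary.consensus,
                                   trees.from_newick(TOPOLOGIES[0]))

    def test_sixty_forty_split(self):
        trace = self._trace_from([0] * 12 + [1] * 8)
        summary = consensus_and_pp(trace, list("abcd"), burn_in=0.0)
        split = frozenset({"c", "d"})
        assert summary.clade_probabilities[split] == pytest.approx(0.6)
        assert trees.has_clade(summary.consensus, {"c", "d"})

    def test_fifty_fifty_tie_excluded(self):
        trace = self._trace_from([0] * 10 + [1] * 10)
        summary = consensus_and_pp(trace, list("abcd"), burn_in=0.0)
        assert trees.bipartitions(summary.consensus,
                                  list("abcd")) == frozenset()
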