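"""Bayesian MCMC over topology, branch lengths and model parameters.

Metropolis–Hastings with flat priors: uniform(0, 100) on rate parameters,
uniform Dirichlet on frequency vectors, uniform(0, 10) on branch lengths,
uniform on unrooted topologies.  Moves: NNI (and optional SPR) on
topology, a multiplier on a random branch length, a two-component transfer
on a frequency vector, and a multiplier on a rate parameter.  Several
independent runs from random starting trees support the Gelman–Rubin
diagnostic; model comparison uses the harmonic-mean marginal-likelihood
estimator (computed with a stable log-sum-exp; its well-known instability
is documented, but it is the published comparison device and is
implemented as such).
"""
from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from . import trees
from .models import PartitionData, partitioned_loglik

BRANCH_MAX = 10.0
RATE_MAX = 100.0


@dataclass
class McmcTrace:
    """Per-sample records of one MCMC run."""

    generations: list[int] = field(default_factory=list)
    lnl: list[float] = field(default_factory=list)
    parameters: list[np.ndarray] = field(default_factory=list)
    topologies: list[frozenset] = field(default_factory=list)
    newicks: list[str] = field(default_factory=list)
    chain_id: int = 0
    run_id: int = 0
    seed: int | None = None
    acceptance_rate: float = float("nan")

    def __post_init__(self):
        pass

    def validate(self) -> None:
        if any(b <= a for a, b in zip(self.generations, self.generations[1:])):
            raise ValueError("generations not strictly increasing")
        if not all(np.isfinite(self.lnl)):
            raise ValueError("non-finite lnL in trace")

    def post_burnin(self, burn_in: float = 0.25) -> "McmcTrace":
        k = int(len(self.lnl) * burn_in)
        return McmcTrace(self.generations[k:], self.lnl[k:],
                         self.parameters[k:], self.topologies[k:],
                         self.newicks[k:], self.chain_id, self.run_id,
                         self.seed, self.acceptance_rate)


@dataclass
class McmcConfig:
    n_generations: int = 20_000
    sample_every: int = 100
    burn_in: float = 0.25
    n_runs: int = 2
    n_chains: int = 1          # Metropolis coupling off by default
    update_model: bool = True
    update_branch_lengths: bool = True
    use_spr: bool = False
    sample_topology: bool = True
    heat: float = 0.1          # increment for heated chains when coupled


def _model_param_vector(partitions: Sequence[PartitionData]) -> np.ndarray:
    out = []
    for p in partitions:
        m = p.model
        if hasattr(m, "exchangeabilities"):
            out.extend(np.asarray(m.exchangeabilities, dtype=float))
        out.extend(m.freqs)
    return np.asarray(out)


class _State:
    def __init__(self, tree, partitions, lnl):
        self.tree = tree
        self.partitions = partitions
        self.lnl = lnl


def _random_start(taxa, partitions, rng, max_tries: int = 100):
    for _ in range(max_tries):
        tree = trees.random_topology(taxa, rng)
        for n in tree.postorder():
            if n is not tree:
                n.length = float(rng.uniform(0.02, 0.5))
        lnl = partitioned_loglik(tree, partitions)
        if np.isfinite(lnl):
            return tree, lnl
    raise RuntimeError("no finite-likelihood starting tree found in "
                       f"{max_tries} attempts")


def _propose_branch(tree, rng) -> tuple[float, trees.Node, float]:
    nodes = [n for n in tree.postorder() if n is not tree]
    node = nodes[int(rng.integers(len(nodes)))]
    lam = 1.0
    mult = math.exp(lam * (rng.random() - 0.5))
    old = node.length
    node.length = old * mult
    log_hastings = math.log(mult)
    return log_hastings, node, old


def _propose_frequencies(model, rng) -> tuple[np.ndarray, float]:
    old = model.freqs.copy()
    k = len(old)
    i, j = rng.choice(k, size=2, replace=False)
    delta = rng.uniform(0, min(old[i], 0.1))
    new = old.copy()
    new[i] -= delta
    new[j] += delta
    if new[i] <= 1e-6:
        return old, -math.inf
    model.freqs = new
    model.frequencies = tuple(new)
    model.invalidate()
    return old, 0.0  # symmetric transfer


def _propose_rate(model, rng) -> tuple[tuple, float]:
    if hasattr(model, "exchangeabilities"):
        vec = np.asarray(model.exchangeabilities, dtype=float)
        i = int(rng.integers(len(vec)))
        mult = math.exp(rng.random() - 0.5)
        old = vec.copy()
        vec[i] *= mult
        if vec[i] > RATE_MAX:
            return ("exch", old), -math.inf
        model.exchangeabilities = tuple(vec)
        model.invalidate()
        return ("exch", old), math.log(mult)
    names = [n for n in ("alpha_single", "alpha_double_substitution",
                         "alpha_double_transversion", "kappa_to_mismatch",
                         "kappa_within_mismatch") if hasattr(model, n)]
    if not names:
        return ("none", None), -math.inf
    name = names[int(rng.integers(len(names)))]
    mult = math.exp(rng.random() - 0.5)
    old = getattr(model, name)
    if old * mult > RATE_MAX:
        return ("attr", (name, old)), -math.inf
    setattr(model, name, old * mult)
    model.invalidate()
    return ("attr", (name, old)), math.log(mult)


def run_mcmc(partitions: Sequence[PartitionData], taxa: Sequence[str],
             config: McmcConfig | None = None, seed: int = 0,
             fixed_tree: trees.Node | None = None,
             fixed_branch_lengths: bool = False) -> list[McmcTrace]:
    """Run ``config.n_runs`` independent MCMC runs; returns one cold-chain
    trace per run.  Deterministic under a fixed seed.  ``fixed_tree`` sets
    the starting tree (topology still moves unless
    ``config.sample_topology`` is off); ``fixed_branch_lengths`` disables
    branch-length updates."""
    cfg = config or McmcConfig()
    taxa = list(taxa)
    out = []
    input_partitions = partitions
    for run in range(cfg.n_runs):
        # each run owns private model objects: proposals mutate them
        partitions = [PartitionData(copy.deepcopy(p.model),
                                    p.leaf_partials, p.column_ids)
                      for p in input_partitions]
        rng = np.random.default_rng((seed, run))
        if fixed_tree is not None:
            tree = fixed_tree.copy()
            lnl = partitioned_loglik(tree, partitions)
        else:
            tree, lnl = _random_start(taxa, partitions, rng)
        trace = McmcTrace(chain_id=0, run_id=run, seed=seed)
        accepted = proposed = 0
        n_leaves = len(taxa)
        for gen in range(1, cfg.n_generations + 1):
            move = rng.random()
            topo_w = 0.4 if cfg.sample_topology else 0.0
            bl_w = 0.3 if (cfg.update_branch_lengths
                           and not fixed_branch_lengths) else 0.0
            model_w = 0.3 if cfg.update_model else 0.0
            total_w = topo_w + bl_w + model_w
            if total_w == 0:
                break
            move *= total_w
            proposed += 1
            if move < topo_w:
                # topology proposal: one random NNI (or SPR) neighbour;
                # NNI neighbourhood sizes are constant across binary
                # topologies, so that proposal is symmetric
                if cfg.use_spr and rng.random() < 0.3:
                    cand = trees.random_spr(tree, rng)
                else:
                    cand = trees.random_nni(tree, rng)
                if cand is None:
                    continue
                cand_lnl = partitioned_loglik(cand, partitions)
                if math.log(rng.random() + 1e-300) < cand_lnl - lnl:
                    tree, lnl = cand, cand_lnl
                    accepted += 1
            elif move < topo_w + bl_w:
                log_h, node, old = _propose_branch(tree, rng)
                if node.length > BRANCH_MAX:
                    node.length = old
                else:
                    cand_lnl = partitioned_loglik(tree, partitions)
                    if math.log(rng.random() + 1e-300) < \
                            cand_lnl - lnl + log_h:
                        lnl = cand_lnl
                        accepted += 1
                    else:
                        node.length = old
            else:
                part = partitions[int(rng.integers(len(partitions)))]
                model = part.model
                if rng.random() < 0.5:
                    old, log_h = _propose_frequencies(model, rng)
                    if not np.isfinite(log_h):
                        continue
                    cand_lnl = partitioned_loglik(tree, partitions)
                    if math.log(rng.random() + 1e-300) < \
                            cand_lnl - lnl + log_h:
                        lnl = cand_lnl
                        accepted += 1
                    else:
                        model.freqs = old
                        model.frequencies = tuple(old)
                        model.invalidate()
                else:
                    undo, log_h = _propose_rate(model, rng)
                    if not np.isfinite(log_h):
                        continue
                    cand_lnl = partitioned_loglik(tree, partitions)
                    if math.log(rng.random() + 1e-300) < \
                            cand_lnl - lnl + log_h:
                        lnl = cand_lnl
                        accepted += 1
                    else:
                        kind, old = undo
                        if kind == "exch":
                            model.exchangeabilities = tuple(old)
                        elif kind == "attr":
                            setattr(model, old[0], old[1])
                        model.invalidate()
            if gen % cfg.sample_every == 0:
                trace.generations.append(gen)
                trace.lnl.append(lnl)
                trace.parameters.append(_model_param_vector(partitions))
                trace.topologies.append(trees.topology_id(tree))
                trace.newicks.append(trees.to_newick(tree))
        trace.acceptance_rate = accepted / max(proposed, 1)
        trace.validate()
        out.append(trace)
    return out


# ---------------------------------------------------------------------------
# Summaries and diagnostics
# ---------------------------------------------------------------------------

def harmonic_mean_lnl(trace: McmcTrace, burn_in: float = 0.25) -> float:
    """log of the harmonic mean of sampled likelihoods, via log-sum-exp."""
    lnl = np.asarray(trace.post_burnin(burn_in).lnl)
    if lnl.size == 0:
        raise ValueError("empty post-burn-in sample")
    return float(math.log(lnl.size) - logsumexp(-lnl))


def bayes_factor(trace_a: McmcTrace, trace_b: McmcTrace,
                 burn_in: float = 0.25) -> float:
    """log Bayes factor of model A over model B: difference of log
    harmonic-mean marginal likelihoods."""
    return harmonic_mean_lnl(trace_a, burn_in) - \
        harmonic_mean_lnl(trace_b, burn_in)


def ess(values: Sequence[float]) -> float:
    """Effective sample size, n / (1 + 2 * sum of autocorrelations), with
    the sum truncated at the first non-positive pair (Geyer/TRACER style).

    A constant trace is degenerate and reported as n."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples")
    var = x.var()
    if var == 0:
        return float(n)  # degenerate: constant trace
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (var * n)
    s = 0.0
    k = 1
    while k + 1 < n:
        pair = acf[k] + acf[k + 1]
        if pair <= 0:
            break
        s += pair
        k += 2
    return float(n / (1 + 2 * s))


def gelman_diagnostic(runs: Sequence[Sequence[float]]) -> float:
    """Potential scale reduction factor across >= 2 equal-length runs;
    <= 1.05 is conventionally converged."""
    if len(runs) < 2:
        raise ValueError("need at least two runs")
    chains = np.asarray([np.asarray(r, dtype=float) for r in runs])
    m, n = chains.shape
    means = chains.mean(axis=1)
    variances = chains.var(axis=1, ddof=1)
    w = variances.mean()
    b = n * means.var(ddof=1)
    var_hat = (n - 1) / n * w + b / n
    if w == 0:
        return 1.0
    return float(math.sqrt(var_hat / w))


@dataclass
class PosteriorSummary:
    clade_probabilities: dict[frozenset, float]
    consensus: trees.Node
    parameter_means: np.ndarray
    parameter_ess: np.ndarray
    harmonic_mean: float

    def __post_init__(self):
        for p in self.clade_probabilities.values():
            if not (0 <= p <= 1):
                raise ValueError("clade probability outside [0, 1]")


def consensus_and_pp(trace: McmcTrace, taxa: Sequence[str],
                     burn_in: float = 0.25) -> PosteriorSummary:
    """Clade posterior probabilities and the majority-rule consensus from
    the post-burn-in topology sample.  Exact 50/50 splits are excluded
    (strict majority)."""
    post = trace.post_burnin(burn_in)
    if not post.topologies:
        raise ValueError("empty post-burn-in sample")
    counts: dict[frozenset, int] = {}
    for topo in post.topologies:
        for split in topo:
            counts[split] = counts.get(split, 0) + 1
    n = len(post.topologies)
    pp = {split: c / n for split, c in counts.items()}
    cons = trees.consensus_tree(post.topologies, sorted(taxa), 0.5)
    params = np.asarray(post.parameters)
    if params.size:
        means = params.mean(axis=0)
        ess_vals = np.array([ess(params[:, j]) if len(params) >= 10
                             else float("nan")
                             for j in range(params.shape[1])])
    else:
        means = np.zeros(0)
        ess_vals = np.zeros(0)
    return PosteriorSummary(pp, cons, means, ess_vals,
                            harmonic_mean_lnl(trace, burn_in))
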