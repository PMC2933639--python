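"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration, closed
forms, cost-only dynamic programs — and shares no code path with the
implementations it checks.
"""
from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np

NUC = "ACGU"
PURINES = set("AG")


# ---------------------------------------------------------------------------
# Parsimony: minimum changes by exhaustive internal labelling
# ---------------------------------------------------------------------------

def brute_force_fitch(root, column: dict, n_states: int) -> int:
    """Minimum number of changes over all internal-node state assignments.

    ``column`` maps leaf label -> set of allowed state indices.
    """
    internals = [n for n in root.postorder() if not n.is_leaf]
    leaves = root.leaves()
    best = math.inf
    leaf_choices = [sorted(column[l.label]) for l in leaves]
    for internal_states in itertools.product(range(n_states),
                                             repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, internal_states)}
        for leaf_states in itertools.product(*leaf_choices):
            for l, s in zip(leaves, leaf_states):
                assign[id(l)] = s
            changes = 0
            for node in root.postorder():
                if node is root:
                    continue
                if assign[id(node)] != assign[id(node.parent)]:
                    changes += 1
            best = min(best, changes)
    return best


# ---------------------------------------------------------------------------
# Likelihood: exhaustive sum over internal states
# ---------------------------------------------------------------------------

def enumerate_loglik(tree, model, leaf_partials: dict) -> float:
    """Site log-likelihoods by explicit summation over every internal-node
    state combination, mixed over the model's rate categories."""
    k = model.n_states
    internals = [n for n in tree.postorder() if not n.is_leaf]
    leaves = tree.leaves()
    n_sites = next(iter(leaf_partials.values())).shape[0]
    weights, rates = model.rate_mixture()
    total = np.zeros(n_sites)
    for w, r in zip(weights, rates):
        pmats = {id(n): model.transition_probabilities(n.length or 0.0,
                                                       rate=r)
                 for n in tree.postorder() if n is not tree}
        site_l = np.zeros(n_sites)
        for states in itertools.product(range(k), repeat=len(internals)):
            assign = {id(n): s for n, s in zip(internals, states)}
            prob = np.full(n_sites, model.freqs[assign[id(tree)]])
            for node in tree.postorder():
                if node is tree:
                    continue
                p = pmats[id(node)]
                parent_state = assign[id(node.parent)]
                if node.is_leaf:
                    lp = leaf_partials.get(node.label)
                    if lp is None:
                        continue  # all-missing leaf marginalises to 1
                    prob = prob * (lp * p[parent_state][None, :]).sum(axis=1)
                else:
                    prob = prob * p[parent_state, assign[id(node)]]
            site_l += prob
        total += w * site_l
    return float(np.log(total).sum())


def jc69_two_taxon_loglik(t_total: float, n_same: int, n_diff: int) -> float:
    """Closed-form Jukes-Cantor log-likelihood of two aligned sequences
    separated by total path length ``t_total``."""
    p_same = 0.25 + 0.75 * math.exp(-4.0 * t_total / 3.0)
    p_diff = 0.25 - 0.25 * math.exp(-4.0 * t_total / 3.0)
    return (n_same * math.log(0.25 * p_same)
            + n_diff * math.log(0.25 * p_diff))


# ---------------------------------------------------------------------------
# Direct optimization oracles
# ---------------------------------------------------------------------------

def nw_cost(a: str, b: str, gap: float, tv: float, ts: float) -> float:
    """Cost-only Needleman-Wunsch with linear gap cost."""
    def sub(x, y):
        if x == y:
            return 0.0
        return ts if (x in PURINES) == (y in PURINES) else tv

    n, m = len(a), len(b)
    prev = [j * gap for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [i * gap] + [0.0] * m
        for j in range(1, m + 1):
            cur[j] = min(prev[j - 1] + sub(a[i - 1], b[j - 1]),
                         prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    return prev[m]


def enumerate_pairwise_cost(a: str, b: str, gap: float, tv: float,
                            ts: float) -> float:
    """Minimum alignment cost by explicit enumeration of all alignments
    (monotone matchings) — exponential, for tiny strings only."""
    def sub(x, y):
        if x == y:
            return 0.0
        return ts if (x in PURINES) == (y in PURINES) else tv

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> float:
        if i == len(a):
            return (len(b) - j) * gap
        if j == len(b):
            return (len(a) - i) * gap
        return min(rec(i + 1, j + 1) + sub(a[i], b[j]),
                   rec(i + 1, j) + gap, rec(i, j + 1) + gap)

    return rec(0, 0)


class QuartetTreeAlignmentOracle:
    """Exact tree-alignment cost on the quartet ((1,2),(3,4)) by
    enumerating both internal-node sequences up to a length bound."""

    def __init__(self, gap: float, tv: float, ts: float, max_internal: int = 4):
        self.costs = (gap, tv, ts)
        self.cands = [""]
        for L in range(1, max_internal + 1):
            self.cands += ["".join(p) for p in
                           itertools.product(NUC, repeat=L)]
        self._pc = lru_cache(maxsize=None)(
            lambda x, y: nw_cost(x, y, *self.costs))
        self._inner = np.array(
            [[self._pc(u, v) for v in self.cands] for u in self.cands])

    def exact_cost(self, leaves: list[str]) -> float:
        a = np.array([self._pc(u, leaves[0]) + self._pc(u, leaves[1])
                      for u in self.cands])
        b = np.array([self._pc(v, leaves[2]) + self._pc(v, leaves[3])
                      for v in self.cands])
        return float((a[:, None] + b[None, :] + self._inner).min())


# ---------------------------------------------------------------------------
# Log-sum-exp harmonic mean, two terms by hand
# ---------------------------------------------------------------------------

def direct_harmonic_mean_log(lnl_values) -> float:
    """log of n / sum(exp(-lnl)) computed with plain floats (safe only for
    small magnitudes; used as an oracle on tiny traces)."""
    s = sum(math.exp(-x) for x in lnl_values)
    return math.log(len(list(lnl_values)) / s)
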