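"""Simplified direct optimization (dynamic homology) of unaligned fragments.

Fragments are scored on a tree without a prior multiple alignment: a
post-order pass assigns every internal node a median sequence obtained by
pairwise alignment of its children's medians under the active cost regime,
the leaf rows are threaded through those alignments into an *implied
alignment*, and the fragment cost is the minimum cost of that implied
alignment on the fixed tree (per-column Sankoff over the five states
A, C, G, U, gap).  This is a documented upper-bound heuristic of the exact
tree-alignment cost: the implied alignment is a genuine alignment, so its
optimal cost can never undercut the true optimum, and on small instances it
usually attains it.  There is no iterative-pass refinement; the thorough
variant instead retries alternative rootings and traceback preferences and
keeps the cheapest implied alignment.

A cost regime is the (gap extension : transversion : transition) triple,
written with its digit label in that order (so "412" is gap 4,
transversion 1, transition 2).  Gap cost is linear (extension only); no
opening cost.  IUPAC ambiguity codes participate as state sets: the cost
between two sets is the minimum over member pairs.  State sets are held as
5-bit masks over A, C, G, U, gap with per-regime 32 x 32 cost and median
lookup tables, which keeps the dynamic programs fast.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import trees
from .alignments import GAP, IUPAC, FragmentSet
from .parsimony import ParsimonyMatrix, fitch_length

NUC_GAP = "ACGU-"
PURINES = {"A", "G"}
GAP_BIT = 1 << 4
FULL_MASK = (1 << 5) - 1


@dataclass(frozen=True)
class CostRegime:
    """(gap extension, transversion, transition) cost triple."""

    gap_extension: float
    transversion: float
    transition: float
    label: str = ""

    def __post_init__(self):
        if min(self.gap_extension, self.transversion, self.transition) <= 0:
            raise ValueError("costs must be positive")
        if not self.label:
            object.__setattr__(
                self, "label",
                f"{self.gap_extension:g}{self.transversion:g}"
                f"{self.transition:g}")

    @classmethod
    def from_label(cls, label: str) -> "CostRegime":
        """Digits map to costs in the printed order gap:tv:ts."""
        if len(label) != 3 or not label.isdigit():
            raise ValueError(f"bad cost-regime label {label!r}")
        g, tv, ts = (float(d) for d in label)
        return cls(g, tv, ts, label)

    def base_cost(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        if a == GAP or b == GAP:
            return self.gap_extension
        if (a in PURINES) == (b in PURINES):
            return self.transition
        return self.transversion

    def cost_matrix5(self) -> np.ndarray:
        """5x5 cost matrix over A, C, G, U, gap."""
        m = np.zeros((5, 5))
        for i, a in enumerate(NUC_GAP):
            for j, b in enumerate(NUC_GAP):
                m[i, j] = self.base_cost(a, b)
        return m


STANDARD_REGIMES = tuple(CostRegime.from_label(l) for l in
                         ("111", "121", "112", "211", "221", "411", "412",
                          "421"))


# ---------------------------------------------------------------------------
# Bitmask state sets and per-regime lookup tables
# ---------------------------------------------------------------------------

def encode_residue(ch: str) -> int:
    """5-bit state mask of a residue character (gap keeps its own bit)."""
    ch = ch.upper().replace("T", "U")
    if ch == GAP:
        return GAP_BIT
    states = IUPAC.get(ch)
    if states is None:
        raise ValueError(f"unknown residue code {ch!r}")
    mask = 0
    for s in states:
        mask |= 1 << NUC_GAP.index(s)
    return mask


def mask_to_states(mask: int) -> frozenset:
    """The residue set a bitmask denotes (for reporting and tests)."""
    return frozenset(NUC_GAP[i] for i in range(5) if mask >> i & 1)


def encode_fragment_sequence(seq: str) -> tuple[int, ...]:
    return tuple(encode_residue(ch) for ch in seq if ch != GAP)


_TABLE_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _regime_tables(regime: CostRegime) -> tuple[np.ndarray, np.ndarray]:
    """(cost, median) lookup tables over all 32 x 32 bitmask pairs.

    cost[a, b] = min over member pairs; median[a, b] = the cost-free
    intersection when one exists, else the union.
    """
    key = (regime.gap_extension, regime.transversion, regime.transition)
    cached = _TABLE_CACHE.get(key)
    if cached is not None:
        return cached
    c5 = regime.cost_matrix5()
    cost = np.full((32, 32), np.inf)
    median = np.zeros((32, 32), dtype=np.int64)
    for a in range(1, 32):
        sa = [i for i in range(5) if a >> i & 1]
        for b in range(1, 32):
            sb = [j for j in range(5) if b >> j & 1]
            best = min(c5[i, j] for i in sa for j in sb)
            cost[a, b] = best
            inter = a & b
            if inter and best == 0:
                median[a, b] = inter
            else:
                median[a, b] = a | b
    cost[0, :] = cost[:, 0] = 0.0
    _TABLE_CACHE[key] = (cost, median)
    return cost, median


def set_cost(regime: CostRegime, mask_a: int, mask_b: int) -> float:
    """Minimum substitution/indel cost between two residue state sets."""
    return float(_regime_tables(regime)[0][mask_a, mask_b])


def pairwise_do_cost(seq_a, seq_b, regime: CostRegime,
                     prefer_gap: bool = False,
                     ) -> tuple[float, list[tuple[int | None, int | None]],
                                tuple[int, ...]]:
    """Needleman-Wunsch with linear gap cost over state sets.

    Returns (cost, alignment trace, median sequence).  The trace is a list
    of (i, j) index pairs into the two sequences, ``None`` marking a gap.
    Medians are bitmask state sets (see :func:`mask_to_states`): at a
    matched column the cost-free intersection when one exists, otherwise
    the union; at an indel column the present residue set plus the gap
    state, so downstream edges may resolve the indel either way.
    ``prefer_gap`` flips the traceback tie-break between co-optimal paths,
    which can yield different implied alignments of equal pairwise cost.
    """
    a = encode_fragment_sequence(seq_a) if isinstance(seq_a, str) \
        else tuple(seq_a)
    b = encode_fragment_sequence(seq_b) if isinstance(seq_b, str) \
        else tuple(seq_b)
    ctab, mtab = _regime_tables(regime)
    n, m = len(a), len(b)
    gap = regime.gap_extension
    dp = np.empty((n + 1, m + 1))
    jg = np.arange(m + 1) * gap
    dp[0, :] = jg
    if n and m:
        sub = ctab[np.array(a)][:, np.array(b)]  # (n, m) substitution costs
    # row recurrence vectorised: with a linear gap cost,
    # dp[i, j] = min_{k <= j} base[k] + (j - k) * gap where
    # base[j] = min(diagonal, vertical) — a running minimum
    base = np.empty(m + 1)
    for i in range(1, n + 1):
        prev = dp[i - 1]
        base[0] = prev[0] + gap
        if m:
            np.minimum(prev[:-1] + sub[i - 1], prev[1:] + gap,
                       out=base[1:])
        dp[i] = np.minimum.accumulate(base - jg) + jg
    trace: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        options = []
        if i > 0 and j > 0 and dp[i, j] == dp[i - 1, j - 1] + \
                sub[i - 1, j - 1]:
            options.append("sub")
        if i > 0 and dp[i, j] == dp[i - 1, j] + gap:
            options.append("del")
        if j > 0 and dp[i, j] == dp[i, j - 1] + gap:
            options.append("ins")
        choice = options[-1] if prefer_gap and len(options) > 1 else options[0]
        if choice == "sub":
            trace.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif choice == "del":
            trace.append((i - 1, None))
            i -= 1
        else:
            trace.append((None, j - 1))
            j -= 1
    trace.reverse()
    median = []
    for (ti, tj) in trace:
        if ti is not None and tj is not None:
            median.append(int(mtab[a[ti], b[tj]]))
        elif ti is not None:
            median.append(a[ti] | GAP_BIT)
        else:
            median.append(b[tj] | GAP_BIT)
    return float(dp[n, m]), trace, tuple(median)


# ---------------------------------------------------------------------------
# Tree-level DO
# ---------------------------------------------------------------------------

@dataclass
class ImpliedAlignment:
    """Leaf rows padded with gaps consistently with the node medians.

    ``rows`` maps each scoped taxon to a tuple of bitmask state sets
    (gap = the gap bit); ``as_strings`` renders IUPAC text rows.
    """

    columns: int
    rows: dict[str, tuple[int, ...]]

    def as_strings(self) -> dict[str, str]:
        out = {}
        for taxon, row in self.rows.items():
            chars = []
            for mask in row:
                if mask == GAP_BIT:
                    chars.append(GAP)
                else:
                    residues = sorted(mask_to_states(mask) - {GAP})
                    chars.append(residues[0] if len(residues) == 1
                                 else _iupac_code(residues))
            out[taxon] = "".join(chars)
        return out

    def as_fasta(self) -> str:
        rows = self.as_strings()
        return "".join(f">{t}\n{rows[t]}\n" for t in sorted(rows))


def _iupac_code(residues: Sequence[str]) -> str:
    target = "".join(sorted(residues))
    for code, states in IUPAC.items():
        if "".join(sorted(states)) == target and code not in "ACGU?":
            return code
    return "N"


def _single_pass_alignment(root: trees.Node, fragment: FragmentSet,
                           regime: CostRegime,
                           prefer_gap: bool = False) -> ImpliedAlignment:
    """One post-order median construction + implied alignment from a given
    rooting and traceback preference."""
    scoped = [l for l in root.leaf_labels() if l in fragment.taxon_scope]
    if not scoped:
        return ImpliedAlignment(0, {})
    if len(scoped) == 1:
        seq = encode_fragment_sequence(fragment.sequences[scoped[0]])
        return ImpliedAlignment(len(seq), {scoped[0]: seq})

    def rec(node):
        if node.is_leaf:
            if node.label not in fragment.taxon_scope:
                return None
            med = encode_fragment_sequence(fragment.sequences[node.label])
            return med, {node.label: med}
        parts = [r for r in (rec(c) for c in node.children) if r is not None]
        if not parts:
            return None
        while len(parts) > 1:
            (med_a, rows_a), (med_b, rows_b) = parts[0], parts[1]
            _, trace, med = pairwise_do_cost(med_a, med_b, regime,
                                             prefer_gap=prefer_gap)
            new_rows: dict[str, tuple[int, ...]] = {}
            for taxon, row in rows_a.items():
                new_rows[taxon] = tuple(row[ti] if ti is not None else GAP_BIT
                                        for ti, _ in trace)
            for taxon, row in rows_b.items():
                new_rows[taxon] = tuple(row[tj] if tj is not None else GAP_BIT
                                        for _, tj in trace)
            parts = [(med, new_rows)] + parts[2:]
        return parts[0]

    med, rows = rec(root)
    return ImpliedAlignment(len(med), rows)


def _sankoff_cost(root: trees.Node, ia: ImpliedAlignment,
                  regime: CostRegime) -> float:
    """Minimum cost of a fixed alignment on a fixed tree, per-column
    Sankoff over the 5-state alphabet; taxa absent from the alignment are
    uninformative."""
    n_cols = ia.columns
    if n_cols == 0 or len(ia.rows) < 2:
        return 0.0
    cm = regime.cost_matrix5()
    INF = 1e12
    leaf_cost = {}
    for taxon, row in ia.rows.items():
        arr = np.full((n_cols, 5), INF)
        masks = np.array(row)
        for s in range(5):
            arr[:, s] = np.where(masks >> s & 1, 0.0, INF)
        leaf_cost[taxon] = arr
    cost: dict[int, np.ndarray] = {}
    for node in root.postorder():
        if node.is_leaf:
            cost[id(node)] = leaf_cost.get(node.label,
                                           np.zeros((n_cols, 5)))
        else:
            arr = np.zeros((n_cols, 5))
            for child in node.children:
                child_cost = cost.pop(id(child))
                arr += (child_cost[:, None, :] + cm[None, :, :]).min(axis=2)
            cost[id(node)] = arr
    return float(cost[id(root)].min(axis=1).sum())


def tree_do_alignment(root: trees.Node, fragment: FragmentSet,
                      regime: CostRegime,
                      thorough: bool = True) -> ImpliedAlignment:
    """Implied alignment of a fragment on a tree.

    ``thorough`` explores alternative rootings (each leaf edge) and both
    traceback preferences, keeping the alignment whose cost on the fixed
    tree is lowest; the cheap single-pass variant (one rooting, one
    traceback) is what tree searches use internally.  Leaves outside the
    fragment's taxon scope are ignored (scored missing).
    """
    best_ia = _single_pass_alignment(root, fragment, regime)
    if not thorough or len(best_ia.rows) < 3:
        return best_ia
    best_cost = _sankoff_cost(root, best_ia, regime)
    variants = [(root, True)]
    for leaf in root.leaf_labels():
        rerooted = trees.reroot_at_leaf_edge(root, leaf)
        variants.extend([(rerooted, False), (rerooted, True)])
    for start, pg in variants:
        ia = _single_pass_alignment(start, fragment, regime, prefer_gap=pg)
        cost = _sankoff_cost(root, ia, regime)
        if cost < best_cost - 1e-9:
            best_cost, best_ia = cost, ia
    return best_ia


def tree_do_cost(root: trees.Node, fragment: FragmentSet,
                 regime: CostRegime, thorough: bool = True) -> float:
    """Heuristic tree-alignment cost of one fragment (upper bound of the
    exact optimum; equals pairwise DP cost on two leaves; 0 for fragments
    with a single scoped taxon)."""
    ia = tree_do_alignment(root, fragment, regime, thorough=thorough)
    if len(ia.rows) < 2:
        return 0.0
    return _sankoff_cost(root, ia, regime)


def implied_alignment(root: trees.Node, fragment: FragmentSet,
                      regime: CostRegime,
                      thorough: bool = True) -> ImpliedAlignment:
    """Public alias for the implied alignment of a fragment on a tree."""
    return tree_do_alignment(root, fragment, regime, thorough=thorough)


def rescore_implied(root: trees.Node, ia: ImpliedAlignment,
                    regime: CostRegime) -> float:
    """Cost of an implied alignment on a fixed tree (self-consistency
    oracle for :func:`tree_do_cost`)."""
    return _sankoff_cost(root, ia, regime)


# ---------------------------------------------------------------------------
# Combined scoring
# ---------------------------------------------------------------------------

@dataclass
class DoScore:
    """Component breakdown of a combined tree score."""

    fragment_costs: dict[str, float] = field(default_factory=dict)
    static_cost: float = 0.0
    structure_cost: float = 0.0
    morphology_cost: float = 0.0
    morphology_weight: float = 1.0

    @property
    def total(self) -> float:
        return (sum(self.fragment_costs.values()) + self.static_cost
                + self.structure_cost
                + self.morphology_cost * self.morphology_weight)


def combined_score(root: trees.Node, parts, regime: CostRegime | None,
                   morph_weight: float = 1.0,
                   static_matrix: ParsimonyMatrix | None = None,
                   structure_matrix: ParsimonyMatrix | None = None,
                   morph_matrix: ParsimonyMatrix | None = None,
                   thorough: bool = True) -> DoScore:
    """Total-evidence score of one tree.

    Static molecular columns and structure characters are scored by Fitch
    at unit weight regardless of the regime (equal weighting under static
    homology); fragments by :func:`tree_do_cost` under the regime;
    morphology by Fitch times the regime's morphology weight.  The
    ``*_matrix`` arguments allow reusing pre-encoded matrices.
    """
    from .parsimony import (matrix_from_alignment, matrix_from_morphology,
                            matrix_from_structure_characters)
    score = DoScore(morphology_weight=morph_weight)
    if parts.do_fragments and regime is None:
        raise ValueError("cost regime required for DO fragments")
    for frag in parts.do_fragments:
        score.fragment_costs[frag.name] = tree_do_cost(root, frag, regime,
                                                       thorough=thorough)
    if parts.static_columns:
        if static_matrix is None:
            static_matrix = matrix_from_alignment(parts.alignment,
                                                  parts.static_columns)
        score.static_cost = fitch_length(root, static_matrix)
    if parts.structure_characters:
        if structure_matrix is None:
            structure_matrix = matrix_from_structure_characters(
                parts.structure_characters, parts.alignment.taxa)
        score.structure_cost = fitch_length(root, structure_matrix)
    if parts.morphology is not None:
        if morph_matrix is None:
            morph_matrix = matrix_from_morphology(
                parts.morphology, taxa=parts.morphology.taxa)
        score.morphology_cost = fitch_length(root, morph_matrix)
    return score


def morphology_weight(mol_length_regime: float, mol_length_111: float
                      ) -> float:
    """Morphology weight for a regime: molecular best length under the
    regime divided by the best length under the all-equal regime 111 (keeps
    the morphological contribution approximately constant across regimes).
    """
    if mol_length_111 <= 0:
        raise ValueError("zero molecular length under regime 111")
    return mol_length_regime / mol_length_111
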