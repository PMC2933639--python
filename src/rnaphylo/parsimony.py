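"""Parsimony scoring, heuristic search and support measures.

Molecular static columns are scored as unordered 5-state characters (gap is
a fifth state); morphology and structure characters as unordered multistate
characters.  Scoring is Fitch's set method, vectorised over columns with
bitmask state sets; missing data is the full state set.  Search is random-
addition Wagner building followed by SPR (optionally TBR-style rerooting of
the pruned subtree) branch swapping, with an optional parsimony ratchet
(reweight ~25% of the columns x2, swap, restore, swap).  Supports: strict
consensus, jackknife (independent column deletion, Farris probability
e^-1), Bremer decay via reverse-constraint (penalised) searches, and the
ensemble consistency/retention indices.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from . import trees
from .alignments import GAP, IUPAC, MISSING, MorphMatrix, StructuredAlignment
from .annotation import StructureCharacter

BIG_PENALTY = 1e9


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

@dataclass
class ParsimonyMatrix:
    """Columns of bitmask state sets with per-column weights."""

    taxa: list[str]
    data: np.ndarray          # (n_taxa, n_cols) unsigned int bitmasks
    weights: np.ndarray       # (n_cols,)
    full_masks: np.ndarray    # (n_cols,) bitmask meaning "any state"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.int64)
        self.weights = np.asarray(self.weights, dtype=float)
        self.full_masks = np.asarray(self.full_masks, dtype=np.int64)
        if (self.weights < 0).any():
            raise ValueError("negative column weight")
        if (self.data <= 0).any():
            raise ValueError("empty state set in matrix")

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.data[self.taxa.index(taxon)]

    def concat(self, other: "ParsimonyMatrix") -> "ParsimonyMatrix":
        if self.taxa != other.taxa:
            raise ValueError("taxon sets differ")
        return ParsimonyMatrix(
            self.taxa,
            np.concatenate([self.data, other.data], axis=1),
            np.concatenate([self.weights, other.weights]),
            np.concatenate([self.full_masks, other.full_masks]))

    def subset(self, cols: Sequence[int]) -> "ParsimonyMatrix":
        cols = list(cols)
        return ParsimonyMatrix(self.taxa, self.data[:, cols],
                               self.weights[cols], self.full_masks[cols])


NUC_GAP = "ACGU-"


def _nuc_bitmask(ch: str) -> int:
    ch = ch.upper().replace("T", "U")
    if ch == GAP:
        return 1 << 4
    if ch in (MISSING,):
        return (1 << 5) - 1
    states = IUPAC.get(ch)
    if states is None:
        raise ValueError(f"unknown residue {ch!r}")
    mask = 0
    for s in states:
        mask |= 1 << NUC_GAP.index(s)
    return mask


def matrix_from_alignment(aln: StructuredAlignment,
                          columns: Sequence[int] | None = None,
                          gap_as_state: bool = True) -> ParsimonyMatrix:
    """5-state (gap-as-fifth-state) matrix from aligned columns."""
    cols = list(columns) if columns is not None else list(range(aln.n_columns))
    full = (1 << 5) - 1 if gap_as_state else (1 << 4) - 1
    data = np.zeros((len(aln.taxa), len(cols)), dtype=np.int64)
    for r, t in enumerate(aln.taxa):
        seq = aln.sequences[t]
        for k, c in enumerate(cols):
            m = _nuc_bitmask(seq[c])
            if not gap_as_state:
                m = (m & 0b1111) or 0b1111
            data[r, k] = m
    return ParsimonyMatrix(list(aln.taxa), data,
                           np.ones(len(cols)),
                           np.full(len(cols), full, dtype=np.int64))


def matrix_from_morphology(morph: MorphMatrix,
                           taxa: Sequence[str] | None = None
                           ) -> ParsimonyMatrix:
    """Multistate matrix; ``?`` and ``-`` both map to missing."""
    taxa = list(taxa) if taxa is not None else list(morph.taxa)
    n = morph.n_characters
    full = np.zeros(n, dtype=np.int64)
    for t in morph.taxa:
        for k, code in enumerate(morph.matrix[t]):
            if code.isdigit():
                full[k] |= 1 << int(code)
    full[full == 0] = 1
    data = np.zeros((len(taxa), n), dtype=np.int64)
    for r, t in enumerate(taxa):
        row = morph.matrix.get(t)
        for k in range(n):
            if row is None or not row[k].isdigit():
                data[r, k] = full[k]
            else:
                data[r, k] = 1 << int(row[k])
                full_k = full[k] | data[r, k]
                full[k] = full_k
    # missing cells must cover the final observed state set
    for r, t in enumerate(taxa):
        row = morph.matrix.get(t)
        for k in range(n):
            if row is None or not row[k].isdigit():
                data[r, k] = full[k]
    return ParsimonyMatrix(taxa, data, np.array(morph.weights, dtype=float),
                           full)


def matrix_from_structure_characters(chars: Sequence[StructureCharacter],
                                     taxa: Sequence[str]) -> ParsimonyMatrix:
    taxa = list(taxa)
    n = len(chars)
    data = np.zeros((len(taxa), n), dtype=np.int64)
    full = np.full(n, 0b11, dtype=np.int64)
    for k, ch in enumerate(chars):
        for r, t in enumerate(taxa):
            code = ch.scores.get(t, "?")
            data[r, k] = 0b11 if code == "?" else (1 << int(code))
    return ParsimonyMatrix(taxa, data, np.ones(n), full)


# ---------------------------------------------------------------------------
# Fitch scoring
# ---------------------------------------------------------------------------

def _binarize(root: trees.Node) -> trees.Node:
    """Copy with every multifurcation folded into binary nodes (an
    arbitrary resolution; polytomies are scored as one such resolution)."""
    def conv(n: trees.Node) -> trees.Node:
        new = trees.Node(n.label, n.length)
        kids = [conv(c) for c in n.children]
        while len(kids) > 2:
            merged = trees.Node()
            merged.add(kids.pop())
            merged.add(kids.pop())
            kids.append(merged)
        for c in kids:
            new.add(c)
        return new
    return conv(root)


def fitch_counts(root: trees.Node, matrix: ParsimonyMatrix,
                 allow_partial: bool = False) -> np.ndarray:
    """Per-column minimum change counts (unweighted) on the tree.

    ``allow_partial`` permits matrix taxa missing from the tree (used while
    growing Wagner trees); otherwise that is an error.
    """
    tree_taxa = set(root.leaf_labels())
    if not allow_partial:
        for t in matrix.taxa:
            if t not in tree_taxa:
                raise ValueError(f"taxon {t!r} in matrix absent from tree")
    root = _binarize(root)
    rows = {t: i for i, t in enumerate(matrix.taxa)}
    counts = np.zeros(matrix.n_columns, dtype=np.int64)
    state: dict[int, np.ndarray] = {}
    for node in root.postorder():
        if node.is_leaf:
            i = rows.get(node.label)
            state[id(node)] = (matrix.data[i] if i is not None
                              else matrix.full_masks)
        else:
            s = None
            for child in node.children:
                cs = state.pop(id(child))
                if s is None:
                    s = cs
                else:
                    inter = s & cs
                    disjoint = inter == 0
                    counts += disjoint
                    s = np.where(disjoint, s | cs, inter)
            state[id(node)] = s
    return counts


def fitch_length(root: trees.Node, matrix: ParsimonyMatrix,
                 allow_partial: bool = False) -> float:
    """Weighted Fitch tree length (gaps count as a fifth state when so
    encoded)."""
    return float((fitch_counts(root, matrix, allow_partial)
                  * matrix.weights).sum())


def min_changes(matrix: ParsimonyMatrix) -> np.ndarray:
    """Per-column minimum conceivable changes on any tree: resolved states
    observed minus one (ambiguous cells that cannot extend the state set
    are ignored)."""
    out = np.zeros(matrix.n_columns, dtype=np.int64)
    for c in range(matrix.n_columns):
        col = matrix.data[:, c]
        singles = col[(col & (col - 1)) == 0]  # resolved cells
        out[c] = max(len(set(singles.tolist())) - 1, 0)
    return out


def max_changes(matrix: ParsimonyMatrix) -> np.ndarray:
    """Per-column maximum changes on any tree (star-tree bound): resolved
    cells minus the count of the commonest state."""
    out = np.zeros(matrix.n_columns, dtype=np.int64)
    for c in range(matrix.n_columns):
        col = matrix.data[:, c]
        singles = [int(v) for v in col if (v & (v - 1)) == 0]
        if not singles:
            continue
        counts: dict[int, int] = {}
        for v in singles:
            counts[v] = counts.get(v, 0) + 1
        out[c] = len(singles) - max(counts.values())
    return out


def ci_ri(root: trees.Node, matrix: ParsimonyMatrix
          ) -> tuple[float, float]:
    """Ensemble consistency and retention indices, uninformative characters
    included.  An all-invariant matrix yields CI = RI = 1 (degenerate)."""
    obs = fitch_counts(root, matrix).astype(float)
    m = min_changes(matrix).astype(float)
    g = max_changes(matrix).astype(float)
    w = matrix.weights
    length = float((obs * w).sum())
    if length == 0:
        return 1.0, 1.0
    ci = float((m * w).sum()) / length
    denom = float((g * w).sum()) - float((m * w).sum())
    ri = 1.0 if denom == 0 else (float((g * w).sum()) - length) / denom
    return ci, ri


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------

@dataclass
class SearchResult:
    best_score: float
    trees: list[trees.Node]
    replicate_scores: list[float]
    seed: int | None = None

    def __post_init__(self):
        if self.best_score < 0:
            raise ValueError("negative parsimony score")

    def consensus(self) -> trees.Node:
        return trees.strict_consensus(self.trees)


@dataclass
class SearchConfig:
    n_builds: int = 4
    swap: str = "SPR"
    ratchet_iterations: int = 0
    keep_max: int = 10_000
    max_rounds: int = 20


def _wagner_build(taxa: Sequence[str], score: Callable[[trees.Node], float],
                  rng: np.random.Generator) -> trees.Node:
    order = [taxa[int(i)] for i in rng.permutation(len(taxa))]
    tree = trees.star_tree(order[:3])
    for t in order[3:]:
        best_edge, best_s = None, math.inf
        for edge in trees._attachment_edges(tree):
            mid = trees._insert_leaf(edge, trees.Node(t, 1.0))
            s = score(tree)
            trees._remove_leaf(mid)
            if s < best_s:
                best_s, best_edge = s, edge
        trees._insert_leaf(best_edge, trees.Node(t, 1.0))
    return tree


def _tbr_neighbors(root: trees.Node):
    """SPR plus rerooting of the pruned subtree at each of its edges."""
    yield from trees.spr_neighbors(root)
    # rerooted variants: approximate TBR by also yielding SPR moves applied
    # to trees rerooted at each leaf edge (changing which vertex of the
    # pruned part faces the reattachment point)
    for leaf in root.leaf_labels()[:4]:
        rerooted = trees.reroot_at_leaf_edge(root, leaf)
        yield from trees.spr_neighbors(rerooted)


def _swap_to_optimum(start: trees.Node, score: Callable, swap: str,
                     cfg: SearchConfig,
                     ) -> tuple[float, list[trees.Node]]:
    """Branch swapping to a local optimum, collecting equally-optimal
    distinct topologies."""
    best_s = score(start)
    best: list[trees.Node] = [start]
    best_ids = {trees.topology_id(start)}
    swap = swap.upper()
    if swap == "TBR":
        neighbor_fn = _tbr_neighbors
    elif swap == "NNI":
        neighbor_fn = trees.nni_neighbors
    else:
        neighbor_fn = trees.spr_neighbors
    for _ in range(cfg.max_rounds):
        improved = False
        for tree in list(best):
            for cand in neighbor_fn(tree):
                s = score(cand)
                if s < best_s - 1e-9:
                    best_s, best = s, [cand]
                    best_ids = {trees.topology_id(cand)}
                    improved = True
                    break
                if abs(s - best_s) <= 1e-9 and len(best) < cfg.keep_max:
                    tid = trees.topology_id(cand)
                    if tid not in best_ids:
                        best_ids.add(tid)
                        best.append(cand)
            if improved:
                break
        if not improved:
            break
    return best_s, best


def heuristic_search(matrix: ParsimonyMatrix | None,
                     taxa: Sequence[str] | None = None,
                     config: SearchConfig | None = None,
                     seed: int = 0,
                     score_fn: Callable[[trees.Node], float] | None = None,
                     ) -> SearchResult:
    """Random-addition builds + branch swapping (+ optional ratchet).

    Scoring comes either from ``matrix`` (weighted Fitch) or an arbitrary
    ``score_fn`` (used for direct-optimization and combined scoring); the
    ratchet applies only with a matrix, since it perturbs column weights.
    Deterministic under a fixed seed.
    """
    cfg = config or SearchConfig()
    if score_fn is None:
        if matrix is None:
            raise ValueError("need a matrix or a score_fn")
        score_fn = lambda t: fitch_length(t, matrix, True)  # noqa: E731
        taxa = taxa or list(matrix.taxa)
    if taxa is None:
        raise ValueError("taxa required with score_fn")
    taxa = list(taxa)
    if len(taxa) < 4:
        tree = trees.star_tree(taxa)
        s = score_fn(tree)
        return SearchResult(s, [tree], [s], seed)
    rng = np.random.default_rng(seed)
    overall_best = math.inf
    kept: list[trees.Node] = []
    kept_ids: set = set()
    rep_scores = []
    for _ in range(cfg.n_builds):
        tree = _wagner_build(taxa, score_fn, rng)
        s, local = _swap_to_optimum(tree, score_fn, cfg.swap, cfg)
        if matrix is not None and cfg.ratchet_iterations:
            s, local = _ratchet(local[0], matrix, cfg, rng, s, local)
        rep_scores.append(s)
        if s < overall_best - 1e-9:
            overall_best, kept, kept_ids = s, [], set()
        if abs(s - overall_best) <= 1e-9:
            for t in local:
                tid = trees.topology_id(t)
                if tid not in kept_ids and len(kept) < cfg.keep_max:
                    kept_ids.add(tid)
                    kept.append(t)
    return SearchResult(overall_best, kept, rep_scores, seed)


def _ratchet(start: trees.Node, matrix: ParsimonyMatrix, cfg: SearchConfig,
             rng: np.random.Generator, best_s: float,
             best: list[trees.Node]):
    current = start
    for _ in range(cfg.ratchet_iterations):
        boost = rng.random(matrix.n_columns) < 0.25
        perturbed = ParsimonyMatrix(matrix.taxa, matrix.data,
                                    matrix.weights * np.where(boost, 2.0, 1.0),
                                    matrix.full_masks)
        _, ptrees = _swap_to_optimum(
            current, lambda t: fitch_length(t, perturbed, True), cfg.swap, cfg)
        s, local = _swap_to_optimum(
            ptrees[0], lambda t: fitch_length(t, matrix, True), cfg.swap, cfg)
        if s < best_s - 1e-9:
            best_s, best = s, local
            current = local[0]
        elif abs(s - best_s) <= 1e-9:
            ids = {trees.topology_id(t) for t in best}
            for t in local:
                if trees.topology_id(t) not in ids and len(best) < cfg.keep_max:
                    best.append(t)
    return best_s, best


def exhaustive_search(matrix: ParsimonyMatrix | None,
                      taxa: Sequence[str] | None = None,
                      score_fn: Callable[[trees.Node], float] | None = None,
                      ) -> SearchResult:
    """Score every unrooted topology (feasible to ~9 taxa)."""
    if score_fn is None:
        score_fn = lambda t: fitch_length(t, matrix, True)  # noqa: E731
        taxa = taxa or list(matrix.taxa)
    best_s, best = math.inf, []
    for tree in trees.enumerate_unrooted(list(taxa)):
        s = score_fn(tree)
        if s < best_s - 1e-9:
            best_s, best = s, [tree]
        elif abs(s - best_s) <= 1e-9:
            best.append(tree)
    return SearchResult(best_s, best, [best_s])


# ---------------------------------------------------------------------------
# Tree fusing
# ---------------------------------------------------------------------------

def _clade_nodes(root: trees.Node) -> dict[frozenset, trees.Node]:
    out = {}
    sets: dict[int, frozenset] = {}
    for n in root.postorder():
        if n.is_leaf:
            sets[id(n)] = frozenset([n.label])
        else:
            sets[id(n)] = frozenset().union(*(sets[id(c)] for c in n.children))
            if n.parent is not None:
                out[sets[id(n)]] = n
    return out


def tree_fuse(source_trees: Sequence[trees.Node],
              score_fn: Callable[[trees.Node], float],
              max_rounds: int = 10) -> SearchResult:
    """Exchange subtrees with identical leaf sets between tree pairs,
    keeping improvements; the final score never exceeds the best input."""
    if len(source_trees) < 1:
        raise ValueError("no trees to fuse")
    taxa0 = frozenset(source_trees[0].leaf_labels())
    for t in source_trees[1:]:
        if frozenset(t.leaf_labels()) != taxa0:
            raise ValueError("leaf-set mismatch between trees")
    pool = [t.copy() for t in source_trees]
    scores = [score_fn(t) for t in pool]
    best_s = min(scores)
    improved = True
    rounds = 0
    while improved and rounds < max_rounds:
        improved = False
        rounds += 1
        order = np.argsort(scores)
        for ai in order:
            for bi in order:
                if ai == bi:
                    continue
                a, b = pool[ai], pool[bi]
                ca, cb = _clade_nodes(a), _clade_nodes(b)
                for clade in set(ca) & set(cb):
                    donor = cb[clade]
                    host = ca[clade]
                    # rooted-clade comparison sees 3-leaf rearrangements
                    # that unrooted bipartitions cannot
                    if set(trees.clades(donor)) == set(trees.clades(host)):
                        continue
                    cand = a.copy()
                    cand_nodes = _clade_nodes(cand)
                    target = cand_nodes[clade]
                    parent = target.parent
                    idx = parent.children.index(target)
                    replacement = donor.copy()
                    replacement.length = target.length
                    parent.children[idx] = replacement
                    replacement.parent = parent
                    s = score_fn(cand)
                    if s < scores[ai] - 1e-9:
                        pool[ai] = cand
                        scores[ai] = s
                        best_s = min(best_s, s)
                        improved = True
                        break
                if improved:
                    break
            if improved:
                break
    winners = [t for t, s in zip(pool, scores) if abs(s - best_s) <= 1e-9]
    uniq, ids = [], set()
    for t in winners:
        tid = trees.topology_id(t)
        if tid not in ids:
            ids.add(tid)
            uniq.append(t)
    return SearchResult(best_s, uniq, scores)


# ---------------------------------------------------------------------------
# Supports
# ---------------------------------------------------------------------------

def strict_consensus(tree_list: Sequence[trees.Node]) -> trees.Node:
    return trees.strict_consensus(list(tree_list))


def jackknife(matrix: ParsimonyMatrix, reps: int = 100,
              deletion_prob: float = math.exp(-1), seed: int = 0,
              config: SearchConfig | None = None) -> dict[frozenset, float]:
    """Clade support from searches on column-resampled matrices.

    Each column is deleted independently with probability ``deletion_prob``
    (Farris's e^-1 by default); support of a split is its frequency among
    the replicate strict consensi, in percent.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    cfg = config or SearchConfig(n_builds=1)
    rng = np.random.default_rng(seed)
    taxa = sorted(matrix.taxa)
    counts: dict[frozenset, int] = {}
    for r in range(reps):
        keep = np.nonzero(rng.random(matrix.n_columns) >= deletion_prob)[0]
        if len(keep) == 0:
            continue
        sub = matrix.subset(keep)
        res = heuristic_search(sub, config=cfg,
                               seed=int(rng.integers(2 ** 31)))
        cons = trees.strict_consensus(res.trees)
        for split in trees.bipartitions(cons, taxa):
            counts[split] = counts.get(split, 0) + 1
    return {split: 100.0 * c / reps for split, c in counts.items()}


def bremer(best_trees: Sequence[trees.Node], matrix: ParsimonyMatrix,
           config: SearchConfig | None = None, seed: int = 0,
           score_fn: Callable[[trees.Node], float] | None = None,
           from_best: bool = True) -> dict[frozenset, float]:
    """Decay index per clade of the strict consensus of the best trees:
    (best score among trees lacking the clade) - (best score), found by
    reverse-constraint (penalised) searches.

    ``from_best`` restarts the penalised swap from the optimal trees (the
    usual cheap variant); otherwise independent penalised searches are run
    from random-addition builds.
    """
    cfg = config or SearchConfig(n_builds=2)
    if score_fn is None:
        score_fn = lambda t: fitch_length(t, matrix)  # noqa: E731
    taxa = sorted(best_trees[0].leaf_labels())
    best_score = min(score_fn(t) for t in best_trees)
    cons = trees.strict_consensus(list(best_trees))
    out: dict[frozenset, float] = {}
    for split in trees.bipartitions(cons, taxa):
        leafset = split

        def penalised(tree, _s=leafset):
            s = score_fn(tree)
            # partial trees during Wagner building may lack clade members
            if _s <= frozenset(tree.leaf_labels()) and \
                    trees.has_clade(tree, _s):
                s += BIG_PENALTY
            return s

        if from_best:
            without = math.inf
            for start in best_trees[:2]:
                s, _ = _swap_to_optimum(start.copy(), penalised, cfg.swap,
                                        cfg)
                without = min(without, s)
        else:
            without = heuristic_search(None, taxa=taxa, config=cfg,
                                       seed=seed,
                                       score_fn=penalised).best_score
        out[split] = without - best_score
    return out
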