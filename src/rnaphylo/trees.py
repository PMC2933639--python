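"""Lightweight phylogenetic trees.

An unrooted tree is stored rooted at an arbitrary internal vertex (usually
trifurcating), which is the natural form for post-order algorithms such as
Fitch scoring and Felsenstein pruning under reversible models, where the
rooting is immaterial.  Newick parsing is delegated to :mod:`dendropy`;
topology comparison goes through non-trivial bipartitions normalised on a
reference taxon.
"""
from __future__ import annotations

from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np


class Node:
    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    # -- construction -----------------------------------------------------
    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def detach(self) -> "Node":
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None
        return self

    # -- traversal --------------------------------------------------------
    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        stack, out = [self], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return reversed(out)

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def copy(self) -> "Node":
        new = Node(self.label, self.length)
        for c in self.children:
            new.add(c.copy())
        return new

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {to_newick(self, lengths=False)}>"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _from_dendropy(dnode) -> Node:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.label:
        label = dnode.label
    node = Node(label, dnode.edge.length)
    for child in dnode.child_nodes():
        node.add(_from_dendropy(child))
    return node


def from_newick(newick: str) -> Node:
    """Parse a Newick string into a :class:`Node` tree."""
    dtree = dendropy.Tree.get(data=newick, schema="newick",
                              preserve_underscores=True)
    return _from_dendropy(dtree.seed_node)


def to_newick(node: Node, lengths: bool = True) -> str:
    def fmt(n: Node) -> str:
        if n.is_leaf:
            s = n.label or ""
        else:
            s = "(" + ",".join(fmt(c) for c in n.children) + ")"
            if n.label:
                s += n.label
        if lengths and n.length is not None:
            s += f":{n.length:.10g}"
        return s

    return fmt(node) + ";"


# ---------------------------------------------------------------------------
# Bipartitions / comparison / consensus
# ---------------------------------------------------------------------------

def clades(root: Node) -> list[frozenset]:
    """Leaf sets of every non-root internal node (rooted clades)."""
    out = []
    sets: dict[int, frozenset] = {}
    for n in root.postorder():
        if n.is_leaf:
            sets[id(n)] = frozenset([n.label])
        else:
            sets[id(n)] = frozenset().union(*(sets[id(c)] for c in n.children))
            if n is not root:
                out.append(sets[id(n)])
    return out


def bipartitions(root: Node, taxa: Sequence[str] | None = None) -> frozenset:
    """Non-trivial splits, each encoded as the side excluding the reference
    taxon (the lexicographic minimum).  Two trees are the same unrooted
    topology iff their bipartition sets are equal."""
    all_taxa = frozenset(taxa if taxa is not None else root.leaf_labels())
    ref = min(all_taxa)
    n = len(all_taxa)
    out = set()
    for clade in clades(root):
        side = clade if ref not in clade else all_taxa - clade
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return frozenset(out)


def same_topology(a: Node, b: Node) -> bool:
    ta = frozenset(a.leaf_labels())
    if ta != frozenset(b.leaf_labels()):
        return False
    return bipartitions(a, ta) == bipartitions(b, ta)


def rf_distance(a: Node, b: Node) -> int:
    taxa = frozenset(a.leaf_labels())
    return len(bipartitions(a, taxa) ^ bipartitions(b, taxa))


def topology_id(root: Node) -> frozenset:
    return bipartitions(root)


def build_from_clades(clade_sets: Iterable[frozenset], taxa: Sequence[str]) -> Node:
    """Assemble a rooted (possibly multifurcating) tree from mutually
    compatible clades.  Splits normalised to exclude the reference taxon nest
    as clades when the tree is rooted on the reference side."""
    taxa = sorted(taxa)
    root = Node()
    leafset: dict[int, frozenset] = {}
    for t in taxa:
        leaf = root.add(Node(t))
        leafset[id(leaf)] = frozenset([t])
    leafset[id(root)] = frozenset(taxa)
    for clade in sorted(set(clade_sets), key=len, reverse=True):
        clade = frozenset(clade)
        if len(clade) < 2 or len(clade) >= len(taxa):
            continue
        # descend to the deepest node whose leaf set contains the clade
        host = root
        descended = True
        while descended:
            descended = False
            for c in host.children:
                if not c.is_leaf and clade <= leafset[id(c)]:
                    host = c
                    descended = True
                    break
        new = Node()
        for c in [c for c in host.children if leafset[id(c)] <= clade]:
            c.detach()
            new.add(c)
        host.add(new)
        leafset[id(new)] = clade
    return root


def consensus_tree(split_sets: Sequence[frozenset], taxa: Sequence[str],
                   min_freq: float = 1.0) -> Node:
    """Consensus from per-tree bipartition sets.

    ``min_freq=1.0`` gives the strict consensus; ``0.5`` the majority rule.
    In majority rule a split must occur with frequency strictly above 0.5
    (exact 50/50 ties are excluded); compatible minority splits are *not*
    added (plain, not greedy-extended, majority rule).
    """
    taxa = sorted(taxa)
    counts: dict[frozenset, int] = {}
    for s in split_sets:
        for split in s:
            counts[split] = counts.get(split, 0) + 1
    n = len(split_sets)
    chosen: list[frozenset] = []
    for split, c in sorted(counts.items(),
                           key=lambda kv: (-kv[1], sorted(kv[0]))):
        freq = c / n
        keep = (freq >= 1.0) if min_freq >= 1.0 else (freq > min_freq)
        if keep and all(_compatible(split, other) for other in chosen):
            chosen.append(split)
    return build_from_clades(chosen, taxa)


def _compatible(a: frozenset, b: frozenset) -> bool:
    # both sides exclude the reference taxon: containment or disjointness
    return a <= b or b <= a or not (a & b)


def strict_consensus(trees: Sequence[Node]) -> Node:
    taxa = sorted(trees[0].leaf_labels())
    return consensus_tree([bipartitions(t, taxa) for t in trees], taxa, 1.0)


def majority_consensus(trees: Sequence[Node]) -> Node:
    taxa = sorted(trees[0].leaf_labels())
    return consensus_tree([bipartitions(t, taxa) for t in trees], taxa, 0.5)


def has_clade(root: Node, leafset: Iterable[str]) -> bool:
    """Is ``leafset`` one side of some (possibly trivial) bipartition?"""
    taxa = frozenset(root.leaf_labels())
    target = frozenset(leafset)
    if not target or not target <= taxa:
        raise ValueError("clade leaves not in tree")
    if len(target) in (1, len(taxa), len(taxa) - 1):
        return True
    ref = min(taxa)
    side = target if ref not in target else taxa - target
    return side in bipartitions(root, taxa)


def mrca_clade(root: Node, some_leaves: Iterable[str]) -> frozenset:
    """Leaf set of the smallest rooted clade containing ``some_leaves``."""
    want = frozenset(some_leaves)
    best = frozenset(root.leaf_labels())
    for clade in clades(root):
        if want <= clade and len(clade) < len(best):
            best = clade
    return best


# ---------------------------------------------------------------------------
# Generation / enumeration
# ---------------------------------------------------------------------------

def _attachment_edges(root: Node) -> list[Node]:
    """Every node except the root represents the edge to its parent."""
    return [n for n in root.postorder() if n is not root]


def _insert_leaf(edge_child: Node, leaf: Node) -> Node:
    """Split the edge above ``edge_child`` and hang ``leaf``; returns the new
    internal node (for undo)."""
    parent = edge_child.parent
    idx = parent.children.index(edge_child)
    mid = Node()
    if edge_child.length is not None:
        mid.length = edge_child.length / 2.0
        edge_child.length = edge_child.length / 2.0
    parent.children[idx] = mid
    mid.parent = parent
    edge_child.parent = mid
    mid.children.append(edge_child)
    mid.add(leaf)
    return mid


def _remove_leaf(mid: Node) -> None:
    """Undo :func:`_insert_leaf`: ``mid`` has children [edge_child, leaf]."""
    edge_child, leaf = mid.children
    parent = mid.parent
    idx = parent.children.index(mid)
    if edge_child.length is not None and mid.length is not None:
        edge_child.length = edge_child.length + mid.length
    parent.children[idx] = edge_child
    edge_child.parent = parent
    mid.children = []
    mid.parent = None
    leaf.parent = None


def star_tree(taxa: Sequence[str]) -> Node:
    root = Node()
    for t in taxa:
        root.add(Node(t, 1.0))
    return root


def enumerate_unrooted(taxa: Sequence[str]) -> Iterator[Node]:
    """All distinct unrooted binary topologies ((2n-5)!! of them)."""
    taxa = list(taxa)
    if len(taxa) < 4:
        yield star_tree(taxa)
        return

    def rec(tree: Node, remaining: list[str]) -> Iterator[Node]:
        if not remaining:
            yield tree.copy()
            return
        t, rest = remaining[0], remaining[1:]
        for edge in _attachment_edges(tree):
            mid = _insert_leaf(edge, Node(t, 1.0))
            yield from rec(tree, rest)
            _remove_leaf(mid)

    yield from rec(star_tree(taxa[:3]), taxa[3:])


def n_unrooted(n: int) -> int:
    out = 1
    for k in range(4, n + 1):
        out *= 2 * k - 5
    return out


def random_topology(taxa: Sequence[str], rng: np.random.Generator) -> Node:
    """Random unrooted binary topology by random stepwise addition."""
    taxa = list(taxa)
    order = [int(i) for i in rng.permutation(len(taxa))]
    tree = star_tree([taxa[i] for i in order[:3]])
    for i in order[3:]:
        edges = _attachment_edges(tree)
        edge = edges[int(rng.integers(len(edges)))]
        _insert_leaf(edge, Node(taxa[i], 1.0))
    return tree


def yule_tree(taxa: Sequence[str], birth_rate: float,
              rng: np.random.Generator) -> Node:
    """Pure-birth (Yule) tree; leaf labels assigned in random order."""
    taxa = list(taxa)
    n = len(taxa)
    root = Node()
    split_time: dict[int, float] = {id(root): 0.0}
    tips = [root.add(Node()), root.add(Node())]
    t_now = 0.0
    while len(tips) < n:
        t_now += rng.exponential(1.0 / (birth_rate * len(tips)))
        i = int(rng.integers(len(tips)))
        parent = tips.pop(i)
        split_time[id(parent)] = t_now
        tips.append(parent.add(Node()))
        tips.append(parent.add(Node()))
    t_end = t_now + rng.exponential(1.0 / (birth_rate * len(tips)))
    for node in root.preorder():
        if node is root:
            continue
        t_parent = split_time[id(node.parent)]
        t_node = split_time.get(id(node), t_end)
        node.length = t_node - t_parent
    order = rng.permutation(n)
    for leaf, i in zip(root.leaves(), order):
        leaf.label = taxa[int(i)]
    return root


def scale_branches(root: Node, factor: float) -> Node:
    for n in root.postorder():
        if n.length is not None:
            n.length *= factor
    return root


def total_branch_length(root: Node) -> float:
    return sum(n.length or 0.0 for n in root.postorder() if n is not root)


# ---------------------------------------------------------------------------
# Rearrangement moves
# ---------------------------------------------------------------------------

def _paths(node: Node, path: tuple[int, ...] = ()):
    yield path, node
    for i, c in enumerate(node.children):
        yield from _paths(c, path + (i,))


def _node_at(root: Node, path: tuple[int, ...]) -> Node:
    n = root
    for i in path:
        n = n.children[i]
    return n


def nni_neighbors(root: Node) -> list[Node]:
    """All trees one nearest-neighbour interchange away (2 per internal
    edge).  Operates on copies; the input tree is untouched."""
    out = []
    for path, node in list(_paths(root)):
        if node is root or node.is_leaf:
            continue
        parent_path = path[:-1]
        for ci in range(len(node.children)):
            tree = root.copy()
            pnode = _node_at(tree, parent_path)
            nnode = _node_at(tree, path)
            siblings = [c for c in pnode.children if c is not nnode]
            if not siblings:
                continue
            sib = siblings[0]
            child = nnode.children[ci]
            pi = pnode.children.index(sib)
            nnode.children[ci] = sib
            sib.parent = nnode
            pnode.children[pi] = child
            child.parent = pnode
            out.append(tree)
    return out


def random_nni(root: Node, rng: np.random.Generator) -> Node | None:
    """One uniformly drawn NNI neighbour (a copy; input untouched)."""
    choices = [(path, ci)
               for path, node in _paths(root)
               if path and not node.is_leaf
               for ci in range(len(node.children))]
    if not choices:
        return None
    path, ci = choices[int(rng.integers(len(choices)))]
    tree = root.copy()
    nnode = _node_at(tree, path)
    pnode = _node_at(tree, path[:-1])
    siblings = [c for c in pnode.children if c is not nnode]
    if not siblings:
        return None
    sib = siblings[int(rng.integers(len(siblings)))]
    child = nnode.children[ci]
    pi = pnode.children.index(sib)
    nnode.children[ci] = sib
    sib.parent = nnode
    pnode.children[pi] = child
    child.parent = pnode
    return tree


def random_spr(root: Node, rng: np.random.Generator) -> Node | None:
    """One randomly drawn SPR neighbour (a copy; input untouched)."""
    all_paths = [p for p, n in _paths(root) if p]
    for _ in range(20):  # rejection sampling over invalid pairs
        prune_path = all_paths[int(rng.integers(len(all_paths)))]
        target_path = all_paths[int(rng.integers(len(all_paths)))]
        if target_path[:len(prune_path)] == prune_path:
            continue
        tree = root.copy()
        sub = _node_at(tree, prune_path)
        target = _node_at(tree, target_path)
        parent = sub.parent
        sub.detach()
        _suppress_unary(parent)
        if _is_detached(target, tree) or target.parent is None:
            continue
        mid = _insert_leaf(target, Node())
        placeholder = mid.children[1]
        placeholder.parent = None
        mid.children[1] = sub
        sub.parent = mid
        if sub.length is None:
            sub.length = 1.0
        if len(tree.children) >= 2:
            return tree
    return None


def _suppress_unary(node: Node) -> None:
    """Splice out a vertex left with a single child after pruning."""
    while node is not None and len(node.children) == 1 and node.parent is not None:
        child = node.children[0]
        if child.length is not None and node.length is not None:
            child.length += node.length
        parent = node.parent
        idx = parent.children.index(node)
        parent.children[idx] = child
        child.parent = parent
        node.children = []
        node.parent = None
        node = parent
    if node is not None and node.parent is None and len(node.children) == 1:
        # root left unary: promote grandchildren
        child = node.children[0]
        if child.is_leaf:
            return
        node.children = child.children
        for c in node.children:
            c.parent = node
        child.children = []
        child.parent = None


def _find_root(node: Node) -> Node:
    n = node
    while n.parent is not None:
        n = n.parent
    return n


def _reroot_at_node(tree: Node, node: Node) -> Node:
    """Reverse parent pointers in place so a fresh binary root sits on the
    edge above ``node``; returns the new root."""
    if node.parent is None:
        return node
    path = []
    n = node
    while n is not None:
        path.append(n)
        n = n.parent
    new_root = Node()
    ln = node.length or 0.0
    node.detach()
    new_root.add(node)
    node.length = ln / 2.0
    prev, carry = new_root, ln / 2.0
    for nd in path[1:]:
        nd.detach()
        prev.add(nd)
        old_len = nd.length
        nd.length = carry
        carry = old_len
        prev = nd
    for n in list(new_root.postorder()):
        if not n.is_leaf and len(n.children) == 1:
            _suppress_unary(n)
    return new_root


def spr_neighbors(root: Node) -> Iterator[Node]:
    """Complete subtree-prune-regraft neighbourhood (yields copies).

    Both sides of every edge are prunable: rooted subtrees directly, and
    root-containing complements by first rerooting along the edge.
    """
    all_paths = [p for p, n in _paths(root) if p]
    for prune_path in all_paths:
        for target_path in all_paths:
            if target_path[:len(prune_path)] == prune_path:
                continue
            tree = root.copy()
            sub = _node_at(tree, prune_path)
            target = _node_at(tree, target_path)
            parent = sub.parent
            sub.detach()
            _suppress_unary(parent)
            if _is_detached(target, tree) or target.parent is None:
                continue
            mid = _insert_leaf(target, Node())
            placeholder = mid.children[1]
            placeholder.parent = None
            mid.children[1] = sub
            sub.parent = mid
            if sub.length is None:
                sub.length = 1.0
            if len(tree.children) >= 2:
                yield tree
    # complement moves: prune the root-containing side of an edge and
    # regraft it inside the clade side
    for edge_path in all_paths:
        probe = _node_at(root, edge_path)
        if probe.is_leaf or len(probe.children) < 2:
            continue
        tree = root.copy()
        clade_top = _node_at(tree, edge_path)
        new_root = _reroot_at_node(tree, clade_top)
        kids = new_root.children
        if len(kids) != 2:
            continue
        comp = kids[0] if kids[1] is clade_top else kids[1]
        comp.detach()
        clade_top.detach()
        clade_top.parent = None
        if comp.length is None:
            comp.length = 1.0
        inner = [n for n in clade_top.postorder() if n is not clade_top]
        for target in inner:
            cand = clade_top.copy()
            # locate the matching node in the copy by traversal order
            orig_nodes = [n for n in clade_top.postorder()]
            copy_nodes = [n for n in cand.postorder()]
            t2 = copy_nodes[orig_nodes.index(target)]
            mid = _insert_leaf(t2, Node())
            placeholder = mid.children[1]
            placeholder.parent = None
            comp2 = comp.copy()
            mid.children[1] = comp2
            comp2.parent = mid
            yield cand


def _is_detached(node: Node, root: Node) -> bool:
    n = node
    while n.parent is not None:
        n = n.parent
    return n is not root


def reroot_at_leaf_edge(root: Node, leaf_label: str) -> Node:
    """Return a copy rerooted so the named leaf is a child of the root
    (rooting along its pendant edge)."""
    tree = root.copy()
    leaf = next(n for n in tree.postorder() if n.label == leaf_label and n.is_leaf)
    if leaf.parent is tree:
        return tree
    # reverse parent pointers along the path leaf -> old root
    path = []
    n = leaf
    while n is not None:
        path.append(n)
        n = n.parent
    new_root = Node()
    lf_len = leaf.length or 0.0
    leaf.detach()
    new_root.add(leaf)
    leaf.length = lf_len / 2.0
    prev = new_root
    carry = lf_len / 2.0
    for node in path[1:]:
        # node loses its edge toward the leaf side; reattach below prev
        parent = node.parent
        node.detach()
        prev.add(node)
        old_len = node.length
        node.length = carry
        carry = old_len
        prev = node
    # the old root may now be unary
    for n in list(new_root.postorder()):
        if not n.is_leaf and len(n.children) == 1:
            _suppress_unary(n)
    return new_root
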