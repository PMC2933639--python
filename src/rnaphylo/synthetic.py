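"""Ground-truth synthetic datasets with the statistical structure the
pipeline assumes.

A Yule tree is drawn; stem regions evolve as coevolving base pairs under a
7-state pair model (projected to two bracket-masked nucleotide columns),
loops evolve independently under GTR+I+G with A-rich stationary
frequencies (mirroring the adenosine bias of unpaired rRNA regions),
designated segments evolve under a substitution + geometric-indel process
yielding length-variable regions emitted both as ``*``-masked alignment
blocks and as unaligned fragment sets, one designated clade loses a helix
(giving a lineage-restricted helix plus a presence/absence character
truth), and a morphological matrix evolves under the Mk model on the same
tree.  Everything is seeded and emitted in the same formats the I/O layer
reads, so every pipeline stage can be tested against a known answer
without any external data.

The default configuration is a strong-signal, reduced-scale stand-in for
the kind of data the pipeline targets: 16 taxa, about 320 pre-aligned
columns (60 stem pairs in four helices + 200 loop sites), three ambiguous
regions and 18 Mk characters, on a Yule tree whose internal branches are
floored so every split leaves a recoverable signal.  Full-pipeline runs
stay fast while topology recovery is expected to succeed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import trees
from .alignments import (GAP, FragmentSet, MorphMatrix, StructuredAlignment)
from .annotation import StructureCharacter
from .models import GTRIG, NUC, PAIR7_STATES, Paired7A, Paired16A

#: loop frequencies echo the adenosine enrichment of unpaired regions
LOOP_FREQS = (0.383, 0.171, 0.219, 0.227)  # A, C, G, U
#: pair-state frequencies favour canonical pairs, G:C-rich as in stems
STEM7_FREQS = (0.10, 0.12, 0.27, 0.22, 0.13, 0.10, 0.06)


@dataclass
class SimulationConfig:
    n_taxa: int = 16
    birth_rate: float = 1.0
    branch_scale: float = 0.5  # mean root-to-tip substitutions per site
    min_branch_length: float = 0.08  # floor; keeps every split resolvable
    tree_newick: str | None = None  # overrides the Yule draw
    n_stem_pairs: int = 60
    n_helices: int = 4
    n_loop_sites: int = 200
    stem_model: str = "7A"  # or "16A"
    stem_frequencies: Sequence[float] = STEM7_FREQS
    loop_frequencies: Sequence[float] = LOOP_FREQS
    loop_gamma_shape: float = 0.8
    loop_p_invariant: float = 0.2
    n_ambiguous_regions: int = 3
    ambiguous_mean_length: int = 8
    indel_rate: float = 0.35       # relative to the substitution rate
    indel_length_p: float = 0.5    # geometric length parameter
    helix_loss_pairs: int = 4      # lineage-restricted helix size
    helix_loss_fraction: float = 0.33  # clade size targeted for the loss
    n_morph_characters: int = 18
    morph_states: int = 2
    morph_rate: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")
        for name in ("n_stem_pairs", "n_loop_sites", "n_ambiguous_regions",
                     "n_morph_characters"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.indel_rate <= 0 or self.morph_rate <= 0:
            raise ValueError("rates must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    true_tree: trees.Node
    alignment: StructuredAlignment
    fragments: list[FragmentSet]
    morphology: MorphMatrix
    structure_character: StructureCharacter
    helix_loss_clade: frozenset
    region_bounds: list[tuple[int, int]]
    helix_name: str = "L"


def _stem_model(cfg: SimulationConfig):
    if cfg.stem_model == "7A":
        rng = np.random.default_rng(1234)  # fixed exchangeability pattern
        ex = tuple(0.3 + rng.random(21))
        return Paired7A(exchangeabilities=ex,
                        frequencies=tuple(cfg.stem_frequencies))
    freqs = list(cfg.stem_frequencies)
    if len(freqs) != 16:
        # spread the 7-state shape over 16 dinucleotides
        from .models import CANONICAL_PAIRS, PAIR16_STATES
        f = dict(zip(CANONICAL_PAIRS, freqs[:6]))
        mm = freqs[6] / 10.0
        freqs = [f.get(s, mm) for s in PAIR16_STATES]
        freqs = [x / sum(freqs) for x in freqs]
    return Paired16A(frequencies=tuple(freqs))


def _loop_model(cfg: SimulationConfig) -> GTRIG:
    rng = np.random.default_rng(4321)
    ex = tuple(0.5 + rng.random(6))
    return GTRIG(exchangeabilities=ex,
                 frequencies=tuple(cfg.loop_frequencies),
                 p_invariant=cfg.loop_p_invariant,
                 gamma_shape=cfg.loop_gamma_shape)


def _mismatch_dinuc(rng) -> str:
    from .models import CANONICAL_PAIRS
    while True:
        d = NUC[rng.integers(4)] + NUC[rng.integers(4)]
        if d not in CANONICAL_PAIRS:
            return d


def _pair_state_to_dinuc(state: str, rng) -> str:
    return _mismatch_dinuc(rng) if state == "MM" else state


def _evolve_indel_segment(tree: trees.Node, root_len: int,
                          model: GTRIG, indel_rate: float, length_p: float,
                          rng) -> dict[str, str]:
    """Substitution + symmetric insertion/deletion process on one segment.

    Indels arrive as a Poisson process at ``indel_rate`` per site per unit
    branch length with geometric lengths; substitutions follow the loop
    model.  Returns the unaligned leaf sequences.
    """
    q = model.rate_matrix()
    root = [int(rng.choice(4, p=model.freqs)) for _ in range(root_len)]
    out: dict[str, str] = {}

    def evolve(seq: list[int], t: float) -> list[int]:
        seq = list(seq)
        if t <= 0:
            return seq
        p = model.transition_probabilities(t)
        seq = [int(rng.choice(4, p=p[s])) for s in seq]
        n_events = rng.poisson(indel_rate * t * max(len(seq), 1))
        for _ in range(n_events):
            length = int(rng.geometric(length_p))
            if rng.random() < 0.5 and len(seq) > length:
                pos = int(rng.integers(len(seq) - length + 1))
                del seq[pos:pos + length]
            else:
                pos = int(rng.integers(len(seq) + 1))
                ins = [int(rng.choice(4, p=model.freqs))
                       for _ in range(length)]
                seq[pos:pos] = ins
        return seq

    def walk(node, seq):
        for child in node.children:
            cseq = evolve(seq, child.length or 0.0)
            if child.is_leaf:
                out[child.label] = "".join(NUC[s] for s in cseq)
            else:
                walk(child, cseq)

    walk(tree, root)
    return out


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate one fully known dataset (see module docstring)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    taxa = [f"t{i + 1:02d}" for i in range(cfg.n_taxa)]
    if cfg.tree_newick:
        tree = trees.from_newick(cfg.tree_newick)
    else:
        tree = trees.yule_tree(taxa, cfg.birth_rate, rng)
        # normalise the mean root-to-tip path to branch_scale substitutions;
        # a floor keeps every internal edge long enough to leave a signal
        depth = _mean_depth(tree)
        if depth > 0:
            trees.scale_branches(tree, cfg.branch_scale / depth)
        for n in tree.postorder():
            if n is not tree and n.length is not None:
                n.length = max(n.length, cfg.min_branch_length)

    stem_model = _stem_model(cfg)
    loop_model = _loop_model(cfg)

    # --- stems: coevolving pair columns --------------------------------
    pair_states = stem_model.simulate(tree, cfg.n_stem_pairs, rng)
    state_names = stem_model.states
    pair_chars = {t: [_pair_state_to_dinuc(state_names[s], rng)
                      for s in pair_states[t]]
                  for t in taxa} if cfg.n_stem_pairs else {t: [] for t in taxa}

    # --- loops ----------------------------------------------------------
    weights, rates = loop_model.rate_mixture()
    site_rates = rng.choice(rates, size=cfg.n_loop_sites, p=weights)
    loop_states = loop_model.simulate(tree, cfg.n_loop_sites, rng,
                                      rates=site_rates) \
        if cfg.n_loop_sites else {t: np.zeros(0, int) for t in taxa}

    # --- lineage-restricted helix --------------------------------------
    clade = _pick_clade(tree, cfg.helix_loss_fraction, rng)
    sub_tree = _induced_subtree(tree, clade)
    helix_pairs = cfg.helix_loss_pairs
    helix_cols: dict[str, list[str]] = {t: ["-"] * (2 * helix_pairs)
                                        for t in taxa}
    if helix_pairs and len(clade) >= 2:
        helix_states = stem_model.simulate(sub_tree, helix_pairs, rng)
        for t in clade:
            dinucs = [_pair_state_to_dinuc(state_names[s], rng)
                      for s in helix_states[t]]
            for k, d in enumerate(dinucs):
                helix_cols[t][k] = d[0]
                helix_cols[t][2 * helix_pairs - 1 - k] = d[1]

    # --- ambiguous regions ----------------------------------------------
    regions = []
    for r in range(cfg.n_ambiguous_regions):
        seqs = _evolve_indel_segment(tree, cfg.ambiguous_mean_length,
                                     loop_model, cfg.indel_rate,
                                     cfg.indel_length_p, rng)
        regions.append(FragmentSet(f"RAA{r + 1}", seqs))

    # --- assemble the alignment -----------------------------------------
    helices_per = max(cfg.n_helices, 1)
    pairs_per_helix = cfg.n_stem_pairs // helices_per if cfg.n_stem_pairs \
        else 0
    loop_chunk = (cfg.n_loop_sites // (helices_per + 1)
                  if cfg.n_loop_sites else 0)
    cols: dict[str, list[str]] = {t: [] for t in taxa}
    mask: list[str] = []
    helix_mask: list[str] = []
    region_bounds: list[tuple[int, int]] = []
    loop_used = pair_used = 0
    helix_names = "ABCDEFGHIJ"

    def emit_loops(k):
        nonlocal loop_used
        k = min(k, cfg.n_loop_sites - loop_used)
        for _ in range(k):
            for t in taxa:
                cols[t].append(NUC[int(loop_states[t][loop_used])])
            mask.append(".")
            helix_mask.append("")
            loop_used += 1

    def emit_region(idx):
        frag = regions[idx]
        width = max((len(s) for s in frag.sequences.values()), default=0)
        start = len(mask)
        for c in range(width):
            for t in taxa:
                s = frag.sequences[t]
                cols[t].append(s[c] if c < len(s) else GAP)
            mask.append("*")
            helix_mask.append("")
        region_bounds.append((start, len(mask)))

    region_slots = list(range(cfg.n_ambiguous_regions))
    for h in range(helices_per):
        emit_loops(loop_chunk)
        npairs = pairs_per_helix if h < helices_per - 1 else \
            cfg.n_stem_pairs - pair_used
        name = helix_names[h % len(helix_names)]
        # opening strand
        for k in range(npairs):
            for t in taxa:
                cols[t].append(pair_chars[t][pair_used + k][0])
            mask.append("(")
            helix_mask.append(name)
        # hairpin loop content: an ambiguous region when available
        if region_slots:
            emit_region(region_slots.pop(0))
        else:
            emit_loops(3)
        for k in reversed(range(npairs)):
            for t in taxa:
                cols[t].append(pair_chars[t][pair_used + k][1])
            mask.append(")")
            helix_mask.append(name)
        pair_used += npairs
    # lineage-restricted helix block
    hl_name = "L"
    if helix_pairs:
        for k in range(helix_pairs):
            for t in taxa:
                cols[t].append(helix_cols[t][k])
            mask.append("(")
            helix_mask.append(hl_name)
        for k in range(helix_pairs, 2 * helix_pairs):
            for t in taxa:
                cols[t].append(helix_cols[t][k])
            mask.append(")")
            helix_mask.append(hl_name)
    emit_loops(cfg.n_loop_sites - loop_used)
    # any leftover ambiguous regions go at the tail
    while region_slots:
        emit_region(region_slots.pop(0))

    aln = StructuredAlignment(
        taxa=list(taxa),
        sequences={t: "".join(cols[t]) for t in taxa},
        pairing_mask="".join(mask),
        helix_mask=helix_mask)

    # --- morphology ------------------------------------------------------
    morph = _simulate_morphology(tree, taxa, cfg, rng)

    char = StructureCharacter(
        hl_name, {t: ("0" if t in clade else "1") for t in taxa})

    return SyntheticDataset(cfg, tree, aln, regions, morph, char,
                            clade, region_bounds, hl_name)


def _mean_depth(tree: trees.Node) -> float:
    depths = []

    def walk(node, d):
        for c in node.children:
            nd = d + (c.length or 0.0)
            if c.is_leaf:
                depths.append(nd)
            else:
                walk(c, nd)

    walk(tree, 0.0)
    return float(np.mean(depths)) if depths else 0.0


def _pick_clade(tree: trees.Node, fraction: float, rng) -> frozenset:
    n = len(tree.leaf_labels())
    target = max(2, int(round(n * fraction)))
    best, best_diff = None, 1e9
    for clade in trees.clades(tree):
        diff = abs(len(clade) - target)
        if diff < best_diff:
            best, best_diff = clade, diff
    return frozenset(best) if best else frozenset(tree.leaf_labels()[:target])


def _induced_subtree(tree: trees.Node, keep: frozenset) -> trees.Node:
    def prune(node):
        new = trees.Node(node.label, node.length)
        for c in node.children:
            sub = prune(c)
            if sub is not None:
                new.add(sub)
        if new.is_leaf and (node.children or node.label not in keep):
            return None
        return new

    pruned = prune(tree)
    # suppress unary internal vertices
    def simplify(node):
        while len(node.children) == 1 and not node.children[0].is_leaf:
            child = node.children[0]
            if child.length and node.length:
                child.length += node.length
            node.children = child.children
            for c in node.children:
                c.parent = node
        for c in node.children:
            if len(c.children) == 1:
                gc = c.children[0]
                gc.length = (gc.length or 0) + (c.length or 0)
                idx = node.children.index(c)
                node.children[idx] = gc
                gc.parent = node
                simplify(node)
                return
        for c in node.children:
            simplify(c)

    simplify(pruned)
    return pruned


def _simulate_morphology(tree, taxa, cfg: SimulationConfig, rng
                         ) -> MorphMatrix:
    k = cfg.morph_states
    freqs = tuple(1.0 / k for _ in range(k))
    matrix = {t: [] for t in taxa}
    for _ in range(cfg.n_morph_characters):
        # Mk: all rates equal; reuse the GTR machinery on k states via a
        # direct transition formula P(same) = 1/k + (1-1/k) e^{-k r t/(k-1)}
        root_state = int(rng.integers(k))

        def walk(node, state):
            for child in node.children:
                t_len = (child.length or 0.0) * cfg.morph_rate
                p_change = (1 - np.exp(-k * t_len / (k - 1))) * (k - 1) / k
                s = state
                if rng.random() < p_change:
                    s = int((state + 1 + rng.integers(k - 1)) % k)
                if child.is_leaf:
                    matrix[child.label].append(str(s))
                else:
                    walk(child, s)

        walk(tree, root_state)
    return MorphMatrix(list(taxa), matrix)


def truth_report(ds: SyntheticDataset) -> dict:
    """Machine-readable key for recovery tests."""
    return {
        "tree_newick": trees.to_newick(ds.true_tree),
        "splits": trees.bipartitions(ds.true_tree),
        "region_bounds": list(ds.region_bounds),
        "helix_loss_clade": set(ds.helix_loss_clade),
        "helix_name": ds.helix_name,
        "seed": ds.config.seed,
    }
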