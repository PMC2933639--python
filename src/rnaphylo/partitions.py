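"""Turn an annotated alignment, fragment files and morphology into the
partition sets each analysis mode consumes, and summarize the pre-aligned
matrix.

Modes
-----
``traditional``
    Static columns only (ambiguous regions discarded); parsimony with gaps
    as a fifth state.
``bayesian``
    The same static columns, split stem/loop for the mixed models.
``standard_do``
    Everything treated dynamically: raw sequences spliced into blocks at
    conserved anchors, every block a direct-optimization fragment.
``constrained_do``
    Static columns stay static; each REC/RAA/RSC interval becomes a
    fragment (rows gap-stripped, per-interval taxon scope respected);
    excluded columns are dropped; structure characters appended.

Summary statistics follow the usual conventions: a position is conserved
when exactly one nucleotide state is observed (gaps and missing data
ignored), variable otherwise, and parsimony-informative when at least two
states each occur in at least two taxa.  By default gaps are *not* counted
as a state for these counts even though tree search scores them as a fifth
state; ``gap_is_state=True`` switches the convention.  Base composition is
reported overall and split into stem/loop contexts from the pairing mask.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alignments import (AMBIGUOUS, GAP, MISSING, FragmentSet, MorphMatrix,
                         StructuredAlignment)
from .annotation import (EXCLUDED, PRE, RAA, REC, RSC, RegionAnnotation,
                         StructureCharacter)

MODES = ("traditional", "bayesian", "standard_do", "constrained_do")


@dataclass
class PartitionSet:
    mode: str
    static_stem_columns: list[int] = field(default_factory=list)
    static_loop_columns: list[int] = field(default_factory=list)
    do_fragments: list[FragmentSet] = field(default_factory=list)
    structure_characters: list[StructureCharacter] = field(default_factory=list)
    morphology: MorphMatrix | None = None
    morphology_weight: float = 1.0
    alignment: StructuredAlignment | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        overlap = set(self.static_stem_columns) & set(self.static_loop_columns)
        if overlap:
            raise ValueError(f"columns in both static sets: {sorted(overlap)[:5]}")
        if self.mode in ("traditional", "bayesian") and self.do_fragments:
            raise ValueError(f"mode {self.mode} admits no DO fragments")
        if self.mode == "standard_do" and (self.static_stem_columns
                                           or self.static_loop_columns):
            raise ValueError("standard_do mode admits no static columns")

    @property
    def static_columns(self) -> list[int]:
        return sorted(self.static_stem_columns + self.static_loop_columns)


def strip_gaps(seq: str) -> str:
    return "".join(ch for ch in seq if ch not in (GAP, MISSING))


def fragment_from_interval(aln: StructuredAlignment, start: int, end: int,
                           name: str,
                           taxon_scope: Iterable[str] | None = None
                           ) -> FragmentSet:
    scope = frozenset(taxon_scope) if taxon_scope else frozenset(aln.taxa)
    seqs = {t: strip_gaps(aln.sequences[t][start:end])
            for t in aln.taxa if t in scope}
    return FragmentSet(name, seqs, frozenset(seqs))


def build_partitions(aln: StructuredAlignment,
                     annotation: RegionAnnotation | None,
                     mode: str,
                     fragments: Sequence[FragmentSet] = (),
                     morphology: MorphMatrix | None = None,
                     structure_characters: Sequence[StructureCharacter] = (),
                     anchors: Sequence[str] | Mapping[str, Sequence[int]] = (),
                     ) -> PartitionSet:
    """Assemble the :class:`PartitionSet` for one analysis mode."""
    if mode == "standard_do":
        raw = {t: strip_gaps(aln.sequences[t]) for t in aln.taxa}
        blocks = splice_at_anchors(raw, anchors)
        return PartitionSet(mode=mode, do_fragments=list(blocks) + list(fragments),
                            morphology=morphology,
                            structure_characters=list(structure_characters),
                            alignment=aln)
    if annotation is None:
        raise ValueError(f"mode {mode!r} requires a region annotation")
    partner = aln.partner()
    stem_cols, loop_cols = [], []
    for col in annotation.columns_of_kind(PRE):
        (stem_cols if col in partner else loop_cols).append(col)
    do_frags: list[FragmentSet] = []
    if mode == "constrained_do":
        for k, iv in enumerate(annotation.ambiguous_intervals()):
            frag = fragment_from_interval(
                aln, iv.start, iv.end,
                name=f"{iv.kind}_{iv.start + 1}_{iv.end}",
                taxon_scope=iv.taxon_scope)
            do_frags.append(frag)
        do_frags.extend(fragments)
    return PartitionSet(
        mode=mode,
        static_stem_columns=stem_cols,
        static_loop_columns=loop_cols,
        do_fragments=do_frags,
        structure_characters=list(structure_characters),
        morphology=morphology,
        alignment=aln,
    )


def splice_at_anchors(raw_sequences: Mapping[str, str],
                      anchors: Sequence[str] | Mapping[str, Sequence[int]],
                      ) -> list[FragmentSet]:
    """Cut each raw sequence into blocks at conserved anchors.

    ``anchors`` is either a list of exact-match motifs (each >= 8 nt and
    found exactly once per sequence) or a per-taxon list of cut
    coordinates.  ``k`` anchors produce ``k + 1`` blocks; with motifs the
    cut is placed at the motif start, so the motif opens the next block.
    """
    taxa = sorted(raw_sequences)
    cuts: dict[str, list[int]] = {}
    if isinstance(anchors, Mapping):
        for t in taxa:
            cuts[t] = sorted(anchors[t])
    else:
        motifs = list(anchors)
        for m in motifs:
            if len(m) < 8:
                raise ValueError(f"anchor motif {m!r} shorter than 8 nt")
        for t in taxa:
            seq = raw_sequences[t]
            pos = []
            for m in motifs:
                hits = _find_all(seq, m)
                if len(hits) != 1:
                    raise ValueError(
                        f"anchor {m!r} found {len(hits)} times in taxon "
                        f"{t!r} (need exactly one)")
                pos.append(hits[0])
            cuts[t] = sorted(pos)
    n_blocks = len(next(iter(cuts.values()))) + 1 if cuts else 1
    for t in taxa:
        if len(cuts[t]) != n_blocks - 1:
            raise ValueError(f"taxon {t!r}: inconsistent number of cuts")
    blocks = []
    for b in range(n_blocks):
        seqs = {}
        for t in taxa:
            bounds = [0] + cuts[t] + [len(raw_sequences[t])]
            seqs[t] = raw_sequences[t][bounds[b]:bounds[b + 1]]
        blocks.append(FragmentSet(f"block_{b + 1}", seqs))
    return blocks


def _find_all(seq: str, motif: str) -> list[int]:
    out, start = [], 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def split_region_with_core(aln: StructuredAlignment, start: int, end: int,
                           core_columns: Sequence[int],
                           scope: Iterable[str],
                           name: str = "D3_1",
                           ) -> tuple[StructuredAlignment | None,
                                      list[FragmentSet]]:
    """Split a length-variable region into a pre-aligned covarying core and
    two flanking direct-optimization fragments.

    ``core_columns`` are alignment columns (within [start, end)) whose
    homology is supported by covariation; ``scope`` lists the taxa
    possessing the structure.  Taxa in scope whose core residues are not
    contiguous in their raw sequence cannot keep the pre-aligned core and
    are demoted to DO-only for the whole region.  Returns the core as an
    alignment restricted to the scoped taxa plus the left/right fragments;
    taxa outside the scope contribute the whole region to the left
    fragment (their residues are not comparable with the core).
    """
    core = sorted(core_columns)
    scope = frozenset(scope)
    if any(c < start or c >= end for c in core):
        raise ValueError("core columns outside region")
    if not core:
        left = fragment_from_interval(aln, start, end, f"{name}_do")
        return None, [left]
    demoted = set()
    for t in scope:
        row = aln.sequences[t]
        # core must map to a contiguous residue run: no residue may sit in
        # a region gap between the core columns
        inside = [c for c in range(min(core), max(core) + 1) if c not in core]
        if any(row[c] not in (GAP, MISSING) for c in inside):
            import warnings
            warnings.warn(f"taxon {t!r}: core not contiguous after gap "
                          f"stripping; demoted to DO-only")
            demoted.add(t)
    kept = scope - demoted
    core_aln = None
    if kept:
        sub = aln.subset_columns(core)
        core_aln = StructuredAlignment(
            taxa=[t for t in sub.taxa if t in kept],
            sequences={t: sub.sequences[t] for t in sub.taxa if t in kept},
            pairing_mask=sub.pairing_mask,
            helix_mask=sub.helix_mask)
    lo, hi = min(core), max(core) + 1
    left_seqs, right_seqs = {}, {}
    for t in aln.taxa:
        if t in kept:
            left_seqs[t] = strip_gaps(aln.sequences[t][start:lo])
            right_seqs[t] = strip_gaps(aln.sequences[t][hi:end])
        else:
            left_seqs[t] = strip_gaps(aln.sequences[t][start:end])
            right_seqs[t] = ""
    left = FragmentSet(f"{name}_left", left_seqs)
    right = FragmentSet(f"{name}_right", right_seqs)
    return core_aln, [left, right]


@dataclass
class AlignmentSummary:
    n_positions: int
    n_conserved: int
    n_variable: int
    n_parsimony_informative: int
    composition_overall: dict
    composition_stems: dict
    composition_loops: dict

    def __post_init__(self):
        assert self.n_conserved + self.n_variable == self.n_positions
        for comp in (self.composition_overall, self.composition_stems,
                     self.composition_loops):
            if comp:
                total = sum(comp.values())
                if abs(total - 100.0) > 0.1:
                    raise ValueError(f"composition sums to {total}")


def summarize_alignment(aln: StructuredAlignment,
                        columns: Sequence[int] | None = None,
                        gap_is_state: bool = False,
                        count_all_gap_columns: bool = False
                        ) -> AlignmentSummary:
    """Conservation/informativeness counts and base composition for the
    selected (pre-aligned) columns."""
    cols = list(columns) if columns is not None else list(range(aln.n_columns))
    if not cols:
        raise ValueError("empty column selection")
    partner = aln.partner()
    n_positions = n_conserved = n_informative = 0
    counts_overall = {b: 0 for b in "UCAG"}
    counts_stem = {b: 0 for b in "UCAG"}
    counts_loop = {b: 0 for b in "UCAG"}
    for c in cols:
        states: dict[str, int] = {}
        for t in aln.taxa:
            ch = aln.sequences[t][c]
            if ch in counts_overall:
                counts_overall[ch] += 1
                (counts_stem if c in partner else counts_loop)[ch] += 1
            if ch in (MISSING, "N"):
                continue
            if ch == GAP:
                if gap_is_state:
                    states[GAP] = states.get(GAP, 0) + 1
                continue
            if ch in "ACGU":
                states[ch] = states.get(ch, 0) + 1
            # other ambiguity codes are ignored for the counts
        if not states and not count_all_gap_columns:
            continue  # all-gap/missing column: not a position
        n_positions += 1
        if len(states) <= 1:
            n_conserved += 1
        else:
            if sum(1 for v in states.values() if v >= 2) >= 2:
                n_informative += 1

    def pct(counts: dict) -> dict:
        total = sum(counts.values())
        if total == 0:
            return {}
        return {b: 100.0 * v / total for b, v in counts.items()}

    return AlignmentSummary(
        n_positions=n_positions,
        n_conserved=n_conserved,
        n_variable=n_positions - n_conserved,
        n_parsimony_informative=n_informative,
        composition_overall=pct(counts_overall),
        composition_stems=pct(counts_stem),
        composition_loops=pct(counts_loop),
    )


def residue_conservation_check(aln: StructuredAlignment,
                               parts: PartitionSet,
                               annotation: RegionAnnotation | None) -> bool:
    """Audit: per taxon, residues in (static + DO + excluded) pieces equal
    the residues of the input row."""
    for t in aln.taxa:
        total = len(strip_gaps(aln.sequences[t]))
        static = sum(1 for c in parts.static_columns
                     if aln.sequences[t][c] not in (GAP, MISSING))
        frag = sum(len(f.sequences.get(t, "")) for f in parts.do_fragments)
        excluded = 0
        if annotation is not None:
            for c in annotation.columns_of_kind(EXCLUDED):
                if aln.sequences[t][c] not in (GAP, MISSING):
                    excluded += 1
        if static + frag + excluded != total:
            return False
    return True
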