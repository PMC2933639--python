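"""Region classification and helix-homology auditing.

Columns flagged ``*`` in the pairing mask form regions of ambiguous
alignment.  Maximal runs of such columns are subtyped by their structural
context: a run flanking a helix terminus is a region of expansion and
contraction (REC); an interior unpaired run is a non-pairing region of
ambiguous alignment (RAA); regions of slipped-strand compensation (RSC)
cannot be diagnosed from the masks alone and are accepted only through
expert overrides.  RAAs sitting in a hairpin (terminal) loop are lumped
with the adjacent REC, because nucleotides can migrate between the stem tip
and the loop, and are handed to direct optimization as one fragment.

Helix homology is audited by covariation: a base-pair bond is considered
supported when at least two distinct canonical pair types (A:U, U:A, G:C,
C:G, G:U, U:G) occur across the taxa — i.e. at least one compensatory or
semi-compensatory substitution is observed.  Protonated A:C pairs are
counted as mismatches by default (toggleable).  A helix confined to one
lineage is not globally homologous: its columns can be excluded from every
structure-aware analysis, and its presence/absence coded as a morphology-
like binary character (1 = helix absent).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .alignments import (AMBIGUOUS, GAP, MISSING, StructuredAlignment,
                         StructureError)
from .models import CANONICAL_PAIRS

PRE = "PRE"
REC = "REC"
RAA = "RAA"
RSC = "RSC"
EXCLUDED = "EXCLUDED"
KINDS = (PRE, REC, RAA, RSC, EXCLUDED)


@dataclass(frozen=True)
class Interval:
    """Half-open column interval [start, end) of one region kind."""

    start: int
    end: int
    kind: str
    taxon_scope: frozenset | None = None  # None = all taxa

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown region kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval ({self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class RegionAnnotation:
    """Ordered intervals tiling the column range without overlap."""

    n_columns: int
    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self):
        self.intervals.sort(key=lambda iv: iv.start)
        pos = 0
        for iv in self.intervals:
            if iv.start != pos:
                raise ValueError("intervals do not tile the column range")
            pos = iv.end
        if pos != self.n_columns:
            raise ValueError("intervals do not tile the column range")

    def kinds(self) -> list[str]:
        out = []
        for iv in self.intervals:
            out.extend([iv.kind] * len(iv))
        return out

    def columns_of_kind(self, *kinds: str) -> list[int]:
        return [c for iv in self.intervals if iv.kind in kinds
                for c in range(iv.start, iv.end)]

    def ambiguous_intervals(self) -> list[Interval]:
        return [iv for iv in self.intervals if iv.kind in (REC, RAA, RSC)]


def _merge_adjacent_same_kind(intervals: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for iv in sorted(intervals, key=lambda iv: iv.start):
        if (out and out[-1].kind == iv.kind
                and out[-1].end == iv.start
                and out[-1].taxon_scope == iv.taxon_scope):
            out[-1] = replace(out[-1], end=iv.end)
        else:
            out.append(iv)
    return out


def read_overrides(path) -> list[Interval]:
    """Tab-separated override file: start, end (1-based inclusive), kind,
    optional space-separated taxon scope."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        start, end, kind = int(parts[0]) - 1, int(parts[1]), parts[2]
        scope = frozenset(parts[3].split()) if len(parts) > 3 and parts[3] \
            else None
        out.append(Interval(start, end, kind, scope))
    return out


def classify_regions(aln: StructuredAlignment,
                     overrides: Iterable[Interval] | None = None
                     ) -> RegionAnnotation:
    """Classify maximal ``*`` runs as REC/RAA (RSC only by override); all
    remaining columns are PRE."""
    n = aln.n_columns
    mask = aln.pairing_mask
    is_pair = [ch in "(){}<>" for ch in mask]
    intervals: list[Interval] = []
    col = 0
    while col < n:
        if mask[col] == AMBIGUOUS:
            start = col
            while col < n and mask[col] == AMBIGUOUS:
                col += 1
            left_paired = start > 0 and is_pair[start - 1]
            right_paired = col < n and is_pair[col]
            kind = REC if (left_paired or right_paired) else RAA
            intervals.append(Interval(start, col, kind))
        else:
            start = col
            while col < n and mask[col] != AMBIGUOUS:
                col += 1
            intervals.append(Interval(start, col, PRE))
    annotation = RegionAnnotation(n, intervals)
    if overrides:
        annotation = apply_overrides(annotation, overrides)
    return annotation


def apply_overrides(annotation: RegionAnnotation,
                    overrides: Iterable[Interval]) -> RegionAnnotation:
    """Re-kind columns according to override intervals (e.g. RSC calls,
    exclusions); overrides may split existing intervals."""
    n = annotation.n_columns
    kinds = annotation.kinds()
    scopes: list[frozenset | None] = [None] * n
    for iv in annotation.intervals:
        for c in range(iv.start, iv.end):
            scopes[c] = iv.taxon_scope
    for ov in overrides:
        if ov.end > n:
            raise ValueError(
                f"override interval ({ov.start + 1}, {ov.end}) outside "
                f"alignment of {n} columns")
        for c in range(ov.start, ov.end):
            kinds[c] = ov.kind
            scopes[c] = ov.taxon_scope
    intervals = []
    col = 0
    while col < n:
        start = col
        while (col < n and kinds[col] == kinds[start]
               and scopes[col] == scopes[start]):
            col += 1
        intervals.append(Interval(start, col, kinds[start], scopes[start]))
    return RegionAnnotation(n, _merge_adjacent_same_kind(intervals))


def _hairpin_loops(aln: StructuredAlignment) -> list[tuple[int, int]]:
    """Half-open column ranges strictly between the innermost bonds of each
    hairpin: (i, j) is a hairpin-closing bond when no bond nests inside."""
    bonds = aln.pair_bonds()
    loops = []
    for (i, j) in bonds:
        if not any(i < a and b < j for a, b in bonds if (a, b) != (i, j)):
            if j - i > 1:
                loops.append((i + 1, j))
    return loops


def lump_terminal_raa(aln: StructuredAlignment,
                      annotation: RegionAnnotation) -> RegionAnnotation:
    """Merge each RAA lying inside a hairpin (terminal) loop with an
    adjacent REC; the merged interval inherits kind REC.  Idempotent."""
    loops = _hairpin_loops(aln)
    intervals = list(annotation.intervals)
    changed = True
    while changed:
        changed = False
        for k, iv in enumerate(intervals):
            if iv.kind != RAA:
                continue
            in_loop = any(lo <= iv.start and iv.end <= hi for lo, hi in loops)
            if not in_loop:
                continue
            neighbors = [m for m in (k - 1, k + 1)
                         if 0 <= m < len(intervals)
                         and intervals[m].kind == REC]
            if not neighbors:
                continue
            m = neighbors[0]
            lo = min(intervals[k].start, intervals[m].start)
            hi = max(intervals[k].end, intervals[m].end)
            merged = Interval(lo, hi, REC, intervals[m].taxon_scope)
            for idx in sorted((k, m), reverse=True):
                del intervals[idx]
            intervals.append(merged)
            intervals.sort(key=lambda iv: iv.start)
            changed = True
            break
    return RegionAnnotation(annotation.n_columns,
                            _merge_adjacent_same_kind(intervals))


@dataclass
class BondSupport:
    """Covariation evidence for one base-pair bond."""

    columns: tuple[int, int]
    pair_type_counts: dict
    n_mismatch_rows: int
    supported: bool  # >= 2 distinct canonical pair types observed
    compensatory: bool  # alias of supported, kept for reporting clarity

    @property
    def n_pair_types(self) -> int:
        return len(self.pair_type_counts)


def covariation_support(aln: StructuredAlignment,
                        columns: Sequence[int] | None = None,
                        protonated_ac_canonical: bool = False
                        ) -> list[BondSupport]:
    """Per-bond pair-type counts for the given helix columns (default: all
    paired columns).  A bond is supported when >= 2 distinct canonical pair
    types occur across taxa; A:C may optionally count as (semi-)canonical.
    """
    partner = aln.partner()
    if columns is None:
        bonds = aln.pair_bonds()
    else:
        colset = set(columns)
        for c in colset:
            if c not in partner:
                raise StructureError(f"column {c + 1} is not paired")
        bonds = sorted({tuple(sorted((c, partner[c]))) for c in colset})
    canonical = set(CANONICAL_PAIRS)
    if protonated_ac_canonical:
        canonical |= {"AC", "CA"}
    out = []
    for i, j in bonds:
        counts: dict[str, int] = {}
        mismatches = 0
        for t in aln.taxa:
            a, b = aln.sequences[t][i], aln.sequences[t][j]
            if a in (GAP, MISSING, "N") or b in (GAP, MISSING, "N"):
                continue
            pair = a + b
            if pair in canonical:
                counts[pair] = counts.get(pair, 0) + 1
            else:
                mismatches += 1
        supported = len(counts) >= 2
        out.append(BondSupport((i, j), counts, mismatches, supported,
                               supported))
    return out


def helix_support_fraction(aln: StructuredAlignment, helix: str,
                           **kw) -> float:
    cols = aln.helix_columns(helix)
    bonds = covariation_support(aln, [c for c in cols if c in aln.partner()],
                                **kw)
    if not bonds:
        raise StructureError(f"helix {helix!r} has no paired columns")
    return sum(b.supported for b in bonds) / len(bonds)


@dataclass
class StructureCharacter:
    """Presence/absence of a secondary-structure element, coded with the
    polarity 1 = helix absent, 0 = present, ? = no data."""

    name: str
    scores: dict[str, str]


def code_helix_character(aln: StructuredAlignment, helix: str,
                         present_taxa: Iterable[str]) -> StructureCharacter:
    """Score the helix presence/absence character for every taxon.

    A taxon with no residues at all in the helix columns is scored ``?``.
    """
    cols = aln.helix_columns(helix)
    if not cols:
        raise StructureError(f"helix {helix!r} not in helix mask")
    present = frozenset(present_taxa)
    scores = {}
    for t in aln.taxa:
        if t in present:
            scores[t] = "0"
        else:
            residues = [aln.sequences[t][c] for c in cols]
            if all(ch in (GAP, MISSING) for ch in residues):
                scores[t] = "?"
            else:
                scores[t] = "1"
    if len(set(scores.values())) == 1:
        warnings.warn(f"structure character {helix!r} is invariant "
                      f"(parsimony-uninformative)")
    return StructureCharacter(helix, scores)


def exclude_lineage_specific(aln: StructuredAlignment,
                             annotation: RegionAnnotation, helix: str,
                             scope: Iterable[str]) -> RegionAnnotation:
    """Mark the columns of a lineage-restricted helix EXCLUDED for all
    structure-aware analyses."""
    scope = frozenset(scope)
    cols = aln.helix_columns(helix)
    if not cols:
        raise StructureError(f"helix {helix!r} not in helix mask")
    if scope >= frozenset(aln.taxa):
        warnings.warn(f"helix {helix!r} scope covers all taxa; "
                      f"nothing excluded")
        return annotation
    overrides = []
    start = cols[0]
    prev = cols[0]
    for c in cols[1:] + [None]:
        if c is None or c != prev + 1:
            overrides.append(Interval(start, prev + 1, EXCLUDED, scope))
            if c is not None:
                start = c
        if c is not None:
            prev = c
    return apply_overrides(annotation, overrides)
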