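"""Reading and writing the pipeline's external representations.

The central container is the :class:`StructuredAlignment`: an aligned
residue grid annotated with a secondary-structure *pairing mask* and a
*helix mask*.  The pairing mask uses three bracket families — ``()``,
``{}``, ``<>`` — for nesting levels of paired sites (the third level flags
crossing/tertiary interactions), ``.`` for unpaired columns and ``*`` for
columns inside regions of ambiguous alignment.  Masks travel inside the
FASTA file as ordinary records with reserved IDs (``#pairing`` and
``#helices`` by default; configurable, since conventions vary between
archives).

Unaligned fragments destined for direct optimization are plain FASTA with
an optional ``#scope:`` header line restricting the taxa for which homology
of the fragment is asserted.  Morphology is a tab-separated matrix of
single-character state codes (``0``–``9``; ``?`` and ``-`` are both read as
missing).  Trees are Newick via :mod:`dendropy`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import trees

GAP = "-"
MISSING = "?"
PAIR_OPEN = {"(": 1, "{": 2, "<": 3}
PAIR_CLOSE = {")": 1, "}": 2, ">": 3}
UNPAIRED = "."
AMBIGUOUS = "*"

#: IUPAC nucleotide ambiguity codes over the RNA alphabet
IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
    MISSING: "ACGU",
}


class FormatError(ValueError):
    """Malformed input file."""


class StructureError(ValueError):
    """Inconsistent secondary-structure annotation."""


def expand_residue(ch: str) -> frozenset:
    """State set of a residue character; the gap keeps its own identity."""
    ch = ch.upper().replace("T", "U")
    if ch == GAP:
        return frozenset(GAP)
    try:
        return frozenset(IUPAC[ch])
    except KeyError:
        raise FormatError(f"unknown residue code {ch!r}") from None


@dataclass
class StructuredAlignment:
    """Taxa x columns residue grid plus pairing and helix masks."""

    taxa: list[str]
    sequences: dict[str, str]
    pairing_mask: str
    helix_mask: list[str]  # per-column helix label, '' when blank

    def __post_init__(self) -> None:
        n = self.n_columns
        for t in self.taxa:
            if len(self.sequences[t]) != n:
                raise FormatError(
                    f"record {t!r} has length {len(self.sequences[t])}, "
                    f"expected {n}")
        if len(self.helix_mask) != n:
            raise FormatError("helix mask length mismatch")
        self.pair_bonds()  # validates bracket balance

    @property
    def n_columns(self) -> int:
        return len(self.pairing_mask)

    def pair_bonds(self, max_level: int = 3) -> list[tuple[int, int]]:
        """(i, j) column pairs, i < j, from bracket matching per nesting
        level.  Raises :class:`StructureError` on unbalanced symbols."""
        bonds: list[tuple[int, int]] = []
        stacks: dict[int, list[int]] = {1: [], 2: [], 3: []}
        for col, ch in enumerate(self.pairing_mask):
            if ch in PAIR_OPEN:
                stacks[PAIR_OPEN[ch]].append(col)
            elif ch in PAIR_CLOSE:
                lvl = PAIR_CLOSE[ch]
                if not stacks[lvl]:
                    raise StructureError(
                        f"unbalanced closing symbol {ch!r} at column {col + 1}")
                i = stacks[lvl].pop()
                if lvl <= max_level:
                    bonds.append((i, col))
            elif ch not in (UNPAIRED, AMBIGUOUS):
                raise StructureError(
                    f"unknown pairing symbol {ch!r} at column {col + 1}")
        for lvl, stack in stacks.items():
            if stack:
                raise StructureError(
                    f"unbalanced opening symbol of level {lvl} at column "
                    f"{stack[-1] + 1}")
        return sorted(bonds)

    def tertiary_bonds(self) -> list[tuple[int, int]]:
        """Level-3 (``<>``) bonds, conventionally crossing/tertiary."""
        bonds = []
        stack: list[int] = []
        for col, ch in enumerate(self.pairing_mask):
            if ch == "<":
                stack.append(col)
            elif ch == ">":
                bonds.append((stack.pop(), col))
        return sorted(bonds)

    def partner(self) -> dict[int, int]:
        out = {}
        for i, j in self.pair_bonds():
            out[i] = j
            out[j] = i
        return out

    def column(self, col: int) -> list[str]:
        return [self.sequences[t][col] for t in self.taxa]

    def helix_columns(self, helix: str) -> list[int]:
        return [i for i, h in enumerate(self.helix_mask) if h == helix]

    def helices(self) -> list[str]:
        seen = []
        for h in self.helix_mask:
            if h and h not in seen:
                seen.append(h)
        return seen

    def subset_columns(self, cols: Sequence[int]) -> "StructuredAlignment":
        cols = list(cols)
        keep = set(cols)
        partner = self.partner()
        mask = []
        for c in cols:
            ch = self.pairing_mask[c]
            if c in partner and partner[c] not in keep:
                ch = UNPAIRED  # broken bond: treat as unpaired
            mask.append(ch)
        return StructuredAlignment(
            taxa=list(self.taxa),
            sequences={t: "".join(self.sequences[t][c] for c in cols)
                       for t in self.taxa},
            pairing_mask="".join(mask),
            helix_mask=[self.helix_mask[c] for c in cols],
        )


@dataclass
class FragmentSet:
    """Unaligned sequences for one region of ambiguous alignment.

    ``taxon_scope`` lists the taxa for which homology of the fragment is
    asserted; taxa outside the scope are scored as missing downstream (the
    device used to keep lineage-restricted insertions in separate files).
    """

    name: str
    sequences: dict[str, str]
    taxon_scope: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.taxon_scope:
            self.taxon_scope = frozenset(self.sequences)
        missing = self.taxon_scope - set(self.sequences)
        if missing:
            raise FormatError(
                f"fragment {self.name!r}: scoped taxa without sequences: "
                f"{sorted(missing)}")
        extra = set(self.sequences) - self.taxon_scope
        if extra:
            raise FormatError(
                f"fragment {self.name!r}: sequences outside declared scope: "
                f"{sorted(extra)}")


@dataclass
class MorphMatrix:
    """Discrete multistate characters; ``?`` and ``-`` both mean missing."""

    taxa: list[str]
    matrix: dict[str, list[str]]  # taxon -> per-character state codes
    weights: list[float] = field(default_factory=list)
    ordered: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        ns = {len(v) for v in self.matrix.values()}
        if len(ns) > 1:
            raise FormatError("unequal character counts across taxa")
        n = ns.pop() if ns else 0
        if not self.weights:
            self.weights = [1.0] * n
        if not self.ordered:
            self.ordered = [False] * n
        if any(w < 0 for w in self.weights):
            raise FormatError("negative character weight")
        for t, row in self.matrix.items():
            for k, code in enumerate(row):
                if code not in "0123456789?-":
                    raise FormatError(
                        f"unknown state code {code!r} at taxon {t!r}, "
                        f"character {k + 1}")

    @property
    def n_characters(self) -> int:
        return len(next(iter(self.matrix.values()))) if self.matrix else 0


# ---------------------------------------------------------------------------
# Structured FASTA
# ---------------------------------------------------------------------------

DEFAULT_MASK_IDS = ("#pairing", "#helices")


def read_structured_fasta(path, mask_ids: tuple[str, str] = DEFAULT_MASK_IDS
                          ) -> StructuredAlignment:
    """Read an aligned FASTA whose mask lines are records with reserved IDs.

    ``T`` is normalised to ``U``.  The helix mask uses one character per
    column (``.`` for blank); multi-column helices are runs of the same
    character.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    pairing_id, helices_id = mask_ids
    pairing = helices = None
    taxa, seqs = [], {}
    for rec in records:
        text = str(rec.seq)
        if rec.id == pairing_id:
            pairing = text
        elif rec.id == helices_id:
            helices = text
        else:
            if rec.id in seqs:
                raise FormatError(f"duplicate taxon {rec.id!r}")
            taxa.append(rec.id)
            seqs[rec.id] = text.upper().replace("T", "U")
    if pairing is None:
        raise FormatError(f"{path}: missing pairing mask record "
                          f"{pairing_id!r}")
    n = len(pairing)
    for t in taxa:
        if len(seqs[t]) != n:
            raise FormatError(
                f"{path}: record {t!r} has length {len(seqs[t])}, "
                f"expected {n}")
    if helices is None:
        helices = "." * n
    if len(helices) != n:
        raise FormatError(f"{path}: helix mask length mismatch")
    helix_mask = ["" if ch == "." else ch for ch in helices]
    return StructuredAlignment(taxa, seqs, pairing, helix_mask)


def write_structured_fasta(aln: StructuredAlignment, path,
                           mask_ids: tuple[str, str] = DEFAULT_MASK_IDS) -> None:
    records = [
        SeqRecord(Seq(aln.sequences[t]), id=t, description="") for t in aln.taxa
    ]
    records.append(SeqRecord(Seq(aln.pairing_mask), id=mask_ids[0],
                             description=""))
    helix = "".join(h if h else "." for h in aln.helix_mask)
    records.append(SeqRecord(Seq(helix), id=mask_ids[1], description=""))
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Fragment files
# ---------------------------------------------------------------------------

def read_fragments(path, name: str | None = None) -> FragmentSet:
    path = Path(path)
    scope = None
    fasta_lines = []
    for line in path.read_text().splitlines():
        if line.startswith("#scope:"):
            scope = frozenset(line[len("#scope:"):].split())
        else:
            fasta_lines.append(line)
    sequences: dict[str, str] = {}
    current = None
    for line in fasta_lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            current = line[1:].split()[0]
            if current in sequences:
                raise FormatError(f"{path}: duplicate taxon {current!r}")
            sequences[current] = ""
        elif current is not None:
            sequences[current] += line.upper().replace("T", "U")
    if not sequences:
        warnings.warn(f"{path}: empty fragment file")
    return FragmentSet(name or path.stem, sequences,
                       scope or frozenset(sequences))


def write_fragments(frag: FragmentSet, path) -> None:
    lines = [f"#scope: {' '.join(sorted(frag.taxon_scope))}"]
    for t in sorted(frag.sequences):
        lines.append(f">{t}")
        lines.append(frag.sequences[t])
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Morphology matrices
# ---------------------------------------------------------------------------

def read_morph_matrix(path) -> MorphMatrix:
    """Tab-separated matrix: ``taxon<TAB>state-string`` per row, or one
    column per character.  Lines starting with ``#`` are comments."""
    taxa, matrix = [], {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        taxon = parts[0]
        codes = list("".join(parts[1:]))
        if taxon in matrix:
            raise FormatError(f"{path}: duplicate taxon {taxon!r}")
        taxa.append(taxon)
        matrix[taxon] = codes
    return MorphMatrix(taxa, matrix)


def write_morph_matrix(m: MorphMatrix, path) -> None:
    lines = [f"{t}\t{''.join(m.matrix[t])}" for t in m.taxa]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def read_newick(path) -> list[trees.Node]:
    text = Path(path).read_text()
    return [trees.from_newick(chunk + ";")
            for chunk in text.split(";") if chunk.strip()]


def write_newick(tree_list: Iterable[trees.Node], path,
                 lengths: bool = True) -> None:
    Path(path).write_text(
        "\n".join(trees.to_newick(t, lengths=lengths) for t in tree_list)
        + "\n")
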