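"""Constructed fixture: two data partitions with identical phylogenetic
signal, hence zero incongruence length difference."""
from rnaphylo.alignments import StructuredAlignment
from rnaphylo.parsimony import matrix_from_alignment

TAXA = list("abcdef")
# columns supporting ((a,b),(c,d),(e,f)) — same signal in both halves
COLUMNS = ["AAGGUU", "AAGGCC", "AAUUGG", "CCGGAA"]


def _matrix(columns):
    seqs = {t: "".join(col[i] for col in columns)
            for i, t in enumerate(TAXA)}
    aln = StructuredAlignment(list(TAXA), seqs, "." * len(columns),
                              [""] * len(columns))
    return matrix_from_alignment(aln)


def congruent_matrices():
    """(combined, partition A, partition B) with identical per-partition
    signal."""
    return _matrix(COLUMNS * 2), _matrix(COLUMNS), _matrix(COLUMNS)
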