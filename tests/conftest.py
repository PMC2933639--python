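import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from rnaphylo import trees
from rnaphylo.alignments import StructuredAlignment, FragmentSet, MorphMatrix


@pytest.fixture
def quartet():
    return trees.from_newick("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);")


@pytest.fixture
def toy_alignment():
    """Two hairpins with an ambiguous tip region and a lineage helix."""
    seqs = {
        "a": "AAGGCUUAA***GGCCUUCC",
        "b": "AAGGCUUAA**-GGCCUUCC",
        "c": "AAGGCUUAAA**GGCCUUCC",
        "d": "AAGGCUUAA-**GGCCUUCC",
    }
    #      01234567890123456789
    mask = "..((((...***))))...."
    seqs = {t: s.replace("*", "A") for t, s in seqs.items()}
    helix = ["", "", "H", "H", "H", "H", "", "", "", "", "", "",
             "H", "H", "H", "H", "", "", "", ""]
    mask_cols = list(mask)
    for i in (9, 10, 11):
        mask_cols[i] = "*"
    return StructuredAlignment(list("abcd"), seqs, "".join(mask_cols), helix)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
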