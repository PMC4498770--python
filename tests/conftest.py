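import numpy as np
import pytest

from cystree.alignment_io import AlignedFamily, QueryProtein
from cystree.phylo import read_newick


@pytest.fixture
def small_family():
    """Query MCACCACA with oxidized positions (1, 3, 4, 6) plus homologs.

    h1 keeps all four cysteines, h2 keeps the (1, 3) pair, h3 keeps an odd
    single cysteine, h4 keeps none.
    """
    fam = AlignedFamily(
        rows=(
            ("query", "MCACCACA"),
            ("h1", "MCACCACA"),
            ("h2", "MCACAAAA"),
            ("h3", "MCAAAAAA"),
            ("h4", "MAAAAAAA"),
        ),
        query_row_id="query",
    )
    query = QueryProtein(id="query", sequence="MCACCACA", oxidized_positions=(1, 3, 4, 6))
    return fam, query


def labeled_tree(newick: str, labels: dict[str, str]):
    """A tree whose leaves carry the given bit-string labels."""
    from cystree.labeling import LABEL_ATTR

    tree = read_newick(newick)
    for tip in tree.tips():
        bits = labels[tip.name]
        setattr(tip, LABEL_ATTR, np.array([int(b) for b in bits], dtype=np.uint8))
    return tree


def bits(s: str) -> np.ndarray:
    return np.array([int(c) for c in s], dtype=np.uint8)
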