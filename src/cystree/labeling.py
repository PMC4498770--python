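"""Binary cysteine-presence labels on tree nodes.

Each node of the rooted family tree is annotated with a bit vector of
length |C| (one bit per oxidized query position): leaves read their bits
straight off the aligned sequence, and every inner node receives the
bitwise OR of its children. Under the loss-only model of cysteine
evolution this OR propagation is the maximum-parsimony reconstruction: a
cysteine is inferred present in an ancestor exactly when at least one
descendant still carries it, which charges every loss to the latest
branch that can explain all observations.

Labels are stored on nodes as the ``cys_label`` attribute
(``numpy`` uint8 arrays of 0/1).
"""

from __future__ import annotations

import numpy as np
from skbio import TreeNode

from .alignment_io import AlignedFamily

LABEL_ATTR = "cys_label"


def leaf_label(aligned_row: str, oxidized_columns: tuple[int, ...]) -> np.ndarray:
    """Bit k is 1 iff the row holds a cysteine at oxidized column k."""
    row = aligned_row.upper()
    return np.fromiter(
        (1 if row[c] == "C" else 0 for c in oxidized_columns), dtype=np.uint8
    )


def popcount(label: np.ndarray) -> int:
    return int(np.sum(label))


def set_leaf_labels(tree: TreeNode, family: AlignedFamily) -> TreeNode:
    """Attach leaf labels from the family's aligned rows (in place)."""
    if not family.oxidized_columns:
        raise ValueError("family has no oxidized columns mapped")
    rows = dict(family.rows)
    for tip in tree.tips():
        if tip.name not in rows:
            raise KeyError(f"leaf {tip.name!r} has no row in the family")
        setattr(tip, LABEL_ATTR, leaf_label(rows[tip.name], family.oxidized_columns))
    return tree


def assign_inner_labels(tree: TreeNode) -> TreeNode:
    """Label every inner node with the OR of its children (in place).

    Implemented as one post-order pass; because OR is associative,
    commutative and idempotent this equals the leaf-initiated recursive
    formulation with backtracking, for any child count, and the result is
    independent of child order. Every leaf must already carry a label of
    one common length.
    """
    length = None
    for tip in tree.tips():
        lbl = getattr(tip, LABEL_ATTR, None)
        if lbl is None:
            raise ValueError(f"leaf {tip.name!r} is unlabeled")
        if length is None:
            length = len(lbl)
        elif len(lbl) != length:
            raise ValueError("leaf labels have inconsistent lengths")
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            continue
        if not node.children:
            raise ValueError("internal node with no children")
        acc = np.zeros(length, dtype=np.uint8)
        for child in node.children:
            acc |= getattr(child, LABEL_ATTR)
        setattr(node, LABEL_ATTR, acc)
    return tree


def get_label(node: TreeNode) -> np.ndarray:
    lbl = getattr(node, LABEL_ATTR, None)
    if lbl is None:
        raise ValueError(f"node {node.name!r} has no cysteine label")
    return lbl


def annotated_newick(tree: TreeNode) -> str:
    """Newick with labels as node comments, e.g. ``[&label=1100]`` (debug aid)."""
    def fmt(node: TreeNode) -> str:
        lbl = getattr(node, LABEL_ATTR, None)
        comment = "" if lbl is None else "[&label=%s]" % "".join(map(str, lbl))
        length = "" if node.length is None else f":{node.length:g}"
        if node.is_tip():
            return f"{node.name}{comment}{length}"
        inner = ",".join(fmt(c) for c in node.children)
        return f"({inner}){node.name or ''}{comment}{length}"

    return fmt(tree) + ";"
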