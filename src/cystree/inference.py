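"""Tandem-mutation evidence: from labeled trees to a connectivity graph.

For every leaf the chain of labels from an all-zeros sentinel through the
leaf up to the root is examined step by step. A step where an even number
mu >= 2 of bits flip on (leaf-to-root direction) is read as mu/2
simultaneous tandem cysteine losses (viewed backwards in time): with
mu = 2 the pair is unambiguous and its edge gains weight 1; with mu > 2
the pairing is unresolved and each of the mu(mu-1)/2 candidate edges gains
2/(mu(mu-1)), so an informative step always deposits total weight 1.
Steps with identical labels carry no information, and odd-mu
(parity-breaking) steps are skipped in this model.

Accumulating over all leaves weights each tree edge by the number of leaf
paths that traverse it, i.e. by its descendant leaf count — the production
accumulator exploits this directly; the literal per-leaf walk is kept as
an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .labeling import get_label


@dataclass(frozen=True)
class ConnectivityGraph:
    """Symmetric non-negative weights over all |C| (|C|-1) / 2 candidate bonds."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", W)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(W, W.T):
            raise ValueError("weight matrix must be symmetric")
        if not np.allclose(np.diag(W), 0.0):
            raise ValueError("weight matrix diagonal must be zero")
        if np.any(W < 0):
            raise ValueError("weights must be non-negative")

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum() / 2.0)

    def edge_list(self) -> list[tuple[int, int, float]]:
        n = self.n
        return [(i, j, float(self.weights[i, j])) for i in range(n) for j in range(i + 1, n)]

    def to_tsv(self, oxidized_positions: tuple[int, ...] | None = None) -> str:
        """TSV edge list; positions are reported 1-based when given."""
        lines = ["cys_i\tcys_j\tweight"]
        for i, j, w in self.edge_list():
            a, b = (i, j) if oxidized_positions is None else (
                oxidized_positions[i] + 1,
                oxidized_positions[j] + 1,
            )
            lines.append(f"{a}\t{b}\t{w:.10g}")
        return "\n".join(lines) + "\n"


def parity(label: np.ndarray) -> str:
    """``"even"`` iff the label's popcount is even."""
    return "even" if int(np.sum(label)) % 2 == 0 else "odd"


def root_path_labels(tree: TreeNode, leaf_name: str) -> list[np.ndarray]:
    """Labels from an all-zeros sentinel through the leaf up to the root."""
    leaf = tree.find(leaf_name)
    if not leaf.is_tip():
        raise ValueError(f"{leaf_name!r} is not a leaf")
    path = [np.zeros_like(get_label(leaf))]
    node: TreeNode | None = leaf
    while node is not None:
        path.append(get_label(node))
        node = node.parent
    return path


def compare_step(l_lower: np.ndarray, l_upper: np.ndarray) -> list[tuple[tuple[int, int], float]]:
    """Edge increments for one step of a leaf-to-root label path.

    ``l_lower`` is the label nearer the leaf, ``l_upper`` its parent; bits
    may only switch on going up (loss-only model seen towards the root).
    """
    if len(l_lower) != len(l_upper):
        raise ValueError("label length mismatch")
    gained = np.flatnonzero((l_lower == 0) & (l_upper == 1))
    mu = len(gained)
    if mu == 0 or mu % 2 == 1:
        return []
    if mu == 2:
        return [((int(gained[0]), int(gained[1])), 1.0)]
    w = 2.0 / (mu * (mu - 1))
    return [
        ((int(gained[a]), int(gained[b])), w)
        for a in range(mu)
        for b in range(a + 1, mu)
    ]


def count_informative_steps(path: list[np.ndarray]) -> int:
    """Steps in a label path that deposit weight (mu even, mu >= 2)."""
    count = 0
    for lo, up in zip(path, path[1:]):
        mu = int(np.sum((lo == 0) & (up == 1)))
        if mu >= 2 and mu % 2 == 0:
            count += 1
    return count


def accumulate_weights(tree: TreeNode, n: int) -> ConnectivityGraph:
    """Connectivity graph from all leaf paths (single-pass accumulator).

    Each tree edge (child, parent) contributes its step's increments once
    per leaf under the child; each leaf additionally contributes the
    sentinel-to-leaf step once. Equal to the per-leaf walk, in O(nodes).
    """
    leaves = list(tree.tips())
    if not leaves:
        raise ValueError("tree has no leaves")
    W = np.zeros((n, n))

    def deposit(steps: list[tuple[tuple[int, int], float]], mult: int) -> None:
        for (i, j), w in steps:
            W[i, j] += w * mult
            W[j, i] += w * mult

    zeros = np.zeros(n, dtype=np.uint8)
    n_desc: dict[int, int] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            n_desc[id(node)] = 1
            deposit(compare_step(zeros, get_label(node)), 1)
        else:
            n_desc[id(node)] = sum(n_desc[id(c)] for c in node.children)
        if node.parent is not None:
            deposit(
                compare_step(get_label(node), get_label(node.parent)),
                n_desc[id(node)],
            )
    return ConnectivityGraph(weights=W)


def accumulate_weights_per_leaf(tree: TreeNode, n: int) -> ConnectivityGraph:
    """Literal per-leaf traversal (test oracle for :func:`accumulate_weights`)."""
    leaves = list(tree.tips())
    if not leaves:
        raise ValueError("tree has no leaves")
    W = np.zeros((n, n))
    for leaf in leaves:
        path = root_path_labels(tree, leaf.name)
        for lo, up in zip(path, path[1:]):
            for (i, j), w in compare_step(lo, up):
                W[i, j] += w
                W[j, i] += w
    return ConnectivityGraph(weights=W)
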