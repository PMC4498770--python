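"""Distance matrices, neighbor joining, and outgroup rooting.

Trees are ``skbio.TreeNode`` objects throughout the package: leaves carry
row ids in ``name``, branch lengths live in ``length``, and the labeling
stage attaches cysteine-presence vectors as a ``cys_label`` attribute.

The neighbor-joining implementation is deliberately deterministic: ties in
the Q criterion are broken by the lexicographically smallest pair of
cluster ids (a cluster inherits the smallest leaf id it contains), so the
same distance matrix always yields the same tree.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .alignment_io import GAP_CHARS, AlignedFamily

#: Cap for the Kimura-corrected distance when p >= 0.75 (correction undefined).
KIMURA_MAX_DISTANCE = 10.0


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with row ids."""

    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "ids", tuple(self.ids))
        n = len(self.ids)
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} does not match {n} ids")
        if not np.all(np.isfinite(m)):
            raise ValueError("distance matrix contains non-finite values")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")


def pairwise_distances(family: AlignedFamily, correction: str = "none") -> DistanceMatrix:
    """Pairwise p-distances over an aligned family.

    For each pair of rows only columns where both are non-gap are compared;
    p = 1 - matches / compared. Pairs with no comparable columns get
    distance 1.0. With ``correction="kimura"`` the Kimura protein
    correction d = -ln(1 - p - p^2/5) is applied for p < 0.75 and capped at
    :data:`KIMURA_MAX_DISTANCE` beyond.
    """
    if correction not in ("none", "kimura"):
        raise ValueError(f"unknown distance correction {correction!r}")
    if family.n_rows < 2:
        raise ValueError("need at least 2 rows to compute distances")
    seqs = [s.upper() for _, s in family.rows]
    arr = np.array([list(s) for s in seqs])
    gap = np.isin(arr, list(GAP_CHARS))
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            comp = int(ok.sum())
            if comp == 0:
                p = 1.0
            else:
                p = 1.0 - float((arr[i, ok] == arr[j, ok]).sum()) / comp
            if correction == "kimura":
                if p < 0.75:
                    p = min(-np.log(1.0 - p - p * p / 5.0), KIMURA_MAX_DISTANCE)
                else:
                    p = KIMURA_MAX_DISTANCE
            D[i, j] = D[j, i] = p
    return DistanceMatrix(ids=family.ids, matrix=D)


def _leaf(name: str, length: float | None = None) -> TreeNode:
    node = TreeNode(name=name)
    node.length = length
    return node


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree.

    The final node trifurcates for >= 3 taxa (unrooted convention); 2 taxa
    produce a single edge split evenly. At each step the pair minimizing
    Q(i,j) = (r-2) D(i,j) - R_i - R_j is joined; Q ties are resolved by the
    lexicographically smallest (id, id) pair. Negative branch lengths are
    clamped to zero with the deficit moved to the sister branch.
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        half = dm.matrix[0, 1] / 2.0
        root = TreeNode()
        root.extend([_leaf(dm.ids[0], half), _leaf(dm.ids[1], half)])
        return root

    D = dm.matrix.astype(float).copy()
    nodes: list[TreeNode] = [_leaf(i) for i in dm.ids]
    # tie-break key: smallest leaf id contained in the cluster
    keys: list[str] = list(dm.ids)

    while len(nodes) > 3:
        r = len(nodes)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q <= qmin + 1e-12)
        i, j = min(
            (tuple(sorted((int(a), int(b)))) for a, b in ties),
            key=lambda ij: tuple(sorted((keys[ij[0]], keys[ij[1]]))) + ij,
        )
        li = 0.5 * D[i, j] + (R[i] - R[j]) / (2.0 * (r - 2))
        lj = D[i, j] - li
        if li < 0:
            lj, li = D[i, j], 0.0
        elif lj < 0:
            li, lj = D[i, j], 0.0
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])
        d_new = 0.5 * (D[:, i] + D[:, j] - D[i, j])
        D = np.delete(np.delete(D, (i, j), axis=0), (i, j), axis=1)
        d_new = np.delete(d_new, (i, j))
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = D[:-1, -1] = d_new
        new_key = min(keys[i], keys[j])
        for idx in sorted((i, j), reverse=True):
            del nodes[idx]
            del keys[idx]
        nodes.append(parent)
        keys.append(new_key)

    # close with the three-point formulas
    (a, b, c) = range(3)
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = TreeNode()
    for node, ln in zip(nodes, (la, lb, lc)):
        node.length = max(ln, 0.0)
        root.append(node)
    return root


def root_with_outgroup(tree: TreeNode, outgroup_id: str, drop_outgroup: bool = True) -> TreeNode:
    """Root at the midpoint of the outgroup's pendant edge.

    With ``drop_outgroup`` (the default) the outgroup leaf is removed and
    the resulting single-child root is contracted away, leaving a rooted
    tree over the homolog leaves only. Pairwise path lengths between
    retained leaves are unchanged.
    """
    try:
        og = tree.find(outgroup_id)
    except Exception as exc:  # skbio raises MissingNodeError
        raise KeyError(f"outgroup {outgroup_id!r} not found in tree") from exc
    if not og.is_tip():
        raise ValueError(f"outgroup {outgroup_id!r} is not a leaf")
    pendant = og.length if og.length else 0.0
    if pendant > 0:
        rooted = tree.root_at(outgroup_id, above=pendant / 2.0, branch_attrs=[])
    else:
        # zero-length pendant edge: root at the attachment node directly
        rooted = tree.root_at(og.parent, branch_attrs=[])
    if not drop_outgroup:
        return rooted
    og = rooted.find(outgroup_id)
    parent = og.parent
    parent.remove(og)
    while len(rooted.children) == 1:
        only = rooted.children[0]
        rooted.remove(only)
        only.parent = None
        rooted = only
    rooted.length = None
    return rooted


def read_newick(source: str) -> TreeNode:
    """Parse a Newick string; missing branch lengths become 0."""
    tree = TreeNode.read(io.StringIO(source), format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    tree.length = None
    return tree


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to a one-line Newick string."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def leaf_names(tree: TreeNode) -> list[str]:
    return [t.name for t in tree.tips()]
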