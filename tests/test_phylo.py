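import io
import itertools
import random

import numpy as np
import pytest

from cystree.alignment_io import AlignedFamily
from cystree.phylo import (
    KIMURA_MAX_DISTANCE,
    DistanceMatrix,
    neighbor_joining,
    pairwise_distances,
    read_newick,
    root_with_outgroup,
    write_newick,
)
from cystree.simulator import random_tree


def splits(tree):
    """Non-trivial bipartitions of an (un)rooted tree, as frozensets of tips."""
    all_tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            out.add(frozenset({side, all_tips - side}))
    return out


def tip_distances(tree):
    """All pairwise leaf path lengths, keyed by frozenset of names."""
    out = {}
    tips = list(tree.tips())
    for a, b in itertools.combinations(tips, 2):
        out[frozenset((a.name, b.name))] = a.distance(b)
    return out


class TestPairwiseDistances:
    def fam(self, *rows):
        return AlignedFamily(
            rows=tuple((f"s{k}", s) for k, s in enumerate(rows)), query_row_id="s0"
        )

    def test_identical_rows_distance_zero(self):
        dm = pairwise_distances(self.fam("ACDE", "ACDE"))
        assert dm.matrix[0, 1] == 0.0

    def test_single_mismatch_quarter(self):
        dm = pairwise_distances(self.fam("AAAA", "AAAT"))
        assert dm.matrix[0, 1] == pytest.approx(0.25)

    def test_gapped_columns_excluded(self):
        # comparable columns are 0 and 2; both match
        dm = pairwise_distances(self.fam("A-CD", "AAC-"))
        assert dm.matrix[0, 1] == 0.0

    def test_no_comparable_columns_maximal(self):
        dm = pairwise_distances(self.fam("A--", "-AA"))
        assert dm.matrix[0, 1] == 1.0

    def test_kimura_correction_formula(self):
        p = 0.25
        dm = pairwise_distances(self.fam("AAAA", "AAAT"), correction="kimura")
        assert dm.matrix[0, 1] == pytest.approx(-np.log(1 - p - p * p / 5))

    def test_kimura_capped_beyond_validity(self):
        dm = pairwise_distances(self.fam("AAAA", "TTTT"), correction="kimura")
        assert dm.matrix[0, 1] == KIMURA_MAX_DISTANCE

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distances(self.fam("AAAA"))


class TestNeighborJoining:
    def test_two_taxa_even_split(self):
        dm = DistanceMatrix(ids=("A", "B"), matrix=np.array([[0, 0.4], [0.4, 0]]))
        tree = neighbor_joining(dm)
        (a, b) = tree.children
        assert a.length == pytest.approx(0.2)
        assert b.length == pytest.approx(0.2)

    def test_three_taxa_closed_form(self):
        # l_a = (D_ab + D_ac - D_bc) / 2 etc.
        D = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = neighbor_joining(DistanceMatrix(ids=("A", "B", "C"), matrix=D))
        lens = {t.name: t.length for t in tree.tips()}
        assert lens["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lens["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lens["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_four_taxon_additive_topology_recovered(self):
        # tree ((A:1,B:2):1,(C:3,D:4):1) -> additive matrix by path sums
        D = np.array(
            [
                [0, 3, 6, 7],
                [3, 0, 7, 8],
                [6, 7, 0, 7],
                [7, 8, 7, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(DistanceMatrix(ids=("A", "B", "C", "D"), matrix=D))
        assert splits(tree) == {
            frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})})
        }

    @pytest.mark.parametrize("n_leaves", [4, 5, 6])
    def test_additive_matrices_recover_generating_topology(self, n_leaves):
        """NJ is consistent: path-length matrices return their own tree."""
        for seed in range(10):
            true = random_tree(n_leaves, seed=seed, branch_scale=1.0)
            names = sorted(t.name for t in true.tips())
            dist = tip_distances(true)
            D = np.zeros((n_leaves, n_leaves))
            for i, a in enumerate(names):
                for j, b in enumerate(names):
                    if i != j:
                        D[i, j] = dist[frozenset((a, b))]
            rec = neighbor_joining(DistanceMatrix(ids=tuple(names), matrix=D))
            assert splits(rec) == splits(true)

    def test_matches_reference_nj_topology(self):
        """Cross-check against an independent NJ implementation."""
        skbio_nj = pytest.importorskip("skbio.tree").nj
        from skbio import DistanceMatrix as SkDM

        rng = np.random.default_rng(0)
        for _ in range(5):
            n = 7
            coords = rng.random((n, 4))
            D = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
            ids = tuple(f"s{k}" for k in range(n))
            ours = neighbor_joining(DistanceMatrix(ids=ids, matrix=D))
            ref = skbio_nj(SkDM(D, ids))
            assert splits(ours) == splits(ref)

    def test_deterministic_under_ties(self):
        # fully tied matrix: the joined pair must be the lexicographically first
        D = np.ones((4, 4)) - np.eye(4)
        ids = ("d", "c", "b", "a")
        t1 = write_newick(neighbor_joining(DistanceMatrix(ids=ids, matrix=D)))
        t2 = write_newick(neighbor_joining(DistanceMatrix(ids=ids, matrix=D)))
        assert t1 == t2

    def test_asymmetric_matrix_rejected(self):
        M = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError):
            DistanceMatrix(ids=("A", "B"), matrix=M)


class TestOutgroupRooting:
    def make(self):
        dm = DistanceMatrix(
            ids=("A", "B", "C", "OG"),
            matrix=np.array(
                [
                    [0, 0.2, 0.5, 1.6],
                    [0.2, 0, 0.5, 1.6],
                    [0.5, 0.5, 0, 1.7],
                    [1.6, 1.6, 1.7, 0],
                ]
            ),
        )
        return neighbor_joining(dm)

    def test_outgroup_dropped_leaf_set_preserved(self):
        rooted = root_with_outgroup(self.make(), "OG")
        assert sorted(t.name for t in rooted.tips()) == ["A", "B", "C"]
        assert rooted.parent is None

    def test_internal_nodes_at_least_binary(self):
        rooted = root_with_outgroup(self.make(), "OG")
        for node in rooted.traverse(include_self=True):
            if not node.is_tip():
                assert len(node.children) >= 2

    def test_path_lengths_between_retained_leaves_unchanged(self):
        unrooted = self.make()
        before = tip_distances(unrooted)
        rooted = root_with_outgroup(unrooted.copy(), "OG")
        after = tip_distances(rooted)
        for pair, d in after.items():
            assert d == pytest.approx(before[pair])

    def test_keep_outgroup_keeps_leaf(self):
        rooted = root_with_outgroup(self.make(), "OG", drop_outgroup=False)
        assert "OG" in [t.name for t in rooted.tips()]

    def test_missing_outgroup_rejected(self):
        with pytest.raises(KeyError):
            root_with_outgroup(self.make(), "nope")


class TestNewick:
    def test_two_leaf_parse(self):
        tree = read_newick("(A:0.1,B:0.2);")
        assert sorted(t.name for t in tree.tips()) == ["A", "B"]
        assert tree.find("A").length == pytest.approx(0.1)

    def test_missing_lengths_default_zero(self):
        tree = read_newick("((A,B),C);")
        assert all(t.length == 0.0 for t in tree.traverse(include_self=False))

    def test_round_trip_random_50_leaf_tree(self):
        tree = random_tree(50, seed=11)
        back = read_newick(write_newick(tree))
        assert splits(back) == splits(tree)
        d0, d1 = tip_distances(tree), tip_distances(back)
        for pair in d0:
            assert d1[pair] == pytest.approx(d0[pair])

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(Exception):
            read_newick("((A:0.1,B:0.2;")
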