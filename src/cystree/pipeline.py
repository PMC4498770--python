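"""End-to-end connectivity prediction for one query protein.

The pipeline chains the package's stages: map the query's oxidized
positions onto alignment columns, drop odd-cysteine homologs, append the
shuffled outgroup, build and root the neighbor-joining tree, propagate
cysteine-presence labels, accumulate tandem-loss weights, and resolve the
graph by maximum-weight perfect matching. When the filtered family is too
small to carry any signal the prediction falls back to a seeded uniform
random matching and says so.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from skbio import TreeNode

from . import alignment_io, inference, labeling, matching, phylo
from .alignment_io import AlignedFamily, QueryProtein
from .inference import ConnectivityGraph
from .matching import BondPattern

#: Fewer surviving homologs (query excluded) than this triggers the
#: random fallback: a lone homolog cannot support an informative tree.
MIN_HOMOLOGS = 2


@dataclass
class PredictionResult:
    pattern: BondPattern
    fallback_random: bool
    graph: ConnectivityGraph | None = None
    tree: TreeNode | None = None
    info: dict[str, Any] = field(default_factory=dict)


def predict_connectivity(
    family: AlignedFamily,
    query: QueryProtein,
    *,
    seed: int = 42,
    correction: str = "none",
    drop_outgroup: bool = True,
    tree: TreeNode | None = None,
) -> PredictionResult:
    """Predict the disulfide pattern of ``query`` from its family MSA.

    Parameters
    ----------
    family : AlignedFamily
        MSA containing the query row.
    query : QueryProtein
        Query sequence and its oxidized cysteine positions (0-based).
    seed : int
        Seeds the outgroup shuffle and the random fallback.
    correction : {"none", "kimura"}
        Distance model for the NJ tree.
    drop_outgroup : bool
        Remove the outgroup leaf after rooting (default). When kept, its
        all-mismatch label still walks a root path.
    tree : TreeNode, optional
        Precomputed *rooted* tree over the family's row ids; skips the
        filter/outgroup/NJ stages entirely.
    """
    n = query.n_cysteines
    family = alignment_io.map_oxidized_columns(family, query)

    if tree is None:
        filtered = alignment_io.filter_even_cysteine_homologs(family)
        removed = [
            (rid, inference.parity(labeling.leaf_label(seq, family.oxidized_columns)))
            for rid, seq in family.rows
            if rid not in set(filtered.ids)
        ]
        n_homologs = sum(1 for rid, _ in filtered.rows if rid != filtered.query_row_id)
        if n_homologs < MIN_HOMOLOGS:
            return PredictionResult(
                pattern=matching.random_matching(n, seed),
                fallback_random=True,
                info={
                    "reason": f"only {n_homologs} homolog(s) after filtering",
                    "filtered_out": removed,
                },
            )
        with_og, og_id = alignment_io.append_outgroup(filtered, query, seed)
        dm = phylo.pairwise_distances(with_og, correction=correction)
        unrooted = phylo.neighbor_joining(dm)
        work_tree = phylo.root_with_outgroup(unrooted, og_id, drop_outgroup=drop_outgroup)
        label_family = with_og if not drop_outgroup else filtered
        info: dict[str, Any] = {
            "n_homologs": n_homologs,
            "filtered_out": removed,
            "outgroup_id": og_id,
        }
    else:
        work_tree = tree
        label_family = family
        info = {"precomputed_tree": True}

    labeling.set_leaf_labels(work_tree, label_family)
    labeling.assign_inner_labels(work_tree)
    graph = inference.accumulate_weights(work_tree, n)
    pattern = matching.max_weight_perfect_matching(graph.weights)
    info["total_graph_weight"] = graph.total_weight
    info["n_informative_steps"] = sum(
        inference.count_informative_steps(
            inference.root_path_labels(work_tree, tip.name)
        )
        for tip in work_tree.tips()
    )
    return PredictionResult(
        pattern=pattern,
        fallback_random=False,
        graph=graph,
        tree=work_tree,
        info=info,
    )
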