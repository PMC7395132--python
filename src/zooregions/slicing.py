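"""Cutting a dated tree at a phylogenetic depth.

Slicing a dated phylogeny at depth ``t`` (Ma before present) removes all
branch segments younger than ``t``; every lineage that crosses the slice
becomes a tip of the remaining tree, and the geographic ranges of its
descendant tips are merged into it. Repeating the pairwise phylogenetic
beta computation on the remaining tree and the merged (branch x site)
incidence yields a dissimilarity matrix "as seen" from depth ``t``: the
deeper the slice, the more recent evolutionary divergence is ignored.

Conventions:

* A branch spanning the slice is truncated -- only its segment older
  than ``t`` is kept (length = start age - t). Keeping the full pendant
  length would double-count evolution younger than the slice.
* A node whose age equals ``t`` exactly belongs to the older side: its
  child branches are removed and the node itself becomes a crossing
  lineage. ``truncate=False`` preserves full crossing-branch lengths for
  sensitivity analyses.
* A lineage is named after the lexicographically smallest tip it
  contains, so at ``t = 0`` the mapping is the identity.
* Depths at or beyond the root age are degenerate: a single lineage
  contains every tip and all pairwise dissimilarities are defined as 0
  (with a warning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .beta import pairwise_pbeta_sim
from .io import DatedTree, DissimilarityMatrix, IncidenceMatrix

__all__ = ["SlicedTree", "slice_tree", "branch_site_matrix", "pbeta_at_depth", "depth_series"]

#: Default slice depths (Ma): present day back to the early Cenozoic.
DEFAULT_DEPTHS = (0.0, 5.0, 10.0, 20.0, 40.0, 60.0)


@dataclass
class SlicedTree:
    """Result of cutting a dated tree at a depth.

    Attributes
    ----------
    depth:
        The slice depth in Ma.
    tree:
        The remaining tree (tips = crossing lineages, pendant lengths
        measured above the slice), or ``None`` when the slice is at or
        beyond the root age.
    tip_to_lineage:
        Maps every original tip label to the id of the lineage whose
        path crosses the slice.
    degenerate:
        True when all tips collapse into a single lineage.
    """

    depth: float
    tree: DatedTree | None
    tip_to_lineage: dict
    degenerate: bool = False

    @property
    def lineage_ids(self) -> list:
        return sorted(set(self.tip_to_lineage.values()))

    @property
    def n_lineages(self) -> int:
        return len(set(self.tip_to_lineage.values()))


def slice_tree(tree: DatedTree, depth: float, truncate: bool = True) -> SlicedTree:
    """Cut ``tree`` at ``depth`` Ma and collapse younger structure."""
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if depth == 0:
        return SlicedTree(
            depth=0.0,
            tree=tree,
            tip_to_lineage={t: t for t in tree.tip_labels},
            degenerate=tree.n_tips == 1,
        )
    if depth >= tree.root_age:
        if depth > tree.root_age:
            warnings.warn(
                f"slice depth {depth} Ma exceeds root age {tree.root_age:.6g} Ma; "
                "all tips collapse into one lineage",
                UserWarning,
            )
        lineage = min(tree.tip_labels)
        return SlicedTree(
            depth=float(depth),
            tree=None,
            tip_to_lineage={t: lineage for t in tree.tip_labels},
            degenerate=True,
        )

    src = tree.dendropy_tree
    clone = src.clone(depth=1)
    ages: dict = {}
    desc: dict = {}
    for node in clone.postorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
            desc[node] = [node.taxon.label]
        else:
            ages[node] = max(ages[ch] + ch.edge.length for ch in node.child_nodes())
            desc[node] = sorted(
                lbl for ch in node.child_nodes() for lbl in desc[ch]
            )

    tip_to_lineage: dict = {}
    namespace = clone.taxon_namespace
    # preorder: the first node on a root-to-tip path with age <= depth is the
    # crossing lineage; everything below it is collapsed.
    for node in clone.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        if ages[node] <= depth < ages[parent]:
            members = desc[node]
            lineage = min(members)
            for m in members:
                tip_to_lineage[m] = lineage
            node.clear_child_nodes()
            if truncate:
                node.edge.length = ages[parent] - depth
            if node.taxon is None:
                taxon = namespace.new_taxon(label=lineage)
                node.taxon = taxon
            else:
                node.taxon.label = lineage
    clone.seed_node.edge.length = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sliced tips sit at age `depth`
        remaining = DatedTree(clone)
    return SlicedTree(
        depth=float(depth),
        tree=remaining,
        tip_to_lineage=tip_to_lineage,
        degenerate=remaining.n_tips == 1,
    )


def branch_site_matrix(s: SlicedTree, m: IncidenceMatrix) -> IncidenceMatrix:
    """Merge tip ranges into their crossing lineages (site x lineage table).

    A lineage is present in a site when any of its mapped tips is present
    there. At ``depth = 0`` the output equals the input (up to taxon
    order).
    """
    unknown = set(m.taxon_ids) - set(s.tip_to_lineage)
    if unknown:
        raise KeyError(f"taxa not mapped by the slice: {sorted(unknown)}")
    lineage_of = pd.Series({t: s.tip_to_lineage[t] for t in m.taxon_ids})
    merged = (
        m.values.T.groupby(lineage_of).any().T.astype(np.int8)
    )
    out = IncidenceMatrix(merged, m.metadata)
    # A site that held at least one tip always holds at least one lineage.
    assert (out.values.sum(axis=1) > 0).equals(m.values.sum(axis=1) > 0)
    return out


def pbeta_at_depth(
    tree: DatedTree, m: IncidenceMatrix, depth: float, truncate: bool = True
) -> DissimilarityMatrix:
    """Pairwise phylogenetic beta_sim at a given phylogenetic depth.

    The tree is first pruned to the taxa present in ``m`` (so depth is
    measured on the history actually represented in the sites), then
    sliced; the pairwise computation runs on the remaining tree and the
    merged branch x site matrix. Degenerate slices (a single crossing
    lineage) return an all-zero matrix with a warning.
    """
    if depth == 0:
        return pairwise_pbeta_sim(tree, m)
    present = m.values.to_numpy(bool).any(axis=0)
    taxa = [t for t, p in zip(m.taxon_ids, present) if p]
    pruned = tree.prune_to(taxa)
    s = slice_tree(pruned, depth, truncate=truncate)
    if s.degenerate:
        warnings.warn(
            f"slice at {depth} Ma leaves a single lineage; "
            "all pairwise dissimilarities set to 0",
            UserWarning,
        )
        n = m.shape[0]
        return DissimilarityMatrix(np.zeros((n, n)), m.site_ids)
    cols_present = m.values.loc[:, taxa]
    merged = branch_site_matrix(s, IncidenceMatrix(cols_present, m.metadata))
    return pairwise_pbeta_sim(s.tree, merged)


def depth_series(
    tree: DatedTree,
    m: IncidenceMatrix,
    depths: Sequence[float] = DEFAULT_DEPTHS,
    truncate: bool = True,
) -> dict[float, DissimilarityMatrix]:
    """One dissimilarity matrix per slice depth, same site ordering."""
    depths = [float(d) for d in depths]
    if any(d < 0 for d in depths):
        raise ValueError("depths must be non-negative")
    if len(set(depths)) != len(depths):
        raise ValueError("depths must be duplicate-free")
    return {d: pbeta_at_depth(tree, m, d, truncate=truncate) for d in depths}
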