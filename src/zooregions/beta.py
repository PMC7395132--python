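"""Simpson turnover (beta_sim) and its phylogenetic analogue (pbeta_sim).

Simpson's beta dissimilarity isolates spatial turnover from richness
differences:

    beta_sim = min(b, c) / (a + min(b, c))

where, for two assemblages A and B, ``a`` is the shared richness,
``b = |A \\ B|`` and ``c = |B \\ A|``. It is 0 whenever one assemblage is
nested in the other and 1 when they share nothing.

The phylogenetic version applies the same formula to branch lengths of a
dated tree: a branch is "present in" a site when at least one of its
descendant tips occurs there, ``a`` is the total length of branches
present in both sites, and ``b``/``c`` the length present only in one.
No branch above the root is counted, and the tree is first pruned to the
taxa actually in play (preserving path lengths), so two sites holding
disjoint halves of the tree are maximally dissimilar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import DatedTree, DissimilarityMatrix, IncidenceMatrix

logger = logging.getLogger("zooregions")

__all__ = [
    "BetaComponents",
    "beta_sim_components",
    "beta_sim",
    "pairwise_beta_sim",
    "pbeta_sim_components",
    "pairwise_pbeta_sim",
    "combine_matrices",
]


@dataclass(frozen=True)
class BetaComponents:
    """Shared (a) and unique (b, c) richness or branch length."""

    a: float
    b: float
    c: float

    def __post_init__(self):
        for name in ("a", "b", "c"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"component {name}={v!r} must be finite and >= 0")


def beta_sim_components(set_a: Iterable, set_b: Iterable) -> BetaComponents:
    """Species-level a/b/c components of two assemblages."""
    A, B = set(set_a), set(set_b)
    if not A or not B:
        raise ValueError("beta_sim is undefined for empty assemblage")
    return BetaComponents(a=len(A & B), b=len(A - B), c=len(B - A))


def beta_sim(components: BetaComponents) -> float:
    """Simpson turnover min(b,c)/(a+min(b,c)) from precomputed components."""
    m = min(components.b, components.c)
    denom = components.a + m
    if denom == 0:
        raise ValueError("beta_sim undefined: both assemblages empty")
    return m / denom


def _pairwise_sim_from_presence(P: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Pairwise Simpson turnover from a boolean presence matrix.

    ``P`` is (n entities x m features) and ``weights`` the per-feature
    weight (1 for species, branch length for phylogenetic beta).
    """
    Pw = P.astype(float) * weights
    shared = Pw @ P.T.astype(float)  # a_ij
    totals = P.astype(float) @ weights
    b = totals[:, None] - shared
    c = totals[None, :] - shared
    m = np.minimum(b, c)
    denom = shared + m
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, m / np.where(denom > 0, denom, 1.0), 0.0)
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(sim, 0.0)
    return sim


def pairwise_beta_sim(m: IncidenceMatrix) -> DissimilarityMatrix:
    """Species-level beta_sim between every pair of sites."""
    X = m.values.to_numpy(dtype=float)
    empty = np.flatnonzero(X.sum(axis=1) == 0)
    if empty.size:
        raise ValueError(f"empty assemblage at site {m.site_ids[empty[0]]!r}")
    sim = _pairwise_sim_from_presence(X > 0, np.ones(X.shape[1]))
    return DissimilarityMatrix(sim, m.site_ids)


def _branch_table(tree: DatedTree, taxa: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Lengths and tip-membership matrix for every branch of the pruned tree.

    Returns ``(lengths (k,), membership (k, len(taxa)) bool)`` where row i
    marks which taxa descend from branch i.
    """
    pruned = tree.prune_to(taxa)
    col = {t: j for j, t in enumerate(taxa)}
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    for length, tips in pruned.branches():
        memb = np.zeros(len(taxa), dtype=bool)
        for t in tips:
            memb[col[t]] = True
        lengths.append(length)
        rows.append(memb)
    return np.asarray(lengths, dtype=float), np.vstack(rows)


def pbeta_sim_components(
    tree: DatedTree, tips_a: Iterable, tips_b: Iterable
) -> BetaComponents:
    """Branch-length a/b/c components of two tip sets.

    The tree is pruned to the union of the two sets (path lengths
    preserved) so that only evolutionary history distinguishing the two
    assemblages enters the components.
    """
    A, B = set(tips_a), set(tips_b)
    if not A or not B:
        raise ValueError("pbeta_sim is undefined for empty assemblage")
    taxa = sorted(A | B)
    unknown = set(taxa) - set(tree.tip_labels)
    if unknown:
        raise KeyError(f"tips not in tree: {sorted(unknown)}")
    lengths, memb = _branch_table(tree, taxa)
    in_a = memb[:, [taxa.index(t) for t in sorted(A)]].any(axis=1)
    in_b = memb[:, [taxa.index(t) for t in sorted(B)]].any(axis=1)
    a = float(lengths[in_a & in_b].sum())
    b = float(lengths[in_a & ~in_b].sum())
    c = float(lengths[~in_a & in_b].sum())
    return BetaComponents(a=a, b=b, c=c)


def pairwise_pbeta_sim(tree: DatedTree, m: IncidenceMatrix) -> DissimilarityMatrix:
    """Phylogenetic beta_sim between every pair of sites.

    The tree is pruned to the matrix's taxon set once (all-zero taxon
    columns are dropped first -- a taxon nobody holds carries no signal),
    then every branch is mapped to the sites containing at least one of
    its descendant tips.
    """
    X = m.values.to_numpy(dtype=bool)
    empty = np.flatnonzero(~X.any(axis=1))
    if empty.size:
        raise ValueError(f"empty assemblage at site {m.site_ids[empty[0]]!r}")
    present = X.any(axis=0)
    taxa = [t for t, p in zip(m.taxon_ids, present) if p]
    unknown = set(taxa) - set(tree.tip_labels)
    if unknown:
        raise KeyError(f"taxa not in tree: {sorted(unknown)}")
    X = X[:, present]
    lengths, memb = _branch_table(tree, taxa)
    P = X @ memb.T  # (sites x branches): site holds >=1 descendant tip
    sim = _pairwise_sim_from_presence(P > 0, lengths)
    return DissimilarityMatrix(sim, m.site_ids)


def combine_matrices(
    matrices: Sequence[DissimilarityMatrix], mode: str = "intersection"
) -> DissimilarityMatrix:
    """Element-wise unweighted mean of per-group dissimilarity matrices.

    ``mode='intersection'`` (default) restricts to the entity ids shared
    by every matrix, logging how many ids were dropped; ``mode='strict'``
    requires identical id sets.
    """
    if not matrices:
        raise ValueError("no matrices to combine")
    if mode not in ("intersection", "strict"):
        raise ValueError(f"unknown mode {mode!r}")
    shared = set(matrices[0].ids)
    for d in matrices[1:]:
        shared &= set(d.ids)
    if not shared:
        raise ValueError("empty intersection of entity ids")
    if mode == "strict":
        for d in matrices:
            if set(d.ids) != shared:
                raise ValueError("matrices do not share an identical id set")
    n_dropped = sum(len(d.ids) - len(shared) for d in matrices)
    if n_dropped:
        logger.info("combine_matrices: dropped %d non-shared ids in total", n_dropped)
    order = [i for i in matrices[0].ids if i in shared]
    stack = np.stack([d.subset(order).values for d in matrices])
    return DissimilarityMatrix(stack.mean(axis=0), order)
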