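"""Shared fixtures and independent oracles.

The oracles deliberately take the slow, explicit route (per-pair set
counting, direct branch-segment enumeration on the original tree,
exhaustive agglomeration, 1-D angle scans) so that agreement with the
vectorized implementations is a meaningful check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

import zooregions as zr

TOY_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def toy_tree() -> zr.DatedTree:
    return zr.DatedTree.from_newick(TOY_NEWICK)


@pytest.fixture
def toy_incidence() -> zr.IncidenceMatrix:
    values = pd.DataFrame(
        [[1, 0, 1], [0, 1, 1]], index=["s1", "s2"], columns=["A", "B", "C"]
    )
    return zr.IncidenceMatrix(values)


@pytest.fixture
def planted_pairs_matrix() -> zr.DissimilarityMatrix:
    """Four sites in two planted pairs: within 0.1, between 0.9."""
    vals = np.full((4, 4), 0.9)
    np.fill_diagonal(vals, 0.0)
    vals[0, 1] = vals[1, 0] = 0.1
    vals[2, 3] = vals[3, 2] = 0.1
    return zr.DissimilarityMatrix(vals, ["a", "b", "c", "d"])


# ---------------------------------------------------------------------------
# random instances
# ---------------------------------------------------------------------------


def random_ultrametric_tree(rng: np.random.Generator, n_tips: int,
                            root_age: float = 10.0) -> zr.DatedTree:
    """Random coalescent-style ultrametric tree with n_tips."""
    labels = [f"t{i}" for i in range(n_tips)]
    nodes: list = list(labels)
    ages = np.sort(rng.uniform(0.0, root_age, size=n_tips - 1))
    for age in ages:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(((a, b), float(age)))

    def newick(node, parent_age):
        if isinstance(node, str):
            return f"{node}:{parent_age:.17g}"
        (left, right), age = node
        return (f"({newick(left, age)},{newick(right, age)})"
                f":{parent_age - age:.17g}")

    (children, root) = nodes[0]
    s = f"({newick(children[0], root)},{newick(children[1], root)});"
    return zr.DatedTree.from_newick(s)


def random_incidence(rng: np.random.Generator, tree: zr.DatedTree,
                     n_sites: int, p: float = 0.5) -> zr.IncidenceMatrix:
    """Random binary incidence whose rows are guaranteed non-empty."""
    taxa = sorted(tree.tip_labels)
    X = (rng.random((n_sites, len(taxa))) < p).astype(np.int8)
    for i in range(n_sites):
        if X[i].sum() == 0:
            X[i, rng.integers(len(taxa))] = 1
    return zr.IncidenceMatrix(
        pd.DataFrame(X, index=[f"s{i}" for i in range(n_sites)], columns=taxa)
    )


def random_dissimilarity(rng: np.random.Generator, n: int) -> zr.DissimilarityMatrix:
    vals = rng.random((n, n))
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 0.0)
    return zr.DissimilarityMatrix(vals, [f"e{i}" for i in range(n)])


# ---------------------------------------------------------------------------
# oracle: branch-segment enumeration for phylogenetic beta at any depth
# ---------------------------------------------------------------------------


def _tree_edges(tree: zr.DatedTree):
    """(child_age, parent_age, descendant tip set) per non-root edge."""
    dt = tree.dendropy_tree
    ages, desc = {}, {}
    edges = []
    for node in dt.postorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
            desc[node] = frozenset([node.taxon.label])
        else:
            ages[node] = max(ages[ch] + ch.edge.length for ch in node.child_nodes())
            desc[node] = frozenset().union(*(desc[ch] for ch in node.child_nodes()))
        if node.parent_node is not None:
            edges.append((node, desc[node]))
    # parent ages known only after full pass
    return [
        (ages[node], ages[node.parent_node], d) for node, d in edges
    ]


def oracle_pbeta_matrix(tree: zr.DatedTree, m: zr.IncidenceMatrix,
                        depth: float = 0.0) -> np.ndarray:
    """Brute-force pairwise phylogenetic Simpson turnover at a depth.

    Works directly on the original tree: a branch contributes the part
    of its [child age, parent age] span older than ``depth``; branches
    holding all of the matrix's taxa in their descendants lie on or above
    the taxa's MRCA and are excluded (shared trunk). Purely per-pair
    python arithmetic -- no code shared with the implementation.
    """
    sets = {s: m.site_taxa(s) for s in m.site_ids}
    taxa = frozenset().union(*sets.values())
    edges = []
    for child_age, parent_age, desc in _tree_edges(tree):
        d = desc & taxa
        if not d or d == taxa:
            continue
        seg = parent_age - max(child_age, depth)
        if seg > 0:
            edges.append((seg, d))
    n = len(m.site_ids)
    out = np.zeros((n, n))
    # the lowest edge holding every taxon has the taxa's MRCA as its child
    mrca_age = min(
        (ca for ca, _, desc in _tree_edges(tree) if desc & taxa == taxa),
        default=tree.root_age,
    )
    if depth >= mrca_age or not edges:
        return out
    for i, j in itertools.combinations(range(n), 2):
        sa, sb = sets[m.site_ids[i]], sets[m.site_ids[j]]
        a = b = c = 0.0
        for seg, d in edges:
            in_a, in_b = bool(d & sa), bool(d & sb)
            if in_a and in_b:
                a += seg
            elif in_a:
                b += seg
            elif in_b:
                c += seg
        mbc = min(b, c)
        out[i, j] = out[j, i] = mbc / (a + mbc) if (a + mbc) > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# oracle: exhaustive UPGMA agglomeration
# ---------------------------------------------------------------------------


def oracle_upgma_cophenetic(D: zr.DissimilarityMatrix) -> np.ndarray:
    """Cophenetic matrix from step-by-step UPGMA with exhaustive pair scans."""
    n = D.n
    clusters = {i: frozenset([i]) for i in range(n)}
    dist = {
        frozenset((i, j)): D.values[i, j]
        for i, j in itertools.combinations(range(n), 2)
    }
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        keys = sorted(clusters)
        best, pair = None, None
        for i, j in itertools.combinations(keys, 2):
            d = dist[frozenset((i, j))]
            if best is None or d < best:
                best, pair = d, (i, j)
        i, j = pair
        ci, cj = clusters.pop(i), clusters.pop(j)
        new = ci | cj
        for a in ci:
            for b in cj:
                coph[a, b] = coph[b, a] = best
        new_key = max(keys) + 1
        for k in list(clusters):
            ck = clusters[k]
            # unweighted average over all original-point pairs
            d = (
                len(ci) * dist[frozenset((i, k))]
                + len(cj) * dist[frozenset((j, k))]
            ) / (len(ci) + len(cj))
            dist[frozenset((new_key, k))] = d
        clusters[new_key] = new
    return coph


# ---------------------------------------------------------------------------
# oracle: 1-D angle scan for Procrustes
# ---------------------------------------------------------------------------


def oracle_procrustes_residual(X: np.ndarray, Y: np.ndarray,
                               allow_scaling: bool = True,
                               allow_reflection: bool = True,
                               n_angles: int = 2_000_000) -> float:
    """Minimum residual sum of squares over a dense grid of rotations."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    norm_y2 = (Yc**2).sum()
    norm_x2 = (Xc**2).sum()
    thetas = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    best = np.inf
    reflections = [False, True] if allow_reflection else [False]
    for refl in reflections:
        Yr = Yc.copy()
        if refl:
            Yr[:, 1] = -Yr[:, 1]
        M = Yr.T @ Xc
        trace = (M[0, 0] + M[1, 1]) * np.cos(thetas) + (M[1, 0] - M[0, 1]) * np.sin(thetas)
        if allow_scaling:
            s = np.maximum(trace, 0.0) / norm_y2
        else:
            s = np.ones_like(trace)
        resid = norm_x2 + s**2 * norm_y2 - 2 * s * trace
        best = min(best, float(resid.min()))
    return best


# ---------------------------------------------------------------------------
# oracle: exhaustive Mantel enumeration
# ---------------------------------------------------------------------------


def oracle_mantel_exact(A: np.ndarray, B: np.ndarray) -> tuple[float, float]:
    """Observed r and exact one-sided p over every entity permutation."""
    n = A.shape[0]
    iu = np.triu_indices(n, 1)

    def corr(M1, M2):
        x, y = M1[iu], M2[iu]
        x = x - x.mean()
        y = y - y.mean()
        return float((x * y).sum() / np.sqrt((x**2).sum() * (y**2).sum()))

    r_obs = corr(A, B)
    count = 0
    total = 0
    for p in itertools.permutations(range(n)):
        if p == tuple(range(n)):
            continue
        total += 1
        if corr(A, B[np.ix_(p, p)]) >= r_obs - 1e-12:
            count += 1
    return r_obs, (1 + count) / (1 + total)
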