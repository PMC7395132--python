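"""NMDS ordination, Procrustes superimposition, and Mantel tests.

Non-metric multidimensional scaling (NMDS) embeds a dissimilarity matrix
in two dimensions while preserving rank order; quality is Kruskal's
stress-1, minimized over several random restarts. Ordinations of
different time slices live in arbitrary rotations of each other, so they
are compared after Procrustes superimposition: the least-squares
translation + rotation/reflection + isotropic scaling of one
configuration onto a reference (the present-day ordination). Linking the
aligned positions of each assemblage across slices gives its trajectory
through time. Mantel permutation tests quantify how strongly two
dissimilarity matrices agree.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import MDS

from .io import DissimilarityMatrix

__all__ = [
    "Ordination",
    "ProcrustesResult",
    "MantelResult",
    "nmds",
    "procrustes",
    "procrustes_trajectory",
    "mantel",
]


@dataclass
class Ordination:
    """A low-dimensional embedding of entities with its stress."""

    ids: list
    coords: np.ndarray  # (n, dims), centered at the origin
    stress: float  # Kruskal stress-1
    n_restarts: int = 1
    seed: int | None = None

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coords.shape[1])]
        return pd.DataFrame(self.coords, index=self.ids, columns=cols)


@dataclass
class ProcrustesResult:
    """A fitted similarity transform mapping a target onto a reference."""

    rotation: np.ndarray  # (d, d) orthogonal
    scale: float
    translation: np.ndarray  # (d,)
    aligned: np.ndarray  # transformed target coordinates
    residual_ss: float  # sum of squared residuals after alignment
    displacement: np.ndarray  # aligned - reference, per entity
    ids: list

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return self.scale * coords @ self.rotation + self.translation


@dataclass
class MantelResult:
    r: float
    n_perm: int
    p_value: float
    seed: int | None = None
    alternative: str = "greater"


def _as_matrix(D) -> tuple[np.ndarray, list | None]:
    if isinstance(D, DissimilarityMatrix):
        return D.values, list(D.ids)
    arr = np.asarray(D, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("expected a square matrix")
    return arr, None


def nmds(
    D,
    dims: int = 2,
    restarts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: int | None = None,
) -> Ordination:
    """Non-metric MDS with monotone regression and random restarts.

    Accepts a :class:`DissimilarityMatrix` or a raw square array. The
    best of ``restarts`` random initializations is kept; results are
    deterministic for a fixed seed. Stress is Kruskal's stress-1.
    """
    values, ids = _as_matrix(D)
    n = values.shape[0]
    if n < dims + 1:
        raise ValueError(f"need at least {dims + 1} entities for {dims}-D NMDS")
    if np.all(values == 0):
        raise ValueError("NMDS undefined on an all-zero matrix")
    model = MDS(
        n_components=dims,
        metric="precomputed",
        metric_mds=False,
        n_init=restarts,
        max_iter=max_iter,
        eps=tol,
        random_state=seed,
        normalized_stress=True,
        init="random",
    )
    coords = model.fit_transform(values)
    coords = coords - coords.mean(axis=0)
    return Ordination(
        ids=ids if ids is not None else list(range(n)),
        coords=coords,
        stress=float(model.stress_),
        n_restarts=restarts,
        seed=seed,
    )


def _coords_and_ids(obj) -> tuple[np.ndarray, list]:
    if isinstance(obj, Ordination):
        return np.asarray(obj.coords, float), list(obj.ids)
    arr = np.asarray(obj, dtype=float)
    return arr, list(range(arr.shape[0]))


def procrustes(
    reference,
    target,
    allow_scaling: bool = True,
    allow_reflection: bool = True,
) -> ProcrustesResult:
    """Least-squares superimposition of ``target`` onto ``reference``.

    Both may be :class:`Ordination` objects (matched by entity id) or
    plain coordinate arrays (matched by row). The optimal orthogonal
    rotation comes from the SVD of the cross-covariance; when reflections
    are disallowed the rotation is constrained to determinant +1.
    """
    X, ids_x = _coords_and_ids(reference)
    Y, ids_y = _coords_and_ids(target)
    if isinstance(reference, Ordination) and isinstance(target, Ordination):
        shared = [i for i in ids_x if i in set(ids_y)]
        if len(shared) < 2:
            raise ValueError("need at least 2 shared entities")
        X = X[[ids_x.index(i) for i in shared]]
        Y = Y[[ids_y.index(i) for i in shared]]
        ids = shared
    else:
        if X.shape != Y.shape:
            raise ValueError("coordinate arrays must have the same shape")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 shared entities")
        ids = list(range(X.shape[0]))

    mu_x, mu_y = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mu_x, Y - mu_y
    norm_y2 = float((Yc**2).sum())
    if norm_y2 == 0:
        raise ValueError("target configuration is a single point")
    M = Yc.T @ Xc
    U, sv, Vt = np.linalg.svd(M)
    R = U @ Vt
    if not allow_reflection and np.linalg.det(R) < 0:
        # flip the direction of least variance to force a proper rotation
        flip = np.ones(len(sv))
        flip[-1] = -1.0
        R = U @ np.diag(flip) @ Vt
        trace = float((sv * flip).sum())
    else:
        trace = float(sv.sum())
    scale = max(trace, 0.0) / norm_y2 if allow_scaling else 1.0
    aligned = scale * Yc @ R + mu_x
    translation = mu_x - scale * (mu_y @ R)
    residual_ss = float(((Xc - scale * Yc @ R) ** 2).sum())
    return ProcrustesResult(
        rotation=R,
        scale=scale,
        translation=translation,
        aligned=aligned,
        residual_ss=residual_ss,
        displacement=aligned - X,
        ids=ids,
    )


def procrustes_trajectory(
    ordinations: Mapping[float, Ordination],
    reference_depth: float | None = None,
    groups: pd.Series | None = None,
    allow_scaling: bool = True,
    allow_reflection: bool = True,
    chained: bool = False,
) -> pd.DataFrame:
    """Align depth-wise ordinations and trace each entity through time.

    All ordinations are superimposed onto the reference depth (the
    smallest depth -- normally the present day -- unless given), so that
    the movement of every entity across slices is comparable. With
    ``chained=True`` each slice is aligned to the previously aligned,
    next-shallower slice instead.

    Returns a tidy table (id, depth, x, y) plus, when ``groups`` labels
    entities with regions, per-region mean coordinates under id
    ``<region>__mean``.
    """
    if not ordinations:
        raise ValueError("no ordinations given")
    depths = sorted(ordinations)
    ref_depth = min(depths) if reference_depth is None else reference_depth
    ref = ordinations[ref_depth]
    id_set = set(ref.ids)
    for d in depths:
        if set(ordinations[d].ids) != id_set:
            raise ValueError(f"ordination at depth {d} has mismatched entity ids")
    rows = []
    prev = ref
    for d in depths:
        ord_d = ordinations[d]
        if d == ref_depth:
            aligned = ord_d.coords[[ord_d.ids.index(i) for i in ref.ids]]
        else:
            base = prev if chained else ref
            res = procrustes(base, ord_d, allow_scaling=allow_scaling,
                             allow_reflection=allow_reflection)
            aligned = res.aligned[[res.ids.index(i) for i in ref.ids]]
        if chained:
            prev = Ordination(ids=list(ref.ids), coords=aligned, stress=ord_d.stress)
        for i, ent in enumerate(ref.ids):
            rows.append({"id": ent, "depth": d, "x": aligned[i, 0], "y": aligned[i, 1]})
    table = pd.DataFrame(rows)
    if groups is not None:
        means = (
            table.assign(region=lambda t: t["id"].map(groups))
            .groupby(["region", "depth"], observed=True)[["x", "y"]]
            .mean()
            .reset_index()
        )
        means["id"] = means["region"].astype(str) + "__mean"
        table = pd.concat(
            [table, means[["id", "depth", "x", "y"]]], ignore_index=True
        )
    return table


def trajectory_displacements(table: pd.DataFrame) -> pd.DataFrame:
    """Net displacement (deepest slice -> shallowest) per entity."""
    out = []
    for ent, grp in table.groupby("id"):
        grp = grp.sort_values("depth")
        x0, y0 = grp.iloc[0][["x", "y"]]
        x1, y1 = grp.iloc[-1][["x", "y"]]
        out.append({"id": ent, "dx": x0 - x1, "dy": y0 - y1,
                    "length": math.hypot(x0 - x1, y0 - y1)})
    return pd.DataFrame(out)


def _lower_triangle(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def mantel(
    D1,
    D2,
    n_perm: int | str = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel permutation test between two dissimilarity matrices.

    Pearson correlation of the lower triangles; the null distribution
    permutes the entities of the second matrix (simultaneous row/column
    shuffles). ``n_perm='all'`` enumerates every non-identity permutation
    (exact test, small n only). The p-value uses the add-one rule
    ``(1 + #extreme) / (1 + n_perm)`` and is therefore never exactly 0.
    """
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    A, ids_a = _as_matrix(D1)
    B, ids_b = _as_matrix(D2)
    if A.shape != B.shape:
        raise ValueError("matrices must have the same size")
    if ids_a is not None and ids_b is not None and ids_a != ids_b:
        if set(ids_a) != set(ids_b):
            raise ValueError("matrices must share entity ids")
        B = D2.subset(ids_a).values
    n = A.shape[0]
    if n < 3:
        raise ValueError("Mantel test needs at least 3 entities")
    x = _lower_triangle(A)
    if np.ptp(x) == 0 or np.ptp(_lower_triangle(B)) == 0:
        raise ValueError("Mantel undefined: constant lower triangle")
    x = x - x.mean()
    x /= np.sqrt((x**2).sum())

    def corr_with(Bp: np.ndarray) -> float:
        y = _lower_triangle(Bp)
        y = y - y.mean()
        ss = np.sqrt((y**2).sum())
        return float((x * y).sum() / ss)

    r_obs = corr_with(B)
    if n_perm == "all":
        perms = [p for p in itertools.permutations(range(n))
                 if p != tuple(range(n))]
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(int(n_perm))]
    r_perm = np.array([corr_with(B[np.ix_(p, p)]) for p in perms])
    if alternative == "greater":
        extreme = int((r_perm >= r_obs - 1e-12).sum())
    else:
        extreme = int((np.abs(r_perm) >= abs(r_obs) - 1e-12).sum())
    p = (1 + extreme) / (1 + len(perms))
    return MantelResult(
        r=r_obs,
        n_perm=len(perms),
        p_value=float(p),
        seed=seed,
        alternative=alternative,
    )
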