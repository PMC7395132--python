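"""End-to-end analyses: present-day regions, depth series, fossil series.

These functions chain the stage modules exactly as the three analyses
run: (1) present-day regionalization from per-group phylogenetic beta
dissimilarity, (2) the same regionalization repeated at a series of
phylogenetic depths with Procrustes trajectories and Mantel correlations
anchored at the present, and (3) the fossil interval series. Each
returns an in-memory result object and can serialize every artifact
(CSV/Newick/JSON) into an output directory with a manifest, so a run is
reproducible from its configuration and seed alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .beta import combine_matrices, pairwise_beta_sim, pairwise_pbeta_sim
from .fossil_pipeline import (
    DEFAULT_INTERVALS,
    IntervalResult,
    RegionLookup,
    TimeInterval,
    clean_occurrences,
    interval_beta_series,
)
from .io import (
    DatedTree,
    DissimilarityMatrix,
    FossilOccurrence,
    IncidenceMatrix,
    filter_sites,
    write_incidence,
)
from .ordination import Ordination, mantel, nmds, procrustes_trajectory
from .regions import Dendrogram, RegionAssignment, linkage, select_regions
from .slicing import DEFAULT_DEPTHS, pbeta_at_depth

logger = logging.getLogger("zooregions")

__all__ = [
    "RunConfig",
    "PresentDayResult",
    "DepthSeriesResult",
    "FossilSeriesResult",
    "run_present_day",
    "run_depth_series",
    "run_fossil_series",
]


@dataclass
class RunConfig:
    """Knobs shared by the end-to-end runs.

    Defaults: slice depths 0/5/10/20/40/60 Ma, regions considered from
    2 to 15, UPGMA linkage, explained-dissimilarity threshold 0.9, 20
    NMDS restarts, 999 Mantel permutations.
    """

    depths: Sequence[float] = DEFAULT_DEPTHS
    k_range: Sequence[int] = tuple(range(2, 16))
    linkage_method: str = "upgma"
    selection_rule: str = "silhouette"
    ed_threshold: float = 0.9
    min_land: float = 0.5
    min_richness: int = 5
    nmds_restarts: int = 20
    nmds_max_iter: int = 500
    mantel_permutations: int = 999
    intervals: Sequence[TimeInterval] = DEFAULT_INTERVALS
    seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["depths"] = list(map(float, d["depths"]))
        d["k_range"] = list(map(int, d["k_range"]))
        d["intervals"] = [[iv.name, iv.old, iv.young] for iv in self.intervals]
        return json.dumps(d, indent=1)


def _filtered_groups(
    incidences: Mapping[str, IncidenceMatrix], config: RunConfig
) -> dict[str, IncidenceMatrix]:
    out = {}
    for group, m in incidences.items():
        out[group] = filter_sites(m, config.min_land, config.min_richness)
        logger.info("group %s: %d sites after filtering", group, out[group].shape[0])
    return out


def _group_pbeta(
    trees: Mapping[str, DatedTree],
    incidences: Mapping[str, IncidenceMatrix],
    depth: float,
) -> DissimilarityMatrix:
    mats = [
        pbeta_at_depth(trees[g], incidences[g], depth) for g in sorted(incidences)
    ]
    return combine_matrices(mats) if len(mats) > 1 else mats[0]


@dataclass
class PresentDayResult:
    dissimilarity: DissimilarityMatrix
    dendrogram: Dendrogram
    assignment: RegionAssignment
    ordination: Ordination


def run_present_day(
    trees: Mapping[str, DatedTree] | DatedTree,
    incidences: Mapping[str, IncidenceMatrix] | IncidenceMatrix,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> PresentDayResult:
    """Present-day regionalization from phylogenetic beta dissimilarity.

    Per taxonomic group: filter sites, compute the pairwise phylogenetic
    Simpson dissimilarity, then average the group matrices, cluster
    (UPGMA by default), select the cut, and ordinate. A single tree +
    matrix is treated as one group.
    """
    config = config or RunConfig()
    if isinstance(trees, DatedTree):
        trees = {"all": trees}
    if isinstance(incidences, IncidenceMatrix):
        incidences = {"all": incidences}
    if set(trees) != set(incidences):
        raise ValueError("trees and incidences must cover the same groups")
    filtered = _filtered_groups(incidences, config)
    D = _group_pbeta(trees, filtered, depth=0.0)
    dend = linkage(D, config.linkage_method)
    assignment = select_regions(dend, D, config.k_range,
                                rule=config.selection_rule,
                                ed_threshold=config.ed_threshold)
    ordn = nmds(D, restarts=config.nmds_restarts,
                max_iter=config.nmds_max_iter, seed=config.seed)
    result = PresentDayResult(D, dend, assignment, ordn)
    if outdir is not None:
        _write_present_day(result, config, Path(outdir))
    return result


@dataclass
class DepthSeriesResult:
    matrices: dict  # depth -> DissimilarityMatrix
    assignments: dict  # depth -> RegionAssignment
    ordinations: dict  # depth -> Ordination
    trajectory: pd.DataFrame
    mantel_table: pd.DataFrame


def run_depth_series(
    trees: Mapping[str, DatedTree] | DatedTree,
    incidences: Mapping[str, IncidenceMatrix] | IncidenceMatrix,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> DepthSeriesResult:
    """Regionalization and ordination at every phylogenetic depth.

    Per depth: slice the trees, recompute the combined dissimilarity,
    cluster and ordinate; then align every ordination onto the
    present-day one (Procrustes) and tabulate the Mantel correlation
    between the present-day matrix and each depth's matrix.
    """
    config = config or RunConfig()
    if isinstance(trees, DatedTree):
        trees = {"all": trees}
    if isinstance(incidences, IncidenceMatrix):
        incidences = {"all": incidences}
    filtered = _filtered_groups(incidences, config)
    depths = sorted(float(d) for d in config.depths)
    matrices, assignments, ordinations = {}, {}, {}
    for d in depths:
        D = _group_pbeta(trees, filtered, depth=d)
        matrices[d] = D
        dend = linkage(D, config.linkage_method)
        assignments[d] = select_regions(dend, D, config.k_range,
                                        rule=config.selection_rule,
                                        ed_threshold=config.ed_threshold)
        nonzero = not np.all(D.values == 0)
        ordinations[d] = (
            nmds(D, restarts=config.nmds_restarts,
                 max_iter=config.nmds_max_iter, seed=config.seed)
            if nonzero
            else Ordination(ids=list(D.ids), coords=np.zeros((D.n, 2)), stress=0.0)
        )
        logger.info("depth %.4g Ma: %d regions", d, assignments[d].k)
    ref_depth = min(depths)
    # degenerate slices (all assemblages identical) collapse to a point and
    # carry no ordination signal; they are left out of the trajectory
    traj_ords = {
        d: o for d, o in ordinations.items() if np.ptp(o.coords) > 0 or d == ref_depth
    }
    skipped = sorted(set(depths) - set(traj_ords))
    if skipped:
        logger.info("trajectory skips degenerate depth(s): %s", skipped)
    trajectory = procrustes_trajectory(
        traj_ords, reference_depth=ref_depth,
        groups=assignments[ref_depth].labels,
    )
    rows = []
    D0 = matrices[ref_depth]
    for d in depths:
        if d == ref_depth:
            rows.append({"depth": d, "r": 1.0, "p_value": np.nan})
            continue
        try:
            res = mantel(D0, matrices[d], n_perm=config.mantel_permutations,
                         seed=config.seed)
            rows.append({"depth": d, "r": res.r, "p_value": res.p_value})
        except ValueError as exc:  # constant matrix at a degenerate depth
            logger.info("Mantel skipped at depth %.4g Ma: %s", d, exc)
            rows.append({"depth": d, "r": np.nan, "p_value": np.nan})
    mantel_table = pd.DataFrame(rows)
    result = DepthSeriesResult(matrices, assignments, ordinations,
                               trajectory, mantel_table)
    if outdir is not None:
        _write_depth_series(result, config, Path(outdir))
    return result


@dataclass
class FossilSeriesResult:
    cleaning_report: dict
    intervals: dict  # name -> IntervalResult
    present_day: IntervalResult | None


def run_fossil_series(
    records: Sequence[FossilOccurrence],
    lookup: RegionLookup,
    config: RunConfig | None = None,
    n_indeterminate: int = 0,
    extant_region_lists: IncidenceMatrix | None = None,
    outdir: str | Path | None = None,
) -> FossilSeriesResult:
    """Fossil cleaning + per-interval beta/clustering/ordination.

    ``extant_region_lists`` (a region x taxon incidence) adds a
    present-day comparison computed with the same species-level beta
    machinery as the fossil intervals.
    """
    config = config or RunConfig()
    df, report = clean_occurrences(
        records, intervals=config.intervals, n_indeterminate=n_indeterminate
    )
    series = interval_beta_series(
        df, lookup, intervals=config.intervals,
        nmds_restarts=config.nmds_restarts, seed=config.seed,
    )
    present = None
    if extant_region_lists is not None:
        D = pairwise_beta_sim(extant_region_lists)
        dend = linkage(D, config.linkage_method)
        ordn = (
            nmds(D, restarts=config.nmds_restarts, seed=config.seed)
            if D.n >= 3 and not np.all(D.values == 0)
            else None
        )
        present = IntervalResult("present", extant_region_lists, D, dend, ordn)
    result = FossilSeriesResult(report, series, present)
    if outdir is not None:
        _write_fossil_series(result, config, Path(outdir))
    return result


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _prepare(outdir: Path, config: RunConfig) -> list[str]:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(config.to_json())
    return ["config.json"]


def _finish(outdir: Path, manifest: list[str]) -> None:
    (outdir / "manifest.json").write_text(json.dumps(sorted(manifest), indent=1))


def _write_assignment(a: RegionAssignment, path: Path) -> None:
    a.labels.rename("region").to_frame().to_csv(path, index_label="site")


def _write_present_day(r: PresentDayResult, config: RunConfig, outdir: Path) -> None:
    manifest = _prepare(outdir, config)
    r.dissimilarity.write_csv(outdir / "pbeta_present.csv")
    _write_assignment(r.assignment, outdir / "regions.csv")
    if r.assignment.table is not None:
        r.assignment.table.to_csv(outdir / "per_k_metrics.csv")
    r.ordination.to_dataframe().to_csv(outdir / "nmds.csv", index_label="site")
    (outdir / "dendrogram.nwk").write_text(r.dendrogram.to_newick())
    manifest += ["pbeta_present.csv", "regions.csv", "per_k_metrics.csv",
                 "nmds.csv", "dendrogram.nwk"]
    _finish(outdir, manifest)


def _write_depth_series(r: DepthSeriesResult, config: RunConfig, outdir: Path) -> None:
    manifest = _prepare(outdir, config)
    for d, D in r.matrices.items():
        name = f"pbeta_depth_{d:g}.csv"
        D.write_csv(outdir / name)
        manifest.append(name)
        name = f"regions_depth_{d:g}.csv"
        _write_assignment(r.assignments[d], outdir / name)
        manifest.append(name)
    r.trajectory.to_csv(outdir / "trajectory.csv", index=False)
    r.mantel_table.to_csv(outdir / "mantel.csv", index=False)
    manifest += ["trajectory.csv", "mantel.csv"]
    _finish(outdir, manifest)


def _write_fossil_series(r: FossilSeriesResult, config: RunConfig, outdir: Path) -> None:
    manifest = _prepare(outdir, config)
    (outdir / "cleaning_report.json").write_text(json.dumps(r.cleaning_report, indent=1))
    manifest.append("cleaning_report.json")
    items = dict(r.intervals)
    if r.present_day is not None:
        items["present"] = r.present_day
    for name, res in items.items():
        slug = name.lower().replace(" ", "_").replace("-", "_")
        write_incidence(res.incidence, outdir / f"incidence_{slug}.csv")
        res.dissimilarity.write_csv(outdir / f"beta_{slug}.csv")
        manifest += [f"incidence_{slug}.csv", f"beta_{slug}.csv"]
        if res.dendrogram is not None:
            (outdir / f"dendrogram_{slug}.nwk").write_text(res.dendrogram.to_newick())
            manifest.append(f"dendrogram_{slug}.nwk")
        if res.ordination is not None:
            res.ordination.to_dataframe().to_csv(
                outdir / f"nmds_{slug}.csv", index_label="region"
            )
            manifest.append(f"nmds_{slug}.csv")
    _finish(outdir, manifest)
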