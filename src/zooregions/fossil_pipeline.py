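"""Fossil occurrence cleaning, binning, and interval-wise dissimilarity.

Fossil sampling is too sparse for grid-cell assemblages, so occurrences
are aggregated to coarse spatial units (the present-day zoogeographical
regions) and coarse temporal units (geological intervals), at the genus
level. The cleaning chain is::

    read -> drop indeterminate genera -> deduplicate -> merge localities
         -> assign geological interval -> region x genus incidence

Every step counts what it removed, and the counts are conserved:
``input = kept + indeterminate + duplicates + unassigned``.

Locality merging snaps coordinates to a 0.1-degree grid (floor binning):
records in the same bin share a locality and the bin-center coordinate.
Interval assignment uses the mean of a record's age range; an interval
spans ``[young, old)`` Ma (young bound inclusive), so a mean age equal to
an interval's young bound falls in that interval.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .beta import pairwise_beta_sim
from .io import DissimilarityMatrix, FossilOccurrence, IncidenceMatrix
from .ordination import Ordination, nmds
from .regions import Dendrogram, linkage

logger = logging.getLogger("zooregions")

__all__ = [
    "TimeInterval",
    "DEFAULT_INTERVALS",
    "RegionLookup",
    "dedup_occurrences",
    "merge_localities",
    "assign_interval",
    "bin_records",
    "region_genus_incidence",
    "interval_beta_series",
    "IntervalResult",
]


@dataclass(frozen=True)
class TimeInterval:
    """A geological interval, bounds in Ma, old > young."""

    name: str
    old: float
    young: float

    def __post_init__(self):
        if not self.old > self.young:
            raise ValueError(f"interval {self.name}: old bound must exceed young bound")

    def contains(self, age: float) -> bool:
        """Young bound inclusive, old bound exclusive."""
        return self.young <= age < self.old


def _validate_intervals(intervals: Sequence[TimeInterval]) -> list[TimeInterval]:
    ivs = sorted(intervals, key=lambda iv: iv.young)
    for a, b in zip(ivs, ivs[1:]):
        if a.old > b.young + 1e-12:
            raise ValueError(f"intervals {a.name} and {b.name} overlap")
    return ivs


#: Cenozoic intervals used for the fossil series. The youngest interval
#: closes at 11.8 Ka (0.0118 Ma); its old bound is set flush against the
#: Mid-Late Miocene at 5.3 Ma so the set is non-overlapping.
DEFAULT_INTERVALS = (
    TimeInterval("Eocene", 56.0, 33.9),
    TimeInterval("Oligocene", 33.9, 23.0),
    TimeInterval("Early Miocene", 23.0, 15.9),
    TimeInterval("Mid-Late Miocene", 15.9, 5.3),
    TimeInterval("Pliocene-Pleistocene", 5.3, 0.0118),
)


class RegionLookup:
    """Maps a coordinate to a present-day zoogeographical region.

    Built from labelled reference points (e.g. grid-cell centers with
    their region assignment); queries return the label of the nearest
    reference point.
    """

    def __init__(self, points: np.ndarray, labels: Sequence):
        points = np.asarray(points, dtype=float)
        if points.ndim != 2 or points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        if len(labels) != points.shape[0]:
            raise ValueError("labels length must match points")
        self._tree = cKDTree(points)
        self._labels = list(labels)

    @classmethod
    def from_assignment(cls, coords: pd.DataFrame, labels: pd.Series) -> "RegionLookup":
        """From per-site coordinates (columns x/y or lon/lat) + region labels."""
        cols = ("lon", "lat") if "lon" in coords.columns else ("x", "y")
        pts = coords.loc[labels.index, list(cols)].to_numpy(float)
        return cls(pts, list(labels))

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "RegionLookup":
        """From a CSV-style table with columns lon, lat, region."""
        return cls(table[["lon", "lat"]].to_numpy(float), list(table["region"]))

    def region_of(self, lon: float, lat: float):
        _, idx = self._tree.query([lon, lat])
        return self._labels[int(idx)]

    def regions_of(self, lons, lats) -> list:
        _, idx = self._tree.query(np.column_stack([lons, lats]))
        return [self._labels[int(i)] for i in np.atleast_1d(idx)]

    @property
    def region_set(self) -> set:
        return set(self._labels)


def _to_frame(records: Iterable[FossilOccurrence]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "genus": r.genus, "family": r.family,
            "lon": r.lon, "lat": r.lat,
            "min_age": r.min_age, "max_age": r.max_age,
            "paleo_lon": r.paleo_lon, "paleo_lat": r.paleo_lat,
        })
    return pd.DataFrame(
        rows,
        columns=["genus", "family", "lon", "lat", "min_age", "max_age",
                 "paleo_lon", "paleo_lat"],
    )


def dedup_occurrences(records) -> tuple[pd.DataFrame, int]:
    """Collapse exact duplicates on (genus, lon, lat, min_age, max_age)."""
    df = records if isinstance(records, pd.DataFrame) else _to_frame(records)
    key = ["genus", "lon", "lat", "min_age", "max_age"]
    before = len(df)
    out = df.drop_duplicates(subset=key, keep="first").reset_index(drop=True)
    n_removed = before - len(out)
    logger.info("dedup_occurrences: removed %d duplicate rows", n_removed)
    return out, n_removed


def merge_localities(records, tol: float = 0.1) -> pd.DataFrame:
    """Snap coordinates to a ``tol``-degree grid and assign locality ids.

    Records whose lon and lat floor to the same bin share a locality id
    and the bin-center coordinate. Binning (rather than single-linkage
    chaining of nearby points) is deterministic and idempotent.
    """
    df = records if isinstance(records, pd.DataFrame) else _to_frame(records)
    df = df.copy()
    lon_bin = np.floor(df["lon"].to_numpy(float) / tol)
    lat_bin = np.floor(df["lat"].to_numpy(float) / tol)
    df["lon"] = (lon_bin + 0.5) * tol
    df["lat"] = (lat_bin + 0.5) * tol
    keys = list(zip(lon_bin.astype(int), lat_bin.astype(int)))
    ids = {}
    for k in keys:
        if k not in ids:
            ids[k] = len(ids)
    df["locality_id"] = [ids[k] for k in keys]
    return df


def assign_interval(record, intervals: Sequence[TimeInterval] = DEFAULT_INTERVALS):
    """Interval containing a record's mean age, or ``None`` if outside all.

    Accepts a :class:`FossilOccurrence`, a mapping with min_age/max_age,
    or a plain mean age.
    """
    ivs = _validate_intervals(intervals)
    if isinstance(record, FossilOccurrence):
        mean_age = record.mean_age
    elif np.isscalar(record):
        mean_age = float(record)
    else:
        mean_age = 0.5 * (float(record["min_age"]) + float(record["max_age"]))
    for iv in ivs:
        if iv.contains(mean_age):
            return iv.name
    return None


def bin_records(
    df: pd.DataFrame, intervals: Sequence[TimeInterval] = DEFAULT_INTERVALS
) -> tuple[pd.DataFrame, int]:
    """Attach an ``interval`` column; drop and count unassignable records."""
    ivs = _validate_intervals(intervals)
    mean_age = 0.5 * (df["min_age"] + df["max_age"])
    assigned = pd.Series([None] * len(df), index=df.index, dtype=object)
    for iv in ivs:
        mask = (mean_age >= iv.young) & (mean_age < iv.old)
        assigned[mask] = iv.name
    out = df.assign(interval=assigned)
    n_unassigned = int(assigned.isna().sum())
    out = out[assigned.notna()].reset_index(drop=True)
    logger.info("bin_records: %d records outside all intervals", n_unassigned)
    return out, n_unassigned


def clean_occurrences(
    records: Iterable[FossilOccurrence],
    intervals: Sequence[TimeInterval] = DEFAULT_INTERVALS,
    locality_tol: float = 0.1,
    n_indeterminate: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Full cleaning chain with a conservation-checked report.

    ``n_indeterminate`` carries the count of rows already excluded by
    :func:`zooregions.io.read_fossils` so the report sums to the raw
    input size.
    """
    df = _to_frame(records)
    df, n_dup = dedup_occurrences(df)
    df = merge_localities(df, tol=locality_tol)
    df, n_unassigned = bin_records(df, intervals)
    report = {
        "n_input": len(df) + n_dup + n_unassigned + n_indeterminate,
        "n_indeterminate": n_indeterminate,
        "n_duplicates": n_dup,
        "n_unassigned_interval": n_unassigned,
        "n_kept": len(df),
    }
    assert report["n_input"] == (
        report["n_kept"] + report["n_indeterminate"]
        + report["n_duplicates"] + report["n_unassigned_interval"]
    )
    return df, report


def region_genus_incidence(
    records: pd.DataFrame,
    lookup: RegionLookup,
    interval: str | TimeInterval,
) -> IncidenceMatrix:
    """Region x genus presence table for one geological interval.

    Records are assigned to regions through ``lookup`` (palaeocoordinates
    are used when present, modern coordinates otherwise). Regions with no
    genus in the interval are dropped with a warning; per-region record
    counts go to the log as a sampling-intensity report.
    """
    name = interval.name if isinstance(interval, TimeInterval) else interval
    sub = records[records["interval"] == name]
    if sub.empty:
        raise ValueError(f"no records in interval {name!r}")
    lons = sub["paleo_lon"].where(sub["paleo_lon"].notna(), sub["lon"]) \
        if "paleo_lon" in sub else sub["lon"]
    lats = sub["paleo_lat"].where(sub["paleo_lat"].notna(), sub["lat"]) \
        if "paleo_lat" in sub else sub["lat"]
    regions = lookup.regions_of(lons.to_numpy(float), lats.to_numpy(float))
    tab = pd.crosstab(pd.Series(regions, name="region"),
                      sub["genus"].reset_index(drop=True))
    counts = pd.Series(regions).value_counts()
    logger.info("interval %s: records per region: %s", name, counts.to_dict())
    missing = lookup.region_set - set(tab.index)
    if missing:
        warnings.warn(
            f"interval {name!r}: no records for region(s) {sorted(missing)}",
            UserWarning,
        )
    return IncidenceMatrix((tab > 0).astype(np.int8))


@dataclass
class IntervalResult:
    interval: str
    incidence: IncidenceMatrix
    dissimilarity: DissimilarityMatrix
    dendrogram: Dendrogram | None
    ordination: Ordination | None


def interval_beta_series(
    records: pd.DataFrame,
    lookup: RegionLookup,
    intervals: Sequence[TimeInterval] = DEFAULT_INTERVALS,
    min_genera: int = 2,
    nmds_restarts: int = 20,
    seed: int | None = None,
) -> dict[str, IntervalResult]:
    """Per-interval beta_sim matrix, UPGMA dendrogram, and NMDS.

    Regions holding fewer than ``min_genera`` genera in an interval are
    excluded with a warning. Intervals with fewer than 3 regions still
    yield the matrix and dendrogram, but NMDS is skipped.
    """
    out: dict[str, IntervalResult] = {}
    for iv in _validate_intervals(intervals):
        if not (records["interval"] == iv.name).any():
            warnings.warn(f"interval {iv.name!r} has no records; skipped", UserWarning)
            continue
        inc = region_genus_incidence(records, lookup, iv)
        rich = inc.richness()
        thin = list(rich.index[rich < min_genera])
        if thin:
            warnings.warn(
                f"interval {iv.name!r}: region(s) {thin} have < {min_genera} genera; excluded",
                UserWarning,
            )
            keep = [r for r in inc.site_ids if r not in thin]
            inc = inc.subset_sites(keep)
        D = pairwise_beta_sim(inc)
        dend = linkage(D, "upgma") if D.n >= 2 else None
        if D.n >= 3 and not np.all(D.values == 0):
            ordn = nmds(D, restarts=nmds_restarts, seed=seed)
        else:
            if D.n < 3:
                warnings.warn(
                    f"interval {iv.name!r}: < 3 regions; NMDS skipped", UserWarning
                )
            ordn = None
        out[iv.name] = IntervalResult(iv.name, inc, D, dend, ordn)
    return out
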