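"""Core data containers and on-disk formats.

Four objects circulate through the pipeline:

* :class:`DatedTree` -- a rooted phylogeny with branch lengths in
  millions of years (Ma), read from Newick.
* :class:`IncidenceMatrix` -- a binary site x taxon table with optional
  per-site metadata (grid coordinates, land fraction).
* :class:`DissimilarityMatrix` -- a symmetric matrix of pairwise
  beta-dissimilarity values in [0, 1]; the currency passed between all
  analysis stages.
* :class:`FossilOccurrence` -- a single genus-level fossil record with
  coordinates and an age range.

All of them round-trip losslessly through plain-text formats (Newick,
CSV).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("zooregions")

__all__ = [
    "DatedTree",
    "IncidenceMatrix",
    "DissimilarityMatrix",
    "FossilOccurrence",
    "FossilReadResult",
    "NewickParseError",
    "read_newick",
    "read_incidence",
    "write_incidence",
    "filter_sites",
    "read_fossils",
    "write_fossils",
]

#: Site-level metadata columns recognised in incidence CSV files.
METADATA_COLUMNS = ("x", "y", "lon", "lat", "land_fraction")


class NewickParseError(ValueError):
    """Raised when a Newick file cannot be parsed or lacks branch lengths."""


# ---------------------------------------------------------------------------
# DatedTree
# ---------------------------------------------------------------------------


class DatedTree:
    """A rooted, dated phylogeny with branch lengths in Ma.

    Node ages are derived from branch lengths: a tip has age 0 and an
    internal node's age is its distance to the furthest descendant tip.
    For trees of extant taxa the tree should be ultrametric; departures
    beyond ``1e-6 x root age`` trigger a warning (not an error), since
    slicing at a depth only makes strict sense on a dated, ultrametric
    tree.

    Parameters
    ----------
    tree:
        A ``dendropy.Tree``. Every non-seed edge must carry a finite,
        non-negative length. A length on the root edge is ignored: no
        branch above the root participates in any beta computation.
    """

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        self._tree = tree
        self._validate()
        self._ages = self._compute_ages()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, source: str | Path) -> "DatedTree":
        """Parse a Newick file path or literal Newick string."""
        text = None
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("(")
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        return cls(tree)

    def to_newick(self, path: str | Path | None = None) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        if path is not None:
            Path(path).write_text(s)
        return s

    def _validate(self) -> None:
        n_roots = 0
        labels: list[str] = []
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                n_roots += 1
                continue
            bl = node.edge.length
            if bl is None:
                raise NewickParseError(
                    "missing branch length on an edge "
                    f"(near node {node.taxon.label if node.taxon else '<internal>'})"
                )
            if not np.isfinite(bl) or bl < 0:
                raise ValueError(f"branch length {bl!r} is not finite and >= 0")
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise NewickParseError("unlabelled tip")
                labels.append(node.taxon.label)
        if n_roots != 1:
            raise ValueError("tree must have exactly one root")
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        if not labels:
            raise ValueError("tree has no tips")

    def _compute_ages(self) -> dict:
        ages: dict = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                ages[node] = 0.0
            else:
                ages[node] = max(
                    ages[ch] + ch.edge.length for ch in node.child_nodes()
                )
        root = self._tree.seed_node
        root_age = ages[root]
        # ultrametricity: every tip's depth (root age minus 0) must match
        depths = []
        for leaf in self._tree.leaf_node_iter():
            d = 0.0
            nd = leaf
            while nd.parent_node is not None:
                d += nd.edge.length
                nd = nd.parent_node
            depths.append(d)
        tol = 1e-6 * root_age if root_age > 0 else 1e-9
        if max(depths) - min(depths) > tol:
            warnings.warn(
                f"tree is not ultrametric: tip depths span "
                f"[{min(depths):.6g}, {max(depths):.6g}] Ma",
                UserWarning,
                stacklevel=3,
            )
        return ages

    # -- basic queries -------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def root_age(self) -> float:
        return self._ages[self._tree.seed_node]

    def node_age(self, node) -> float:
        return self._ages[node]

    def branches(self) -> Iterator[tuple[float, frozenset]]:
        """Yield ``(length, descendant tip labels)`` for every non-root branch.

        The branch above the root (if a root edge length exists in the
        file) is never yielded.
        """
        desc: dict = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                desc[node] = frozenset([node.taxon.label])
            else:
                desc[node] = frozenset().union(
                    *(desc[ch] for ch in node.child_nodes())
                )
            if node.parent_node is not None:
                yield float(node.edge.length), desc[node]

    def total_branch_length(self) -> float:
        return sum(length for length, _ in self.branches())

    def prune_to(self, labels: Iterable[str]) -> "DatedTree":
        """Restrict to ``labels``, preserving tip-to-tip path lengths.

        Unifurcations created by the pruning are suppressed with their
        edge lengths added, so distances between retained tips are
        unchanged.
        """
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        if keep == set(self.tip_labels):
            return self
        sub = self._tree.extract_tree_with_taxa_labels(keep)
        sub.seed_node.edge.length = None  # drop any residual root edge
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # subtree may look non-ultrametric
            return DatedTree(sub)

    def mrca_age(self, labels: Iterable[str]) -> float:
        taxa = [self._tree.taxon_namespace.get_taxon(l) for l in labels]
        node = self._tree.mrca(taxa=taxa)
        return self._ages[node]

    def __repr__(self) -> str:
        return f"DatedTree(n_tips={self.n_tips}, root_age={self.root_age:.4g} Ma)"


def read_newick(path: str | Path) -> DatedTree:
    """Read a rooted, dated tree from a Newick file."""
    return DatedTree.from_newick(Path(path))


# ---------------------------------------------------------------------------
# IncidenceMatrix
# ---------------------------------------------------------------------------


class IncidenceMatrix:
    """Binary site x taxon presence/absence table.

    The same container is reused for region x genus tables (fossils) and
    branch x site tables produced by tree slicing (there the "taxa" are
    lineage ids).

    Parameters
    ----------
    values:
        DataFrame indexed by site id with taxon-id columns; strictly 0/1.
    metadata:
        Optional per-site table (same index) with any of the columns
        ``x, y, lon, lat, land_fraction``.
    """

    def __init__(self, values: pd.DataFrame, metadata: pd.DataFrame | None = None):
        v = values.copy()
        arr = v.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            bad = np.argwhere(~np.isin(arr, (0, 1)))[0]
            raise ValueError(
                f"non-binary cell at site {v.index[bad[0]]!r}, "
                f"taxon {v.columns[bad[1]]!r}: {arr[tuple(bad)]!r}"
            )
        if v.index.duplicated().any():
            raise ValueError(f"duplicate site ids: {sorted(v.index[v.index.duplicated()])}")
        if v.columns.duplicated().any():
            raise ValueError(
                f"duplicate taxon ids: {sorted(v.columns[v.columns.duplicated()])}"
            )
        self.values = v.astype(np.int8)
        if metadata is not None:
            metadata = metadata.loc[v.index]
            if "land_fraction" in metadata:
                lf = metadata["land_fraction"].to_numpy(float)
                if ((lf < 0) | (lf > 1)).any():
                    raise ValueError("land_fraction must lie in [0, 1]")
        self.metadata = metadata

    @property
    def site_ids(self) -> list:
        return list(self.values.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def richness(self) -> pd.Series:
        """Number of taxa present per site."""
        return self.values.sum(axis=1)

    def site_taxa(self, site) -> set:
        row = self.values.loc[site]
        return set(row.index[row.to_numpy(bool)])

    def subset_sites(self, sites: Sequence) -> "IncidenceMatrix":
        md = self.metadata.loc[sites] if self.metadata is not None else None
        return IncidenceMatrix(self.values.loc[sites], md)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IncidenceMatrix):
            return NotImplemented
        same_values = self.values.equals(other.values)
        if self.metadata is None or other.metadata is None:
            return same_values and (self.metadata is None) == (other.metadata is None)
        return same_values and self.metadata.equals(other.metadata)

    def __repr__(self) -> str:
        return f"IncidenceMatrix(sites={self.shape[0]}, taxa={self.shape[1]})"


def read_incidence(path: str | Path, sep: str | None = None) -> IncidenceMatrix:
    """Read a site x taxon incidence CSV/TSV.

    The first column holds site ids; columns named ``x, y, lon, lat,
    land_fraction`` are split off as metadata; every remaining column is
    a taxon and must contain only 0/1.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    meta_cols = [c for c in df.columns if c in METADATA_COLUMNS]
    metadata = df[meta_cols].astype(float) if meta_cols else None
    taxa = df.drop(columns=meta_cols)
    return IncidenceMatrix(taxa, metadata)


def write_incidence(m: IncidenceMatrix, path: str | Path, sep: str = ",") -> None:
    df = m.values.copy()
    if m.metadata is not None:
        df = pd.concat([m.metadata, df], axis=1)
    df.index.name = df.index.name or "site"
    df.to_csv(path, sep=sep)


def filter_sites(
    m: IncidenceMatrix,
    min_land: float = 0.5,
    min_richness: int = 5,
) -> IncidenceMatrix:
    """Drop grid cells with low land area or low richness.

    A site is retained when ``land_fraction >= min_land`` **and** its
    richness (row sum) ``>= min_richness``; both thresholds are inclusive
    on the keep side. Taxa that end up globally absent are kept as
    all-zero columns (and counted in the log) so that taxon sets stay
    aligned across groups; downstream beta computations ignore them.
    """
    keep = m.richness() >= min_richness
    if min_land > 0:
        if m.metadata is None or "land_fraction" not in m.metadata:
            raise ValueError("min_land > 0 requires land_fraction metadata")
        keep &= m.metadata["land_fraction"] >= min_land
    if not keep.any():
        raise ValueError("empty matrix after filtering")
    n_dropped = int((~keep).sum())
    out = m.subset_sites(list(m.values.index[keep]))
    n_empty_taxa = int((out.values.sum(axis=0) == 0).sum())
    logger.info(
        "filter_sites: dropped %d of %d sites; %d taxa now globally absent",
        n_dropped, m.shape[0], n_empty_taxa,
    )
    return out


# ---------------------------------------------------------------------------
# DissimilarityMatrix
# ---------------------------------------------------------------------------


class DissimilarityMatrix:
    """Symmetric pairwise dissimilarity in [0, 1] with entity ids."""

    def __init__(self, values: np.ndarray, ids: Sequence):
        values = np.asarray(values, dtype=float)
        ids = list(ids)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("values must be a square matrix")
        if len(ids) != values.shape[0]:
            raise ValueError("ids length must match matrix size")
        if len(set(ids)) != len(ids):
            raise ValueError("entity ids must be unique")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if values.size and (values.min() < -1e-12 or values.max() > 1 + 1e-12):
            raise ValueError("values must lie in [0, 1]")
        self.values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(self.values, 0.0)
        self.ids = ids

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Lower-triangle values in scipy's condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def loc(self, a, b) -> float:
        ia, ib = self.ids.index(a), self.ids.index(b)
        return float(self.values[ia, ib])

    def subset(self, ids: Sequence) -> "DissimilarityMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DissimilarityMatrix(self.values[np.ix_(idx, idx)], list(ids))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DissimilarityMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("row and column ids must match")
        return cls(df.to_numpy(float), list(df.index))

    def write_csv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "id"
        df.to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls.from_dataframe(df)

    def __repr__(self) -> str:
        return f"DissimilarityMatrix(n={self.n})"


# ---------------------------------------------------------------------------
# FossilOccurrence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FossilOccurrence:
    """One genus-level fossil record with an age range in Ma."""

    genus: str
    lon: float
    lat: float
    min_age: float
    max_age: float
    family: str | None = None
    source: str | None = None
    paleo_lon: float | None = None
    paleo_lat: float | None = None

    def __post_init__(self):
        if not self.genus:
            raise ValueError("genus must be non-empty")
        if self.min_age > self.max_age:
            raise ValueError(
                f"min_age {self.min_age} > max_age {self.max_age} for {self.genus}"
            )
        if abs(self.lat) > 90:
            raise ValueError(f"latitude {self.lat} out of range for {self.genus}")

    @property
    def mean_age(self) -> float:
        return 0.5 * (self.min_age + self.max_age)


class FossilReadResult(NamedTuple):
    records: list
    n_indeterminate: int


#: Genera flagged as unidentifiable at the genus level: open nomenclature
#: ("indet.", "sp.", "cf."-style suffixes) or quoted names.
INDETERMINATE_PATTERN = re.compile(r'(\bindet\.?$)|(\bsp{1,2}\.?$)|["“”]')


def read_fossils(
    path: str | Path,
    indeterminate_pattern: re.Pattern | str = INDETERMINATE_PATTERN,
) -> FossilReadResult:
    """Read a fossil occurrence CSV, excluding indeterminate genera.

    Required columns: ``genus, lon, lat, min_age, max_age``; optional:
    ``family, source, paleo_lon, paleo_lat``. Rows whose genus is empty
    or matches ``indeterminate_pattern`` are excluded and counted.
    Invalid numbers or inverted age ranges raise with the row number.
    """
    if isinstance(indeterminate_pattern, str):
        indeterminate_pattern = re.compile(indeterminate_pattern)
    df = pd.read_csv(path, dtype={"genus": str, "family": str, "source": str})
    required = {"genus", "lon", "lat", "min_age", "max_age"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fossil CSV missing columns: {sorted(missing)}")
    records: list[FossilOccurrence] = []
    n_indet = 0
    for i, row in df.iterrows():
        genus = "" if pd.isna(row["genus"]) else str(row["genus"]).strip()
        if not genus or indeterminate_pattern.search(genus):
            n_indet += 1
            continue
        try:
            rec = FossilOccurrence(
                genus=genus,
                lon=float(row["lon"]),
                lat=float(row["lat"]),
                min_age=float(row["min_age"]),
                max_age=float(row["max_age"]),
                family=None if "family" not in df or pd.isna(row.get("family")) else str(row["family"]),
                source=None if "source" not in df or pd.isna(row.get("source")) else str(row["source"]),
                paleo_lon=float(row["paleo_lon"]) if "paleo_lon" in df and pd.notna(row.get("paleo_lon")) else None,
                paleo_lat=float(row["paleo_lat"]) if "paleo_lat" in df and pd.notna(row.get("paleo_lat")) else None,
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"fossil CSV row {i}: {exc}") from exc
        records.append(rec)
    logger.info(
        "read_fossils: %d records kept, %d indeterminate rows excluded",
        len(records), n_indet,
    )
    return FossilReadResult(records, n_indet)


def write_fossils(records: Iterable[FossilOccurrence], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "genus": r.genus,
                "family": r.family,
                "lon": r.lon,
                "lat": r.lat,
                "min_age": r.min_age,
                "max_age": r.max_age,
                "source": r.source,
                "paleo_lon": r.paleo_lon,
                "paleo_lat": r.paleo_lat,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
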