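# Methods

## Model and procedure

The package reconstructs how faunal regions relate to each other through
time, under the assumption that a region is a set of geographically
coherent grid cells whose assemblages are more similar within than
between regions. Two routes are implemented.

**Phylogenetic route.** Given a rooted, dated, (near-)ultrametric tree
with branch lengths in Ma and a binary site × taxon incidence matrix,
the pairwise dissimilarity between sites is phylogenetic Simpson
turnover: with `a` the total length of branches whose descendant tips
occur in both sites and `b`, `c` the lengths unique to each,
`pbeta_sim = min(b, c) / (a + min(b, c))`. The tree is pruned to the
taxa present in the matrix before anything else, and the branch above
the (pruned) root never enters the components — two sites holding
disjoint halves of the tree are therefore maximally dissimilar rather
than sharing a trunk. Slicing the tree at depth *t* removes all branch
segments younger than *t*; each lineage crossing the slice becomes one
analytical unit whose range is the union of its descendants' ranges, and
the same pairwise computation runs on the remaining tree and the merged
branch × site matrix. Repeating this over a depth grid (default 0, 5,
10, 20, 40, 60 Ma) gives a depth-indexed series of matrices.

**Fossil route.** Genus-level occurrences are cleaned (indeterminate
genera excluded, exact duplicates removed, localities merged on a
0.1° grid), assigned to geological intervals by the mean of their age
range, and aggregated into region × genus incidence tables using a
nearest-reference-point region lookup. Simpson turnover on these tables
gives one dissimilarity matrix per interval.

Both routes end in the same analyses: UPGMA dendrograms with cut
selection, 2-D non-metric multidimensional scaling, Procrustes
superimposition of slice ordinations onto the present-day one, and
Mantel permutation tests against the present-day matrix.

## Conventions and numerical choices

* **Slicing.** Crossing branches are truncated at the slice (only the
  segment older than *t* is kept); retaining the full pendant length
  would double-count evolution younger than the slice and is available
  as `truncate=False` for sensitivity analyses. A node whose age equals
  *t* exactly belongs to the older side: its child branches are removed
  and it becomes a crossing lineage. Depths at or beyond the root age
  are degenerate — a single lineage holds every tip, all pairwise values
  are defined as 0 with a warning, and such slices are excluded from
  Procrustes trajectories (they collapse to a point).
* **Site filtering.** Cells with land fraction < 0.5 or richness < 5
  are removed before any beta computation; thresholds are inclusive on
  the keep side. Taxa that become globally absent stay as zero columns
  so taxon sets remain aligned across groups.
* **Multi-group combination.** Per-group matrices are combined by the
  unweighted element-wise mean, restricted to the sites shared by all
  groups.
* **Linkage.** The eight agglomerative methods are single, complete,
  UPGMA, WPGMA, UPGMC, WPGMC, and the two Ward variants (ward1 applies
  the Ward update to the dissimilarities, ward2 to their squares; ward1
  is computed through the sqrt/square transform equivalence). Ties in
  agglomeration follow scipy's nearest-neighbor-chain ordering;
  continuous dissimilarities are tie-free in practice.
* **Cut selection.** For each k in 2..15 the dendrogram is cut and
  scored by explained dissimilarity (ED, the between-cluster share of
  total pairwise dissimilarity) and mean silhouette width. The default
  rule picks the k maximizing mean silhouette. ED was considered as the
  primary criterion, but on landscapes with a clear planted k the ED
  curve rises steeply to the natural number of regions and then
  plateaus — right around typical cutoff values — so a fixed ED
  threshold is knife-edge and can wander several k past the silhouette
  optimum; the silhouette has a sharp interior maximum at the natural k.
  The ED-threshold rule (smallest k with ED ≥ 0.9, configurable) remains
  available as `rule='ed'`, and the full per-k table is always emitted
  so any other rule can be applied.
* **NMDS.** Kruskal stress-1 with monotone regression, 2-D, best of 20
  random restarts (seed-derived), convergence tolerance 1e-7, max 500
  iterations. Coordinates are centered at the origin; stress below ~0.2
  is treated as an interpretable ordination.
* **Procrustes.** Least-squares superimposition (translation +
  orthogonal rotation + optional isotropic scaling) of each slice's
  ordination onto the present-day reference; reflections are allowed by
  default since only shape correspondence matters. The rotation comes
  from the SVD of the cross-covariance; with reflections disallowed the
  determinant is constrained to +1 by flipping the smallest singular
  direction.
* **Mantel.** Pearson correlation of lower triangles; the null permutes
  the entities of the second matrix (simultaneous row/column shuffles);
  one-sided "greater" by default with the add-one p-value
  `(1 + #extreme) / (1 + n_perm)`, so p is never exactly 0. `n_perm='all'`
  enumerates every non-identity permutation for exact small-n tests.
* **Wilcoxon comparison of linkage methods.** Paired over matrices on
  cophenetic correlations; two-sided, zero differences dropped, exact
  null for small tie-free samples (scipy's auto rule). All-zero
  differences return p = 1 with a warning. Matrix/method combinations
  with undefined cophenetic correlation (e.g. single linkage on a
  matrix whose zero-graph is connected) are recorded as NaN and dropped
  pairwise.
* **Fossil intervals.** Eocene 56.0–33.9, Oligocene 33.9–23.0, Early
  Miocene 23.0–15.9, Mid–Late Miocene 15.9–5.3, Pliocene–Pleistocene
  5.3–0.0118 Ma. An interval spans [young, old) with the young bound
  inclusive, so a mean age on a boundary falls in the younger interval;
  ages outside all intervals are excluded and counted. Locality merging
  uses fixed floor-binning (deterministic and idempotent) rather than
  single-linkage chaining of nearby points.

## Synthetic data: what it emulates and what it does not

The generator plants K contiguous regions (vertical strips) on a
rectangular lattice. Each region contributes one clade whose split ages
follow a user-set divergence schedule (default: (R1,R2) at 10 Ma,
(R3,R4) at 30 Ma, root at 60 Ma — chosen so that slices at the default
depth grid straddle both splits and the deepest informative slice at
40 Ma retains two lineages); within-clade joins are uniform below 95%
of the clade's split age. Species occupy home-region cells with
probability 0.8 and foreign cells with probability 0.05 — values that
make regions well separated but not trivially disjoint (cross-region
Simpson turnover around 0.5–0.9 versus ~0.2 within). Sites are
resampled until they reach the minimum richness of 5, mirroring the
richness filter. Fossils are sampled per interval, species and occupied
cell with a preservation probability (default 0.3, roughly sparse-record
territory; 1.0 reproduces the extant incidence exactly by construction).

The generator does **not** emulate range cohesion gradients, dispersal
kernels, extinction, polytomy-rich trees, uneven spatial sampling of
fossils, or taxonomic noise. Passing recovery tests therefore shows the
inference chain is correct and well calibrated on data matching its
assumptions — not that real occurrence databases are free of the
sampling artifacts the cleaning steps only partially address.

## Problem sizes

The test suite and the acceptance script run the planted scenario at
20 × 20 cells × 100 species over 25–50 replicate seeds, the oracle
comparisons on trees of up to 12 tips (where exhaustive branch-set and
permutation enumeration is feasible), and the Mantel type-I calibration
at n = 10 entities with 999 permutations × 1000 replicates. The worked
examples use a 12 × 12 grid so each script finishes in seconds to tens
of seconds.

## Known limitations

* Non-ultrametric trees are accepted with a warning, but slice depths
  are only meaningful on dated, ultrametric trees.
* Palaeocoordinate rotation is out of scope; records carry optional
  pre-rotated `paleo_lon`/`paleo_lat` columns that take precedence over
  modern coordinates in the region lookup.
* Rasterizing range polygons, reading shapefiles, and map projections
  are upstream of this package: it consumes incidence matrices.
* The region lookup is nearest-reference-point; fossil records far
  outside the reference point cloud are still assigned to the nearest
  region rather than rejected.
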