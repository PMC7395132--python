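# zooregions

Reconstructing the temporal evolution of zoogeographical regions from
two complementary lines of evidence:

* **Phylogenetic time** — extant assemblages on a grid, scored by
  phylogenetic beta dissimilarity computed at successive slice depths of
  a dated phylogeny. Cutting the tree at depth *t* (Ma before present)
  collapses every lineage crossing the slice into one analytical unit
  whose range is the union of its descendants' ranges, so deeper slices
  progressively ignore recent divergence.
* **Geological time** — fossil assemblages binned into geological
  intervals and coarse regions, scored by compositional beta
  dissimilarity at the genus level.

Both feed the same downstream machinery: UPGMA clustering into regions,
cut selection by explained dissimilarity and silhouette width, NMDS
ordination, Procrustes trajectories through time, and Mantel tests
between dissimilarity matrices. The package is aimed at biogeographers
who already have (or can simulate) a dated tree, a site × taxon
incidence table, and optionally a fossil occurrence table.

## The statistic

For two assemblages with `a` shared and `b`, `c` unique elements,
Simpson's beta dissimilarity is the turnover-only component

```
beta_sim = min(b, c) / (a + min(b, c))
```

It is 0 when one assemblage nests inside the other and 1 when they share
nothing, and is insensitive to richness differences. The species-level
version counts taxa; the phylogenetic version (`pbeta_sim`) measures
`a`, `b`, `c` as branch lengths of the dated tree: a branch is present
in a site when at least one of its descendant tips occurs there. No
branch above the root of the (pruned) tree is counted. Slicing the tree
at depth *t* and recomputing `pbeta_sim` on the branch × site matrix
yields the dissimilarity structure "as seen" from *t* Ma.

## Worked example

`examples/01_present_day_regions.py` plants four regions (one clade
each, splits at 10/30/60 Ma) on a 12 × 12 grid and runs the present-day
regionalization:

```
sites: 144, species: 60
selected regions: k = 4
explained dissimilarity at the cut: 0.918
mean silhouette width at the cut:   0.669
NMDS stress (2-D):                  0.187
adjusted Rand index vs planted truth: 1.000
```

The cut recovers the planted number of regions and labels every cell
correctly (ARI = 1). `examples/02_depth_series.py` then slices the same
data through time:

```
depth (Ma)  regions  Mantel r vs present
        0        4  1.000  (reference)
        5        4  0.929
       10        3  0.794
       20        2  0.721
       40        2  0.434
       60        1  nan  (degenerate slice)
```

The two regions planted to diverge at 10 Ma merge at the 10 Ma slice,
the 30 Ma pair by 40 Ma, and past the 60 Ma root a single lineage
remains; the Mantel correlation with the present-day matrix decays
accordingly. `examples/03_fossil_intervals.py` runs the fossil pipeline
(cleaning → interval binning → region × genus beta series) and
`examples/04_compare_linkages.py` ranks the eight linkage methods by
cophenetic correlation (UPGMA wins, which is why it is the default).

A thin CLI mirrors the workflows:

```
zooregions simulate --outdir sim --seed 3 --grid 12
zooregions regionalize --tree sim/tree.nwk --incidence sim/incidence.csv \
    --outdir run --seed 3
zooregions depth-series --tree sim/tree.nwk --incidence sim/incidence.csv \
    --outdir run_depths --depths 0,5,10,20,40,60
```

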