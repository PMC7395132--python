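"""Fossil-assemblage dissimilarity across geological intervals.

Samples synthetic fossil occurrences from the planted ranges (30%
preservation per interval), cleans them (deduplication, locality
binning, mean-age interval assignment), aggregates to region x genus
tables, and computes the per-interval Simpson dissimilarity with UPGMA
clustering and NMDS.
"""

import warnings

import zooregions as zr

scenario = zr.SyntheticScenario(seed=42, preservation=0.3, grid_width=12,
                                 grid_height=12, species_per_region=15)
sim = zr.simulate_scenario(scenario)
records = [
    zr.FossilOccurrence(r.genus, r.lon, r.lat, r.min_age, r.max_age)
    for r in sim["fossils"].itertuples()
]
lookup = zr.RegionLookup.from_assignment(
    sim["incidence"].metadata.rename(columns={"x": "lon", "y": "lat"}),
    sim["truth"],
)

with warnings.catch_warnings():
    warnings.simplefilter("ignore", UserWarning)
    result = zr.run_fossil_series(records, lookup, zr.RunConfig(seed=42, nmds_restarts=8))

print("cleaning report:", result.cleaning_report)
print("\ninterval              regions  mean beta_sim  dendrogram")
for name, res in result.intervals.items():
    off = res.dissimilarity.condensed()
    dend = res.dendrogram.to_newick() if res.dendrogram else "-"
    print(f"{name:21s} {res.dissimilarity.n:7d}  {off.mean():12.3f}  {dend}")
# All input records are accounted for (kept + duplicates + unassigned).
# With four planted regions and genus-level sampling, the per-interval
# dendrograms should group the two recently-diverged region pairs
# (R1,R2) and (R3,R4) together, mirroring the planted divergence order.
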