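import numpy as np
import pandas as pd
import pytest

import zooregions as zr
from conftest import oracle_upgma_cophenetic, random_dissimilarity


class TestLinkage:
    def test_three_point_upgma_by_hand(self):
        D = zr.DissimilarityMatrix(
            np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]]),
            ["p1", "p2", "p3"],
        )
        dend = zr.linkage(D, "upgma")
        heights = sorted(dend.merges[:, 2])
        assert heights[0] == pytest.approx(0.1)
        assert heights[1] == pytest.approx(0.9)
        # the first merge joins p1 and p2
        assert set(dend.merges[0, :2].astype(int)) == {0, 1}

    @pytest.mark.parametrize("method", zr.LINKAGE_METHODS)
    def test_two_points_merge_at_their_distance(self, method):
        D = zr.DissimilarityMatrix(np.array([[0, 0.3], [0.3, 0]]), ["a", "b"])
        dend = zr.linkage(D, method)
        assert dend.merges.shape == (1, 4)
        assert dend.merges[0, 2] == pytest.approx(0.3)

    def test_upgma_matches_exhaustive_agglomeration(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            D = random_dissimilarity(rng, int(rng.integers(3, 9)))
            dend = zr.linkage(D, "upgma")
            got = dend.cophenetic()
            iu = np.triu_indices(D.n, 1)
            expected = oracle_upgma_cophenetic(D)[iu]
            np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_monotone_heights_for_monotone_linkages(self):
        rng = np.random.default_rng(2)
        D = random_dissimilarity(rng, 10)
        for method in ("single", "complete", "upgma"):
            h = zr.linkage(D, method).merges[:, 2]
            assert (np.diff(h) >= -1e-12).all()

    def test_upgma_cophenetic_is_ultrametric(self):
        rng = np.random.default_rng(4)
        D = random_dissimilarity(rng, 12)
        from scipy.spatial.distance import squareform
        C = squareform(zr.linkage(D, "upgma").cophenetic())
        n = C.shape[0]
        worst = 0.0
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    worst = max(worst, C[i, j] - max(C[i, k], C[k, j]))
        assert worst <= 1e-12

    def test_cut_nesting(self):
        """Cutting at k then k+1 refines the partition."""
        rng = np.random.default_rng(8)
        D = random_dissimilarity(rng, 12)
        dend = zr.linkage(D, "upgma")
        for k in range(2, 11):
            a = dend.cut(k)
            b = dend.cut(k + 1)
            # every cluster at k+1 sits inside one cluster at k
            for lbl in b.unique():
                assert a[b == lbl].nunique() == 1


class TestCopheneticCorrelation:
    def test_ultrametric_input_is_reproduced_exactly(self):
        rng = np.random.default_rng(9)
        base = random_dissimilarity(rng, 8)
        from scipy.spatial.distance import squareform
        coph = squareform(zr.linkage(base, "upgma").cophenetic())
        D = zr.DissimilarityMatrix(coph / max(coph.max(), 1.0), base.ids)
        dend = zr.linkage(D, "upgma")
        assert zr.cophenetic_correlation(dend, D) == pytest.approx(1.0, abs=1e-12)

    def test_three_point_toy_is_perfect(self):
        D = zr.DissimilarityMatrix(
            np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]]),
            ["p1", "p2", "p3"],
        )
        dend = zr.linkage(D, "upgma")
        assert zr.cophenetic_correlation(dend, D) == pytest.approx(1.0)

    def test_bounded(self):
        rng = np.random.default_rng(10)
        D = random_dissimilarity(rng, 9)
        for method in zr.LINKAGE_METHODS:
            c = zr.cophenetic_correlation(zr.linkage(D, method), D)
            assert -1.0 <= c <= 1.0


class TestCompareLinkages:
    def test_table_shapes_and_pairwise_count(self):
        rng = np.random.default_rng(12)
        mats = [random_dissimilarity(rng, 8) for _ in range(4)]
        scores, pvals = zr.compare_linkage_methods(mats)
        assert scores.shape == (5, 8)  # 4 matrices + mean row
        assert pvals.shape == (8, 8)
        offdiag = pvals.values[np.triu_indices(8, 1)]
        assert len(offdiag) == 28
        assert ((offdiag > 0) & (offdiag <= 1)).all()

    def test_single_matrix_rejected(self):
        rng = np.random.default_rng(13)
        with pytest.raises(ValueError):
            zr.compare_linkage_methods([random_dissimilarity(rng, 5)])

    def test_wilcoxon_all_positive_n6_exact(self):
        # enumeration: 2 of the 2^6 sign assignments are as extreme
        assert zr.wilcoxon_signed_rank([0.02, 0.01, 0.03, 0.05, 0.04, 0.06]) \
            == pytest.approx(2 / 64)

    def test_wilcoxon_all_zero_convention(self):
        with pytest.warns(UserWarning, match="zero"):
            assert zr.wilcoxon_signed_rank([0.0, 0.0, 0.0]) == 1.0


class TestCutMetrics:
    def test_explained_dissimilarity_extremes(self, planted_pairs_matrix):
        D = planted_pairs_matrix
        assert zr.explained_dissimilarity(D, ["g"] * 4) == 0.0
        assert zr.explained_dissimilarity(D, list("wxyz")) == 1.0

    def test_explained_dissimilarity_planted_pairs(self, planted_pairs_matrix):
        ed = zr.explained_dissimilarity(planted_pairs_matrix, ["u", "u", "v", "v"])
        assert ed == pytest.approx(3.6 / 3.8)

    def test_mean_silhouette_planted_pairs(self, planted_pairs_matrix):
        s = zr.mean_silhouette(planted_pairs_matrix, ["u", "u", "v", "v"])
        assert s == pytest.approx((0.9 - 0.1) / 0.9)

    def test_equidistant_points_have_zero_silhouette(self):
        vals = np.full((4, 4), 0.5)
        np.fill_diagonal(vals, 0)
        D = zr.DissimilarityMatrix(vals, list("abcd"))
        assert zr.mean_silhouette(D, ["u", "u", "v", "v"]) == pytest.approx(0.0)

    def test_silhouette_k_bounds(self, planted_pairs_matrix):
        with pytest.raises(ValueError):
            zr.mean_silhouette(planted_pairs_matrix, ["g"] * 4)

    def test_ed_monotone_in_k_along_dendrogram_cuts(self):
        rng = np.random.default_rng(21)
        D = random_dissimilarity(rng, 14)
        dend = zr.linkage(D, "upgma")
        eds = [zr.explained_dissimilarity(D, dend.cut(k)) for k in range(1, 14)]
        assert (np.diff(eds) >= -1e-12).all()
        assert all(0 <= e <= 1 for e in eds)


class TestSelectRegions:
    def test_two_perfect_clusters(self):
        vals = np.zeros((6, 6))
        vals[:3, 3:] = 1.0
        vals[3:, :3] = 1.0
        D = zr.DissimilarityMatrix(vals, list("abcdef"))
        dend = zr.linkage(D, "upgma")
        a = zr.select_regions(dend, D, k_range=range(2, 5))
        assert a.k == 2
        assert a.explained_dissimilarity == pytest.approx(1.0)

    def test_ed_rule_picks_smallest_reaching_threshold(self):
        vals = np.zeros((6, 6))
        vals[:3, 3:] = 1.0
        vals[3:, :3] = 1.0
        D = zr.DissimilarityMatrix(vals, list("abcdef"))
        dend = zr.linkage(D, "upgma")
        a = zr.select_regions(dend, D, k_range=range(2, 5), rule="ed")
        assert a.k == 2

    def test_all_zero_matrix_degenerates_to_one_region(self):
        D = zr.DissimilarityMatrix(np.zeros((5, 5)), list("abcde"))
        dend = zr.linkage(D, "upgma")
        with pytest.warns(UserWarning, match="single region"):
            a = zr.select_regions(dend, D, k_range=range(2, 4))
        assert a.k == 1

    def test_per_k_table_always_emitted(self, planted_pairs_matrix):
        dend = zr.linkage(planted_pairs_matrix, "upgma")
        a = zr.select_regions(dend, planted_pairs_matrix, k_range=[2, 3])
        assert list(a.table.index) == [2, 3]
        assert {"explained_dissimilarity", "mean_silhouette"} <= set(a.table.columns)


class TestSpatialDiagnostics:
    @pytest.fixture
    def lattice(self):
        coords = pd.DataFrame(
            [(x, y) for x in range(4) for y in range(2)],
            columns=["x", "y"],
            index=[f"c{x}{y}" for x in range(4) for y in range(2)],
        )
        labels = pd.Series(
            ["L" if c.x < 2 else "R" for c in coords.itertuples()],
            index=coords.index,
        )
        return coords, labels

    def test_boundary_strength_hand_computed(self, lattice):
        coords, labels = lattice
        n = len(coords)
        vals = np.full((n, n), 0.9)
        np.fill_diagonal(vals, 0.0)
        ids = list(coords.index)
        same = labels.to_numpy()[:, None] == labels.to_numpy()[None, :]
        vals[same] = 0.1
        np.fill_diagonal(vals, 0.0)
        D = zr.DissimilarityMatrix(vals, ids)
        a = zr.RegionAssignment(labels, 2, 1.0, 1.0)
        adj = zr.lattice_adjacency(coords, rule="rook")
        table = zr.boundary_strength(a, D, adj)
        assert len(table) == 1
        assert table.iloc[0]["mean_dissimilarity"] == pytest.approx(0.9)
        assert table.iloc[0]["n_adjacent_pairs"] == 2  # two cross-boundary edges

    def test_non_adjacent_regions_absent(self, lattice):
        coords, _ = lattice
        labels = pd.Series(
            ["A" if c.x == 0 else ("B" if c.x < 3 else "C")
             for c in coords.itertuples()],
            index=coords.index,
        )
        n = len(coords)
        vals = np.full((n, n), 0.5)
        np.fill_diagonal(vals, 0.0)
        D = zr.DissimilarityMatrix(vals, list(coords.index))
        a = zr.RegionAssignment(labels, 3, 1.0, 1.0)
        table = zr.boundary_strength(a, D, zr.lattice_adjacency(coords))
        pairs = set(map(tuple, table[["region_a", "region_b"]].to_numpy()))
        assert ("A", "C") not in pairs  # A and C never touch

    def test_coherence_contiguous_block_is_one(self, lattice):
        coords, labels = lattice
        a = zr.RegionAssignment(labels, 2, 1.0, 1.0)
        table = zr.geographic_coherence(a, zr.lattice_adjacency(coords))
        assert (table["largest_component_fraction"] == 1.0).all()
        assert not table["flagged"].any()

    def test_split_region_flagged(self):
        coords = pd.DataFrame(
            {"x": list(range(10)), "y": [0] * 10},
            index=[f"c{i}" for i in range(10)],
        )
        # region S occupies cells 0-6 except a gap: 7 + 3 split
        labels = pd.Series(
            ["S"] * 4 + ["T"] * 3 + ["S"] * 3, index=coords.index
        )
        a = zr.RegionAssignment(labels, 2, 1.0, 1.0)
        table = zr.geographic_coherence(a, zr.lattice_adjacency(coords))
        row = table.set_index("region").loc["S"]
        assert row["largest_component_fraction"] == pytest.approx(4 / 7)
        assert bool(row["flagged"])

    def test_singleton_region_coherent(self):
        coords = pd.DataFrame({"x": [0, 1, 2], "y": [0, 0, 0]},
                              index=["a", "b", "c"])
        labels = pd.Series(["u", "u", "v"], index=coords.index)
        a = zr.RegionAssignment(labels, 2, 1.0, 1.0)
        table = zr.geographic_coherence(a, zr.lattice_adjacency(coords))
        assert table.set_index("region").loc["v", "largest_component_fraction"] == 1.0
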