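import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import zooregions as zr
from conftest import (
    oracle_mantel_exact,
    oracle_procrustes_residual,
    random_dissimilarity,
)


def planted_configuration(seed=0, n=20):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2))
    return X, squareform(pdist(X))


class TestNMDS:
    def test_recovers_embeddable_configuration(self):
        _, D = planted_configuration()
        ordn = zr.nmds(D, restarts=20, seed=1)
        assert ordn.stress <= 0.01
        assert np.allclose(ordn.coords.mean(axis=0), 0.0, atol=1e-9)

    def test_rank_invariance_under_monotone_transform(self):
        _, D = planted_configuration()
        s1 = zr.nmds(D, restarts=10, seed=1).stress
        s2 = zr.nmds(np.sqrt(D), restarts=10, seed=1).stress
        assert s2 <= 0.01
        assert abs(s1 - s2) < 0.01  # same ranks, same achievable stress

    def test_simplex_has_zero_stress(self):
        vals = np.full((3, 3), 0.6)
        np.fill_diagonal(vals, 0.0)
        ordn = zr.nmds(zr.DissimilarityMatrix(vals, list("abc")),
                       restarts=5, seed=0)
        assert ordn.stress == pytest.approx(0.0, abs=1e-4)

    def test_deterministic_for_fixed_seed(self):
        _, D = planted_configuration(3)
        a = zr.nmds(D, restarts=5, seed=42)
        b = zr.nmds(D, restarts=5, seed=42)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            zr.nmds(np.zeros((4, 4)))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            zr.nmds(np.array([[0.0, 1.0], [1.0, 0.0]]))


class TestProcrustes:
    def test_similarity_transform_is_recovered_exactly(self):
        X, _ = planted_configuration(5)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        Y = 2.5 * X @ R + np.array([3.0, -1.0])
        res = zr.procrustes(X, Y)
        assert res.residual_ss < 1e-10
        np.testing.assert_allclose(res.aligned, X, atol=1e-8)
        # rotation is orthogonal
        np.testing.assert_allclose(res.rotation @ res.rotation.T, np.eye(2),
                                   atol=1e-10)

    def test_reflection_blocked_leaves_residual(self):
        X, _ = planted_configuration(6)
        Y = X.copy()
        Y[:, 0] = -Y[:, 0]  # pure reflection
        allowed = zr.procrustes(X, Y, allow_reflection=True)
        blocked = zr.procrustes(X, Y, allow_reflection=False)
        assert allowed.residual_ss < 1e-10
        assert blocked.residual_ss > 1e-6
        assert np.linalg.det(blocked.rotation) == pytest.approx(1.0)

    @pytest.mark.parametrize("allow_scaling,allow_reflection",
                             [(True, True), (True, False),
                              (False, True), (False, False)])
    def test_matches_angle_scan_oracle(self, allow_scaling, allow_reflection):
        rng = np.random.default_rng(30)
        X = rng.normal(size=(12, 2))
        Y = rng.normal(size=(12, 2))
        res = zr.procrustes(X, Y, allow_scaling=allow_scaling,
                            allow_reflection=allow_reflection)
        oracle = oracle_procrustes_residual(
            X, Y, allow_scaling=allow_scaling, allow_reflection=allow_reflection
        )
        assert res.residual_ss == pytest.approx(oracle, abs=1e-6)

    def test_id_matching_between_ordinations(self):
        X, _ = planted_configuration(8, n=6)
        a = zr.Ordination(ids=list("abcdef"), coords=X, stress=0.0)
        # same points, permuted id order
        perm = [3, 1, 0, 5, 4, 2]
        b = zr.Ordination(ids=[list("abcdef")[i] for i in perm],
                          coords=X[perm], stress=0.0)
        res = zr.procrustes(a, b)
        assert res.residual_ss < 1e-18

    def test_too_few_entities_rejected(self):
        with pytest.raises(ValueError):
            zr.procrustes(np.zeros((1, 2)), np.zeros((1, 2)))


class TestTrajectory:
    def _ordinations(self, coords_by_depth):
        return {
            d: zr.Ordination(ids=list(range(len(c))), coords=np.asarray(c, float),
                             stress=0.0)
            for d, c in coords_by_depth.items()
        }

    def test_identical_ordinations_give_zero_arrows(self):
        X, _ = planted_configuration(9, n=8)
        ords = self._ordinations({0.0: X, 5.0: X, 10.0: X})
        table = zr.procrustes_trajectory(ords)
        disp = zr.ordination.trajectory_displacements(table)
        assert (disp["length"] < 1e-10).all()

    def test_rigid_rotations_are_removed_by_alignment(self):
        X, _ = planted_configuration(10, n=8)
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        ords = self._ordinations({0.0: X, 5.0: X @ R, 10.0: X @ R @ R})
        table = zr.procrustes_trajectory(ords)
        disp = zr.ordination.trajectory_displacements(table)
        assert (disp["length"] < 1e-8).all()

    def test_planted_drift_is_detected(self):
        X, _ = planted_configuration(11, n=12)
        delta = np.array([2.0, 0.0])
        drifted = X.copy()
        # one small "region" shifted in the deep slice; keeping it a minority
        # limits how much of the drift the centroid alignment absorbs
        drifted[:3] += delta
        ords = self._ordinations({0.0: X, 40.0: drifted})
        groups = pd.Series(["moved"] * 3 + ["still"] * 9, index=range(12))
        table = zr.procrustes_trajectory(ords, groups=groups)
        per_entity = table[~table["id"].astype(str).str.endswith("__mean")]
        disp = zr.ordination.trajectory_displacements(per_entity)
        disp["group"] = disp["id"].map(groups)
        mean_moved = disp.loc[disp.group == "moved", "length"].mean()
        mean_still = disp.loc[disp.group == "still", "length"].mean()
        # alignment (centroid/rotation/scale) absorbs part of the planted
        # drift, but the moved region must still stand out clearly
        assert mean_moved > 1.5 * mean_still

    def test_mismatched_ids_rejected(self):
        a = zr.Ordination(ids=[1, 2, 3], coords=np.zeros((3, 2)), stress=0.0)
        b = zr.Ordination(ids=[1, 2, 4], coords=np.zeros((3, 2)), stress=0.0)
        with pytest.raises(ValueError):
            zr.procrustes_trajectory({0.0: a, 5.0: b})


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(14)
        D = random_dissimilarity(rng, 8)
        res = zr.mantel(D, D, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert 0 < res.p_value <= 1

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(15)
        D1 = random_dissimilarity(rng, 8)
        D2 = random_dissimilarity(rng, 8)
        D2 = zr.DissimilarityMatrix(D2.values, D1.ids)
        assert zr.mantel(D1, D2, n_perm=9, seed=0).r == pytest.approx(
            zr.mantel(D2, D1, n_perm=9, seed=0).r
        )

    def test_exhaustive_mode_matches_enumeration(self):
        rng = np.random.default_rng(16)
        for _ in range(5):
            A = random_dissimilarity(rng, 4).values
            B = random_dissimilarity(rng, 4).values
            res = zr.mantel(A, B, n_perm="all")
            r_exp, p_exp = oracle_mantel_exact(A, B)
            assert res.n_perm == 23
            assert res.r == pytest.approx(r_exp, abs=1e-12)
            assert res.p_value == pytest.approx(p_exp, abs=1e-12)

    def test_p_never_zero(self):
        rng = np.random.default_rng(18)
        D = random_dissimilarity(rng, 6)
        res = zr.mantel(D, D, n_perm=99, seed=3)
        assert res.p_value >= 1 / 100

    def test_constant_matrix_rejected(self):
        vals = np.full((4, 4), 0.5)
        np.fill_diagonal(vals, 0.0)
        with pytest.raises(ValueError, match="constant"):
            zr.mantel(vals, vals)

    def test_agrees_with_independent_implementation(self):
        """Cross-check r against scikit-bio's Mantel on the same input."""
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel
        rng = np.random.default_rng(19)
        A = random_dissimilarity(rng, 10)
        B = random_dissimilarity(rng, 10)
        B = zr.DissimilarityMatrix(B.values, A.ids)
        ours = zr.mantel(A, B, n_perm=99, seed=0)
        theirs_r, _, _ = skbio_mantel(
            SkbioDM(A.values), SkbioDM(B.values), permutations=0, alternative="greater"
        )
        assert ours.r == pytest.approx(float(theirs_r), abs=1e-12)
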