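"""Mean curvature, landmark pairs, geodesic ratios, area/volume and the
feature-matrix assembly/standardization."""

import numpy as np
import pytest
import trimesh

from morphomcia.shape_features import (
    FeatureMatrix,
    area_volume_ratio,
    build_feature_matrix,
    euclid_geodesic_ratios,
    geodesic_distance,
    mean_curvature,
    sample_landmark_pairs,
    standardize,
)


class TestMeanCurvature:
    def test_unit_sphere(self, sphere_1000):
        H = mean_curvature(sphere_1000)
        assert abs(H.mean() - 1.0) < 0.05  # analytic H = 1/r

    def test_radius_two_sphere(self):
        mesh = trimesh.creation.icosphere(subdivisions=3, radius=2.0)
        assert abs(mean_curvature(mesh).mean() - 0.5) < 0.025

    def test_flat_patch_zero(self):
        box = trimesh.creation.box(extents=(10, 10, 1))
        for _ in range(3):
            box = box.subdivide()
        H = mean_curvature(box)
        v = box.vertices
        interior = (
            (np.abs(v[:, 2] - 0.5) < 1e-9)
            & (np.abs(v[:, 0]) < 3)
            & (np.abs(v[:, 1]) < 3)
        )
        assert interior.sum() > 0
        assert np.abs(H[interior]).max() < 1e-6

    def test_translation_invariant(self, icosphere_642):
        shifted = icosphere_642.copy()
        shifted.vertices += np.array([10.0, -4.0, 2.0])
        assert np.allclose(
            mean_curvature(icosphere_642), mean_curvature(shifted), atol=1e-9
        )


class TestLandmarkPairs:
    def test_deterministic(self):
        a = sample_landmark_pairs(1000, 500, seed=42)
        b = sample_landmark_pairs(1000, 500, seed=42)
        assert np.array_equal(a.pairs, b.pairs)

    def test_distinct_and_valid(self):
        lp = sample_landmark_pairs(1000, 500, seed=0)
        assert lp.pairs.shape == (500, 2)
        assert np.all(lp.pairs[:, 0] != lp.pairs[:, 1])
        keys = lp.pairs[:, 0] * 1000 + lp.pairs[:, 1]
        assert len(np.unique(keys)) == 500
        assert lp.pairs.max() < 1000

    def test_too_many_pairs_errors(self):
        with pytest.raises(ValueError, match="only 3 pairs exist"):
            sample_landmark_pairs(3, 4, seed=0)


class TestGeodesics:
    def test_adjacent_is_edge_length(self, icosphere_642):
        i, j = icosphere_642.edges_unique[0]
        expected = float(
            np.linalg.norm(
                icosphere_642.vertices[i] - icosphere_642.vertices[j]
            )
        )
        assert geodesic_distance(icosphere_642, int(i), int(j)) == pytest.approx(expected)

    def test_same_vertex_zero(self, icosphere_642):
        assert geodesic_distance(icosphere_642, 5, 5) == 0.0

    def test_antipodal_near_pi(self, icosphere_2562):
        v = icosphere_2562.vertices
        j = int(np.argmin(((v + v[0]) ** 2).sum(axis=1)))
        g = geodesic_distance(icosphere_2562, 0, j)
        assert abs(g - np.pi) / np.pi < 0.06  # graph metric overestimates

    def test_ratios_in_unit_interval(self, sphere_1000):
        pairs = sample_landmark_pairs(1000, 200, seed=1)
        r = euclid_geodesic_ratios(sphere_1000, pairs)
        assert np.all(r > 0) and np.all(r <= 1 + 1e-12)

    def test_antipodal_ratio_two_over_pi(self, icosphere_2562):
        from morphomcia.shape_features import LandmarkPairs

        v = icosphere_2562.vertices
        j = int(np.argmin(((v + v[0]) ** 2).sum(axis=1)))
        lp = LandmarkPairs(pairs=np.array([[0, j]]), seed=0, n_pairs=1)
        r = euclid_geodesic_ratios(icosphere_2562, lp)[0]
        assert abs(r - 2 / np.pi) < 0.05


class TestAreaVolume:
    def test_sphere_near_three(self, sphere_1000):
        assert abs(area_volume_ratio(sphere_1000) - 3.0) < 0.06  # 3/r, r=1

    def test_cube_exact(self):
        cube = trimesh.creation.box(extents=(2, 2, 2))
        assert area_volume_ratio(cube) == pytest.approx(3.0)

    def test_scaling_halves_ratio(self, icosphere_642):
        big = icosphere_642.copy()
        big.vertices *= 2
        assert area_volume_ratio(big) == pytest.approx(
            area_volume_ratio(icosphere_642) / 2
        )

    def test_open_mesh_errors(self, icosphere_642):
        open_mesh = trimesh.Trimesh(
            vertices=icosphere_642.vertices,
            faces=icosphere_642.faces[:-5],
            process=False,
        )
        with pytest.raises(ValueError, match="watertight"):
            area_volume_ratio(open_mesh)


class TestFeatureMatrix:
    def test_row_count_identity(self, small_cohort):
        _, meshes, _ = small_cohort
        pairs = sample_landmark_pairs(300, 20, seed=0)
        fm = build_feature_matrix(meshes["liverish"], pairs, organ="liverish")
        assert fm.X.shape == (300 + 20 + 1, 10)
        assert fm.feature_names[0] == "curv_0"
        assert fm.feature_names[-1] == "area_vol"

    def test_identical_individuals_identical_columns(self, sphere_1000):
        pairs = sample_landmark_pairs(1000, 30, seed=0)
        fm = build_feature_matrix([sphere_1000, sphere_1000.copy()], pairs)
        assert np.allclose(fm.X[:, 0], fm.X[:, 1])

    def test_mixed_vertex_counts_error(self, sphere_1000, icosphere_642):
        pairs = sample_landmark_pairs(642, 10, seed=0)
        with pytest.raises(ValueError, match="correspondence"):
            build_feature_matrix([sphere_1000, icosphere_642], pairs)

    def test_translation_invariant_features(self, small_cohort):
        _, meshes, _ = small_cohort
        ms = meshes["spleenish"][:3]
        shifted = []
        for m in ms:
            c = m.copy()
            c.vertices += np.array([3.0, -7.0, 1.0])
            shifted.append(c)
        pairs = sample_landmark_pairs(300, 25, seed=3)
        a = build_feature_matrix(ms, pairs)
        b = build_feature_matrix(shifted, pairs)
        assert np.allclose(a.X, b.X, atol=1e-8)


class TestStandardize:
    rng = np.random.default_rng(5)

    def _fm(self, X):
        return FeatureMatrix(
            X=X, feature_names=[f"f{i}" for i in range(X.shape[0])]
        )

    def test_rows_zero_mean_unit_variance(self):
        z = standardize(self._fm(self.rng.normal(size=(20, 8)) * 5 + 3))
        assert np.abs(z.X.mean(axis=1)).max() < 1e-10
        assert np.abs(z.X.std(axis=1, ddof=0) - 1).max() < 1e-10
        assert z.standardized

    def test_constant_row_dropped(self):
        X = self.rng.normal(size=(5, 6))
        X[2] = 4.2
        with pytest.warns(UserWarning, match="zero-variance"):
            z = standardize(self._fm(X))
        assert z.d == 4
        assert "f2" not in z.feature_names

    def test_idempotent(self):
        z = standardize(self._fm(self.rng.normal(size=(10, 7))))
        zz = standardize(z)
        assert np.allclose(z.X, zz.X, atol=1e-12)

    def test_single_individual_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            standardize(self._fm(self.rng.normal(size=(4, 1))))
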