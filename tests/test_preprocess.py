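"""Noise removal, ground classification, normalization and CHM tests."""

import numpy as np
import pytest

import crownlidar as cl
from crownlidar.preprocess import remove_noise, classify_ground, \
    normalize_heights, rasterize_chm


def make_cloud(xyz):
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    return cl.PointCloud(xyz[:, 0], xyz[:, 1], xyz[:, 2])


class TestRemoveNoise:
    def test_empty_cloud_passes_through(self):
        out = remove_noise(make_cloud(np.empty((0, 3))), radius=5, min_neighbors=1)
        assert len(out) == 0

    def test_isolated_point_removed_cluster_kept(self, rng):
        cluster = rng.uniform(-0.5, 0.5, size=(100, 3))
        outlier = np.array([[10.0, 10.0, 10.0]])
        cloud = make_cloud(np.vstack([cluster, outlier]))
        out = remove_noise(cloud, radius=5.0, min_neighbors=1)
        assert len(out) == 100
        assert np.hypot(out.x, out.y).max() < 1.0

    def test_pair_just_inside_radius_retained(self):
        cloud = make_cloud([[0, 0, 0], [4.9, 0, 0]])
        out = remove_noise(cloud, radius=5.0, min_neighbors=1)
        assert len(out) == 2

    @pytest.mark.parametrize("radius,min_neighbors", [(1.0, 2), (2.5, 4)])
    def test_matches_brute_force_neighbor_counts(self, rng, radius, min_neighbors):
        xyz = rng.uniform(0, 8, size=(200, 3))
        cloud = make_cloud(xyz)
        d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
        counts = (d <= radius).sum(axis=1) - 1  # exclude self
        expected = counts >= min_neighbors
        out = remove_noise(cloud, radius, min_neighbors)
        assert len(out) == expected.sum()
        np.testing.assert_array_equal(out.x, cloud.x[expected])

    def test_idempotent_on_own_output(self, rng):
        # clustered returns (LiDAR-like density) plus scattered strays
        clusters = np.concatenate([
            rng.normal(center, 0.4, size=(120, 3))
            for center in ([2, 2, 5], [7, 6, 8], [4, 8, 3])
        ])
        strays = rng.uniform(0, 10, size=(15, 3)) + np.array([20.0, 0, 0])
        cloud = make_cloud(np.vstack([clusters, strays]))
        once = remove_noise(cloud, radius=1.5, min_neighbors=3)
        twice = remove_noise(once, radius=1.5, min_neighbors=3)
        np.testing.assert_array_equal(once.xyz, twice.xyz)

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            make_cloud([[0, 0, np.nan]])


class TestClassifyGround:
    def test_flat_plane_separates_from_canopy(self, rng):
        gx = rng.uniform(0, 20, size=(400, 2))
        ground = np.column_stack([gx, np.full(400, 100.0)])
        cx = rng.uniform(0, 20, size=(300, 2))
        canopy = np.column_stack([cx, np.full(300, 110.0)])
        cloud = make_cloud(np.vstack([ground, canopy]))
        out = classify_ground(cloud, cell_size=2.0)
        labels = out.classification
        assert np.all(labels[:400] == cl.CLASS_GROUND)
        assert np.all(labels[400:] == cl.CLASS_VEGETATION)

    def test_tilted_terrain_recovers_true_ground(self):
        # air/low blunders are removed upstream of ground classification
        config = cl.StandConfig(seed=5, terrain_slope_deg=10.0,
                                extent=(12.0, 12.0), n_air_points=0,
                                n_low_points=0)
        cloud, truth = cl.generate_stand(config)
        out = classify_ground(cloud, cell_size=2.0)
        true_ground = truth.point_class == cl.CLASS_GROUND
        recovered = out.classification[true_ground] == cl.CLASS_GROUND
        assert recovered.mean() >= 0.95

    def test_two_points_insufficient_support(self):
        with pytest.raises(ValueError, match="insufficient ground support"):
            classify_ground(make_cloud([[0, 0, 0], [1, 1, 0]]))


class TestNormalizeHeights:
    def test_constant_ground_offset(self, rng):
        gx = rng.uniform(0, 10, size=(100, 2))
        ground = make_cloud(np.column_stack([gx, np.full(100, 50.0)]))
        pt = make_cloud([[5.0, 5.0, 60.0]])
        out = normalize_heights(pt, ground)
        assert out.z[0] == pytest.approx(10.0)

    def test_ground_against_itself_is_zero(self, rng):
        gx = rng.uniform(0, 10, size=(150, 2))
        z = 100 + 0.3 * gx[:, 0] - 0.1 * gx[:, 1]
        ground = make_cloud(np.column_stack([gx, z]))
        out = normalize_heights(ground, ground)
        np.testing.assert_allclose(out.z, 0.0, atol=1e-9)

    def test_tilted_plane_interpolation_error_bounded(self, rng):
        # seeds on a 2 m grid, query points at known analytic offsets
        gx, gy = np.meshgrid(np.arange(0, 21, 2.0), np.arange(0, 21, 2.0))
        slope = np.tan(np.radians(10.0))
        gz = 100 + slope * gx
        ground = make_cloud(np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]))
        qx = rng.uniform(1, 19, size=(200, 2))
        offsets = rng.uniform(1, 5, size=200)
        pts = make_cloud(np.column_stack(
            [qx, 100 + slope * qx[:, 0] + offsets]))
        out = normalize_heights(pts, ground)
        # planar terrain is reproduced exactly by a TIN through grid seeds
        assert np.abs(out.z - offsets).max() < 2 * 0.3


class TestRasterizeCHM:
    def test_single_point_single_cell(self):
        chm = rasterize_chm(make_cloud([[0.1, 0.1, 10.0]]), resolution=1.0)
        assert chm.shape == (1, 1)
        assert chm.values[0, 0] == pytest.approx(10.0)

    def test_cell_maxima_match_exhaustive_scan(self, rng):
        xyz = rng.uniform(0, 10, size=(500, 3))
        cloud = make_cloud(xyz)
        res = 0.5
        chm = rasterize_chm(cloud, resolution=res)
        row, col = chm.cell_of(cloud.x, cloud.y)
        for r in range(chm.shape[0]):
            for c in range(chm.shape[1]):
                here = (row == r) & (col == c)
                if here.any():
                    assert chm.values[r, c] == pytest.approx(cloud.z[here].max())

    def test_interior_hole_filled_with_neighbor_median(self, rng):
        pts = []
        for i in range(3):
            for j in range(3):
                if (i, j) == (1, 1):
                    continue
                pts.append([j + 0.5, i + 0.5, 7.0])
        chm = rasterize_chm(make_cloud(pts), resolution=1.0)
        assert chm.values[1, 1] == pytest.approx(7.0)

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rasterize_chm(make_cloud(np.empty((0, 3))), resolution=1.0)
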