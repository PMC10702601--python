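import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import canospec as cs
from canospec.errors import DegenerateInputError, ProjectionError
from canospec.fusion import image_plane_to_pixel
from canospec.types import CameraModel


class TestRotationMatrix:
    def test_zero_angles_is_identity(self):
        np.testing.assert_allclose(cs.rotation_matrix(0, 0, 0), np.eye(3), atol=1e-15)

    @given(st.integers(0, 2 ** 32 - 1))
    def test_orthonormal_for_random_angles(self, seed):
        r = np.random.default_rng(seed)
        for _ in range(5):
            m = cs.rotation_matrix(*r.uniform(-np.pi, np.pi, 3))
            np.testing.assert_allclose(m.T @ m, np.eye(3), atol=1e-12)

    def test_kappa_quarter_turn_permutes_axes(self):
        m = cs.rotation_matrix(0, 0, np.pi / 2)
        expected = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        np.testing.assert_allclose(m, expected, atol=1e-12)

    def test_composition_of_elementary_rotations(self):
        om, ph, ka = 0.3, -0.2, 1.1
        rx = cs.rotation_matrix(om, 0, 0)
        ry = cs.rotation_matrix(0, ph, 0)
        rz = cs.rotation_matrix(0, 0, ka)
        np.testing.assert_allclose(cs.rotation_matrix(om, ph, ka), rz @ ry @ rx,
                                   atol=1e-12)


class TestCollinearity:
    def _nadir(self):
        return CameraModel(f=0.01, xs=0, ys=0, zs=80)

    def test_on_axis_point_projects_to_origin(self):
        x, y = cs.collinearity_project(self._nadir(), 0.0, 0.0, 0.0)
        assert x == 0.0 and y == 0.0

    def test_hand_evaluated_offset_point(self):
        # x = -f * 8 / (0 - 80) = 0.1 f
        x, y = cs.collinearity_project(self._nadir(), 8.0, 0.0, 0.0)
        np.testing.assert_allclose(x, 0.1 * 0.01, atol=1e-15)
        assert y == 0.0

    @given(st.integers(0, 2 ** 32 - 1))
    def test_ray_invariance(self, seed):
        r = np.random.default_rng(seed)
        cam = CameraModel(f=0.02, xs=r.uniform(-5, 5), ys=r.uniform(-5, 5),
                          zs=80.0, omega=r.uniform(-0.2, 0.2),
                          phi=r.uniform(-0.2, 0.2), kappa=r.uniform(-np.pi, np.pi))
        target = np.array([r.uniform(-10, 10), r.uniform(-10, 10), 0.0])
        direction = target - cam.position
        ts = np.linspace(0.3, 1.5, 7)
        pts = cam.position + ts[:, None] * direction
        xs, ys = cs.collinearity_project(cam, pts[:, 0], pts[:, 1], pts[:, 2])
        assert np.ptp(xs) <= 1e-9 and np.ptp(ys) <= 1e-9

    def test_point_behind_camera_raises(self):
        with pytest.raises(ProjectionError):
            cs.collinearity_project(self._nadir(), 0.0, 0.0, 200.0)

    def test_camera_rotation_property_is_orthonormal(self):
        cam = CameraModel(f=0.01, xs=0, ys=0, zs=80, omega=0.1, phi=0.2, kappa=0.3)
        np.testing.assert_allclose(cam.rotation.T @ cam.rotation, np.eye(3),
                                   atol=1e-10)


class TestSampleBand:
    def _raster(self, grid):
        return cs.SpectralRaster({"NIR": np.asarray(grid, dtype=float)},
                                 origin=(0.0, 2.0), pixel_size=1.0, nodata=-9999.0)

    def test_constant_raster_both_methods(self):
        ras = self._raster(np.full((4, 4), 7.5))
        assert cs.sample_band(ras, "NIR", 1.3, 2.7, "nearest") == 7.5
        assert cs.sample_band(ras, "NIR", 1.3, 2.7, "bilinear") == pytest.approx(7.5)

    def test_nearest_at_cell_center_returns_stored_value(self):
        ras = self._raster([[1.0, 2.0], [3.0, 4.0]])
        assert cs.sample_band(ras, "NIR", 1, 0, "nearest") == 3.0

    def test_bilinear_midpoint_closed_form(self):
        ras = self._raster([[0.0, 10.0], [0.0, 10.0]])
        assert cs.sample_band(ras, "NIR", 0.5, 0.5, "bilinear") == pytest.approx(5.0)

    def test_nodata_neighbor_propagates(self):
        ras = self._raster([[0.0, -9999.0], [0.0, 10.0]])
        assert cs.sample_band(ras, "NIR", 0.5, 0.5, "bilinear") == -9999.0


class TestFuse:
    def test_outside_point_dropped_and_counted(self):
        ras = cs.SpectralRaster({"NIR": np.full((4, 4), 9.0)}, origin=(0.0, 4.0),
                                pixel_size=1.0)
        cloud = cs.PointCloud(x=[1.0, 100.0], y=[1.0, 1.0], z=[0.0, 0.0])
        fused, stats = cs.fuse(cloud, ras)
        assert stats.n_outside == 1 and stats.n_fused == 1
        assert fused.nir.tolist() == [9.0]

    def test_zero_retained_points_is_an_error(self):
        ras = cs.SpectralRaster({"NIR": np.full((2, 2), 1.0)}, origin=(0.0, 2.0),
                                pixel_size=1.0)
        cloud = cs.PointCloud(x=[50.0], y=[50.0], z=[0.0])
        with pytest.raises(DegenerateInputError):
            cs.fuse(cloud, ras)

    def test_every_fused_nir_is_a_raster_sample(self, small_scene):
        c = small_scene.cloud
        ras = cs.render_orthoimage(c, gsd=0.25)
        fused, _ = cs.fuse(c, ras, resample="nearest")
        stored = ras.band("NIR")[ras.band("NIR") != ras.nodata]
        assert np.isin(fused.nir, stored).all()

    def test_closed_loop_winners_recover_true_nir(self, small_scene):
        base = small_scene.cloud
        c = base.with_(nir_true=base.nir.copy(), tree_id=np.arange(len(base)))
        ras = cs.render_orthoimage(c, gsd=0.25)
        px = ras.pixel_size
        col = np.clip(np.floor((c.x - ras.origin[0]) / px).astype(int),
                      0, ras.width - 1)
        row = np.clip(np.floor((ras.origin[1] - c.y) / px).astype(int),
                      0, ras.height - 1)
        cell = row * ras.width + col
        order = np.lexsort((c.z, cell))
        last = np.ones(len(order), bool)
        last[:-1] = cell[order][1:] != cell[order][:-1]
        winner_ids = order[last]

        views = cs.flight_grid_viewpoints(small_scene.extent, spacing=10)
        visible = c.subset(cs.multiview_visible(c.xyz, views))
        fused, _ = cs.fuse(visible, ras, resample="nearest")
        is_winner = np.isin(fused.tree_id, winner_ids)
        # surviving per-cell max-Z points receive their own NIR exactly
        assert np.mean(fused.nir[is_winner] == fused.nir_true[is_winner]) == 1.0

    def test_perspective_mode_matches_ortho_on_a_flat_scene(self, rng):
        # flat ground, nadir camera whose pixel pitch reproduces the ortho GSD
        n = 400
        cloud = cs.PointCloud(x=rng.uniform(0.5, 19.5, n), y=rng.uniform(0.5, 19.5, n),
                              z=np.zeros(n), nir=rng.uniform(7, 14, n))
        ras = cs.render_orthoimage(cloud, gsd=0.1, extent=(0, 0, 20, 20))
        fused_o, _ = cs.fuse(cloud, ras, mode="ortho", resample="nearest")
        h = 80.0
        f = 0.02
        pitch = 0.1 * f / h
        cam = CameraModel(f=f, xs=10.0, ys=10.0, zs=h, pixel_pitch=pitch,
                          width=ras.width, height=ras.height)
        # build the camera image by resampling the ortho onto the pixel grid
        xi, yi = cs.collinearity_project(cam, cloud.x, cloud.y, cloud.z)
        rowp, colp = image_plane_to_pixel(cam, xi, yi)
        rowo, colo = cs.map_to_pixel(ras, cloud.x, cloud.y)
        assert np.abs(np.rint(rowp) - rowo).max() <= 1
        assert np.abs(np.rint(colp) - colo).max() <= 1
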