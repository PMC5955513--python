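"""Space-time kernel density: kernels, voxel evaluation, classification,
and voxel export round-trips."""

import numpy as np
import pytest

from hotcube.stkde import (StkdeParams, StkdeVolume, classify_equal_interval,
                           export_voxels, read_xyzv_csv, spatial_kernel,
                           stkde_density, temporal_kernel)

from conftest import naive_stkde


class TestKernels:
    def test_temporal_kernel_peak_is_three_quarters(self):
        assert temporal_kernel(0.0) == 0.75

    def test_spatial_kernel_peak_is_two_over_pi(self):
        assert spatial_kernel(0.0, 0.0) == pytest.approx(2 / np.pi)

    def test_compact_support_boundaries(self):
        assert temporal_kernel(1.0) == 0.0
        assert spatial_kernel(0.8, 0.6) == 0.0  # u^2+v^2 = 1
        assert spatial_kernel(1.5, 0.0) == 0.0


class TestStkdeDensity:
    def test_single_event_peak_under_unit_bandwidths(self):
        params = StkdeParams(h_s=1.0, h_t=1.0, scale_factor=1e10,
                             dx=0.5, dy=0.5, dt=0.5)
        vol = stkde_density([0.0], [0.0], [0.0], params,
                            x_coords=[0.0], y_coords=[0.0], t_coords=[0.0])
        assert vol.intensity[0, 0, 0] == pytest.approx(1e10 * (2 / np.pi) * 0.75,
                                                       rel=1e-12)

    def test_zero_outside_spatial_support(self):
        params = StkdeParams(h_s=1.0, h_t=1.0)
        vol = stkde_density([0.0], [0.0], [0.0], params,
                            x_coords=[1.0], y_coords=[0.2], t_coords=[0.0])
        assert vol.intensity[0, 0, 0] == 0.0

    def test_three_events_match_naive_triple_loop(self, rng):
        ev_x = rng.uniform(0, 10, 3)
        ev_y = rng.uniform(0, 10, 3)
        ev_t = rng.uniform(0, 10, 3)
        xs = np.linspace(0, 10, 5)
        params = StkdeParams(h_s=4.0, h_t=4.0, scale_factor=1e10)
        vol = stkde_density(ev_x, ev_y, ev_t, params,
                            x_coords=xs, y_coords=xs, t_coords=xs)
        oracle = naive_stkde(xs, xs, xs, ev_x, ev_y, ev_t, 4.0, 4.0, 1e10)
        np.testing.assert_allclose(vol.intensity, oracle, rtol=1e-12,
                                   atol=1e-2)

    def test_riemann_sum_converges_to_one_with_unit_scale(self, rng):
        ev_x = rng.uniform(40, 60, 10)
        ev_y = rng.uniform(40, 60, 10)
        ev_t = rng.uniform(40, 60, 10)
        params = StkdeParams(h_s=10.0, h_t=10.0, scale_factor=1.0,
                             dx=1.0, dy=1.0, dt=1.0)
        vol = stkde_density(ev_x, ev_y, ev_t, params)
        mass = vol.intensity.sum() * 1.0
        assert mass == pytest.approx(1.0, rel=0.02)

    def test_linearity_in_scale_factor(self, rng):
        ev = rng.uniform(0, 5, (3, 4))
        xs = np.linspace(0, 5, 4)
        p1 = StkdeParams(h_s=3.0, h_t=3.0, scale_factor=1.0)
        p2 = StkdeParams(h_s=3.0, h_t=3.0, scale_factor=2.0)
        v1 = stkde_density(ev[0], ev[1], ev[2], p1,
                           x_coords=xs, y_coords=xs, t_coords=xs)
        v2 = stkde_density(ev[0], ev[1], ev[2], p2,
                           x_coords=xs, y_coords=xs, t_coords=xs)
        np.testing.assert_allclose(v2.intensity, 2 * v1.intensity, rtol=1e-12)

    def test_compact_support_on_full_volume(self, rng):
        ev_x, ev_y, ev_t = [5.0], [5.0], [5.0]
        params = StkdeParams(h_s=2.0, h_t=2.0, dx=0.5, dy=0.5, dt=0.5)
        vol = stkde_density(ev_x, ev_y, ev_t, params)
        X, Y, T = np.meshgrid(vol.x, vol.y, vol.t, indexing="ij")
        outside = ((np.hypot(X - 5, Y - 5) >= 2.0) | (np.abs(T - 5) >= 2.0))
        assert not vol.intensity[outside].any()

    def test_planted_cluster_argmax_near_true_centre(self):
        r = np.random.default_rng(99)
        n = 500
        ev_x = r.normal(0.0, 100.0, n)
        ev_y = r.normal(0.0, 100.0, n)
        ev_t = r.normal(4000.0, 80.0, n)
        params = StkdeParams(h_s=1000.0, h_t=720.0, dx=250, dy=250, dt=180)
        vol = stkde_density(ev_x, ev_y, ev_t, params)
        i, j, k = np.unravel_index(np.argmax(vol.intensity),
                                   vol.intensity.shape)
        assert np.hypot(vol.x[i], vol.y[j]) <= 1000.0
        assert abs(vol.t[k] - 4000.0) <= 720.0

    def test_empty_event_set_raises(self):
        with pytest.raises(ValueError):
            stkde_density([], [], [], StkdeParams())


class TestClassifyEqualInterval:
    def _volume(self, values):
        values = np.asarray(values, float)
        ax = np.arange(values.shape[0], dtype=float)
        return StkdeVolume(x=ax, y=np.arange(values.shape[1], dtype=float),
                           t=np.arange(values.shape[2], dtype=float),
                           intensity=values, params=StkdeParams())

    def test_equal_interval_breaks_on_0_to_100(self):
        vals = np.array([0.0, 10, 25, 45, 65, 85, 100]).reshape(7, 1, 1)
        vol = classify_equal_interval(self._volume(vals))
        # intervals [80,100]->1, [60,80)->2, [40,60)->3, [20,40)->4, [0,20)->5
        assert vol.classes.ravel().tolist() == [5, 5, 4, 3, 2, 1, 1]

    def test_class_2_is_strong_and_class_3_weak(self):
        vals = np.array([0.0, 50, 70, 100]).reshape(4, 1, 1)
        vol = classify_equal_interval(self._volume(vals))
        assert vol.strength.ravel().tolist() == ["none", "weak", "strong",
                                                 "strong"]

    def test_constant_volume_degenerates_with_class_k(self):
        vol = classify_equal_interval(self._volume(np.ones((3, 2, 2))))
        assert (vol.classes == 5).all()
        assert (vol.strength == "none").all()

    def test_fewer_than_2_classes_raises(self):
        with pytest.raises(ValueError):
            classify_equal_interval(self._volume(np.ones((2, 1, 1))), k=1)


class TestExport:
    def _classified_volume(self, rng):
        params = StkdeParams(h_s=3.0, h_t=3.0)
        xs = np.linspace(0, 6, 4)
        vol = stkde_density(rng.uniform(0, 6, 5), rng.uniform(0, 6, 5),
                            rng.uniform(0, 6, 5), params,
                            x_coords=xs, y_coords=xs, t_coords=xs)
        return classify_equal_interval(vol)

    def test_csv_round_trip_is_lossless(self, tmp_path, rng):
        vol = self._classified_volume(rng)
        path = tmp_path / "vox.csv"
        export_voxels(vol, path, format="xyzv_csv")
        back = read_xyzv_csv(path)
        np.testing.assert_allclose(back.intensity, vol.intensity, rtol=1e-12)
        np.testing.assert_array_equal(back.classes, vol.classes)
        np.testing.assert_allclose(back.x, vol.x)

    def test_vtk_header_declares_lattice_dimensions(self, tmp_path, rng):
        vol = self._classified_volume(rng)
        path = tmp_path / "vox.vtk"
        export_voxels(vol, path, format="vtk_structured")
        text = path.read_text().splitlines()
        assert text[3] == "DATASET STRUCTURED_POINTS"
        assert text[4] == "DIMENSIONS 4 4 4"
        assert text[7] == "POINT_DATA 64"

    def test_empty_volume_raises(self):
        vol = StkdeVolume(x=np.array([]), y=np.array([]), t=np.array([]),
                          intensity=np.zeros((0, 0, 0)), params=StkdeParams())
        with pytest.raises(ValueError):
            export_voxels(vol, "nowhere.csv")

    def test_unknown_format_raises(self, tmp_path, rng):
        with pytest.raises(ValueError, match="format"):
            export_voxels(self._classified_volume(rng), tmp_path / "x",
                          format="netcdf")
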