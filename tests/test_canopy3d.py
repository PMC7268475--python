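import numpy as np
import pytest

from uasyield import synthdata
from uasyield.canopy3d import (
    HeightField,
    RigidTransform,
    calibrate_heights,
    filter_outliers,
    height_deviation,
    icp_register,
    increment_field,
    kabsch,
    mesh_volume,
    plot_geometric_features,
    rgb_feature_columns,
)
from uasyield.clouds import PointCloud
from uasyield.errors import (
    CalibrationError,
    DataQualityWarning,
    MeshingError,
    ParameterError,
)
from uasyield.plotgrid import FieldSpec, PlotPolygon, build_plot_polygons


def _grid_cloud(nx=40, ny=40, pitch=0.1, z=0.0):
    xs, ys = np.meshgrid(np.arange(nx) * pitch, np.arange(ny) * pitch)
    pts = np.column_stack([xs.ravel(), ys.ravel(), np.full(nx * ny, float(z))])
    return PointCloud(pts, role="terrain")


class TestOutlierFilter:
    def test_single_isolated_point_removed(self):
        cloud = _grid_cloud()
        spiked = PointCloud(np.vstack([cloud.points, [2.0, 2.0, 5.0]]))
        filtered, keep = filter_outliers(spiked)
        assert not keep[-1]
        assert keep[:-1].all()
        assert len(filtered) == len(spiked) - 1

    def test_clean_cloud_essentially_unchanged(self):
        rng = np.random.default_rng(4)
        cloud = PointCloud(
            np.column_stack([rng.uniform(0, 5, (4000, 2)), rng.normal(0, 0.01, 4000)])
        )
        filtered, keep = filter_outliers(cloud)
        # only the natural tail of the neighbour-distance distribution goes
        assert keep.mean() > 0.95

    def test_small_cloud_rejected(self):
        with pytest.raises(ParameterError):
            filter_outliers(PointCloud(np.zeros((5, 3))), k_neighbors=8)

    def test_excessive_removal_warns(self):
        rng = np.random.default_rng(0)
        base = _grid_cloud(20, 20)
        junk = rng.uniform(5, 10, (60, 3))  # 13% gross outliers
        cloud = PointCloud(np.vstack([base.points, junk]))
        with pytest.warns(DataQualityWarning):
            filter_outliers(cloud, max_fraction=0.05)

    def test_injected_outliers_recovered(self, small_field):
        clouds = small_field.clouds
        date = "DAP61"
        labels = clouds.outlier_labels[date]
        _, keep = filter_outliers(clouds.canopy[date])
        recovered = (~keep & labels).sum() / labels.sum()
        assert recovered >= 0.95


class TestRegistration:
    def test_identity_recovery(self):
        cloud = _grid_cloud()
        t = icp_register(cloud, cloud)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t.translation, 0, atol=1e-9)
        assert t.rms_m < 1e-9

    def test_translation_recovered_exactly_on_copy(self):
        rng = np.random.default_rng(0)
        fixed = PointCloud(
            np.column_stack([rng.uniform(0, 10, (2000, 2)), rng.normal(0, 0.02, 2000)])
        )
        offset = np.array([0.5, 0.3, 0.1])
        moving = PointCloud(fixed.points + offset)
        # start close enough for closest-point matching to lock on
        init = RigidTransform(np.eye(3), -offset + [0.02, -0.015, 0.01])
        t = icp_register(moving, fixed, init=init)
        np.testing.assert_allclose(t.translation, -offset, atol=1e-3)
        assert abs(t.yaw_deg) < 0.1

    def test_yaw_and_translation_on_independent_samples(self, small_field):
        """5-degree-scale yaw + translation between independently sampled
        clouds of the same terrain is recovered to survey accuracy."""
        clouds = small_field.clouds
        spec = small_field.spec
        from uasyield.pipeline import register_canopy

        for date, cloud in clouds.canopy.items():
            filtered, _ = filter_outliers(cloud)
            _, t = register_canopy(
                filtered, clouds.terrain, spec,
                tie_points=clouds.tie_points[date], bars=clouds.bars,
            )
            truth = clouds.perturbations[date].inverse()
            assert abs(t.yaw_deg - truth.yaw_deg) < 0.1
            np.testing.assert_allclose(t.translation, truth.translation, atol=1e-2)

    def test_kabsch_exact(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(100, 3))
        truth = synthdata._yaw_transform(17.0, (0.3, -0.2, 0.9))
        t = kabsch(a, truth.apply(a))
        np.testing.assert_allclose(t.rotation, truth.rotation, atol=1e-12)
        np.testing.assert_allclose(t.translation, truth.translation, atol=1e-12)


class TestHeightDeviation:
    def test_flat_terrain_constant_canopy(self):
        terrain = _grid_cloud(z=0.0)
        canopy = PointCloud(terrain.points + [0.0, 0.0, 0.8])
        hf = height_deviation(canopy, terrain)
        np.testing.assert_allclose(hf.heights, 0.8, atol=1e-9)

    def test_quadric_terrain_height_recovery(self):
        rng = np.random.default_rng(0)
        coeffs = synthdata.DEFAULT_QUADRIC
        noise = 0.01
        xy = rng.uniform(0, 10, (20000, 2))
        z = synthdata._quadric_z(coeffs, xy[:, 0], xy[:, 1])
        terrain = PointCloud(np.column_stack([xy, z + rng.normal(0, noise, len(xy))]))
        xy2 = rng.uniform(1, 9, (2000, 2))
        z2 = synthdata._quadric_z(coeffs, xy2[:, 0], xy2[:, 1]) + 0.5
        canopy = PointCloud(np.column_stack([xy2, z2 + rng.normal(0, noise, len(xy2))]))
        hf = height_deviation(canopy, terrain)
        assert np.abs(hf.heights - 0.5).max() < 3 * noise * 3  # 3 sigma incl. fit error
        assert np.abs(hf.heights.mean() - 0.5) < 0.005

    def test_below_terrain_clamped_to_zero(self):
        terrain = _grid_cloud(z=1.0)
        canopy = PointCloud(terrain.points[:100] - [0, 0, 0.5])
        hf = height_deviation(canopy, terrain)
        assert (hf.heights == 0).all()


class TestBarCalibration:
    def _field(self, bias=0.0):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(0, 10, (5000, 2)), np.zeros(5000)])
        heights = np.full(5000, 0.0)
        bars = []
        for i, (bx, by, bh) in enumerate(
            [(1, 1, 1.2), (9, 1, 1.4), (5, 5, 1.5), (1, 9, 1.6), (9, 9, 1.8)]
        ):
            ang = rng.uniform(0, 2 * np.pi, 100)
            rad = 0.08 * np.sqrt(rng.uniform(0, 1, 100))
            bxy = np.column_stack([bx + rad * np.cos(ang), by + rad * np.sin(ang)])
            pts = np.vstack([pts, np.column_stack([bxy, np.full(100, bh + bias)])])
            heights = np.concatenate([heights, np.full(100, bh + bias)])
            bars.append((bx, by, bh))
        return HeightField(pts, heights), bars

    def test_zero_offset(self):
        hf, bars = self._field()
        out = calibrate_heights(hf, bars)
        assert out.calibration_offset_m == pytest.approx(0.0, abs=1e-6)

    def test_bias_recovered(self):
        hf, bars = self._field(bias=0.05)
        out = calibrate_heights(hf, bars)
        assert out.calibration_offset_m == pytest.approx(-0.05, abs=1e-3)

    def test_inconsistent_bars_fail(self):
        hf, bars = self._field()
        bars[0] = (bars[0][0], bars[0][1], bars[0][2] + 0.3)  # one bad survey
        with pytest.raises(CalibrationError):
            calibrate_heights(hf, bars)

    def test_needs_a_bar(self):
        hf, _ = self._field()
        with pytest.raises(ParameterError):
            calibrate_heights(hf, [])


class TestMeshVolume:
    poly = PlotPolygon("p", "f", 0.0, 0.0, 2.0, 2.0)

    def _uniform_field(self, h=1.0, n=500, seed=0):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 2, (n, 2))
        pts = np.column_stack([xy, np.full(n, h)])
        return HeightField(pts, np.full(n, float(h)))

    def test_uniform_height_prism(self):
        vol = mesh_volume(self._uniform_field(1.0), self.poly)
        assert vol == pytest.approx(4000.0, rel=0.02)

    def test_zero_heights_zero_volume(self):
        assert mesh_volume(self._uniform_field(0.0), self.poly) == 0.0

    def test_hemisphere_against_riemann_oracle(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 2, (4000, 2))
        r2 = (xy[:, 0] - 1) ** 2 + (xy[:, 1] - 1) ** 2
        h = np.sqrt(np.maximum(0.81 - r2, 0.0))  # hemisphere r = 0.9
        hf = HeightField(np.column_stack([xy, h]), h)
        # fine-grid Riemann oracle of the same surface
        g = np.linspace(0, 2, 400)
        gx, gy = np.meshgrid(g, g)
        hh = np.sqrt(np.maximum(0.81 - (gx - 1) ** 2 - (gy - 1) ** 2, 0.0))
        oracle = hh.sum() * (2 / 400) ** 2 * 1000
        assert mesh_volume(hf, self.poly) == pytest.approx(oracle, rel=0.05)

    def test_collinear_points_fail(self):
        pts = np.column_stack([np.linspace(0, 1, 10), np.zeros(10), np.ones(10)])
        with pytest.raises(MeshingError):
            mesh_volume(HeightField(pts, np.ones(10)), self.poly)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(2)
        xy = rng.uniform(0.2, 1.8, (2000, 2))
        r2 = (xy[:, 0] - 1) ** 2 + (xy[:, 1] - 1) ** 2
        h = np.exp(-r2 / 0.18)  # radially symmetric mound, fully inside
        hf = HeightField(np.column_stack([xy, h]), h)
        th = np.radians(30)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        xy_r = (xy - 1) @ rot.T + 1
        hf_r = HeightField(np.column_stack([xy_r, h]), h)
        v0, v1 = mesh_volume(hf, self.poly), mesh_volume(hf_r, self.poly)
        assert v1 == pytest.approx(v0, rel=0.02)


class TestGeometricFeatures:
    def _height_fields(self, step=0.0, seed=0):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 5, (4000, 2))
        h1 = 0.5 + 0.05 * rng.standard_normal(4000)
        pts1 = np.column_stack([xy, h1])
        hf1 = HeightField(pts1, h1)
        xy2 = xy + rng.normal(0, 0.01, xy.shape)
        h2 = h1 + step
        hf2 = HeightField(np.column_stack([xy2, h2]), h2)
        return hf1, hf2

    poly = [PlotPolygon("P01", "F", 0.5, 0.5, 4.5, 4.5)]

    def test_identical_dates_zero_increment(self):
        hf1, _ = self._height_fields()
        recs, dropped = plot_geometric_features({"D1": hf1, "D2": hf1}, self.poly)
        inc = next(r for r in recs if r.source == "INC")
        assert inc.hmean_cm == 0.0 and inc.cv_dm3 == 0.0
        assert not dropped

    def test_height_step_in_increment(self):
        hf1, hf2 = self._height_fields(step=0.2)
        recs, _ = plot_geometric_features({"D1": hf1, "D2": hf2}, self.poly)
        inc = next(r for r in recs if r.source == "INC")
        assert inc.hmean_cm == pytest.approx(20.0, abs=1.0)

    def test_twelve_model_features(self):
        cols = rgb_feature_columns(("DAP61", "DAP70", "INC"))
        assert len(cols) == 12

    def test_empty_plot_dropped(self):
        hf1, hf2 = self._height_fields()
        polys = self.poly + [PlotPolygon("P99", "F", 100.0, 100.0, 101.0, 101.0)]
        recs, dropped = plot_geometric_features({"D1": hf1, "D2": hf2}, polys)
        assert dropped == ["P99"]
        assert {r.plot_id for r in recs} == {"P01"}
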