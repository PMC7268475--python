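import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uasyield.errors import (
    DegenerateClusteringError,
    NumericDomainError,
    SampleSizeError,
)
from uasyield.triples import (
    VIParams,
    VI_NAMES,
    biweight_midvariance,
    canopy_cover,
    compute_vis,
    count_rows,
    gaussian_stats,
    msi_feature_columns,
    plot_radiometric_features,
    robust_stats,
    row_length,
    segment_vegetation,
)


def bwmv_oracle(x):
    """Literal term-by-term evaluation of the biweight midvariance."""
    x = np.asarray(x, dtype=float)
    m = np.median(x)
    mad = np.median(np.abs(x - m))
    num = den = 0.0
    for xi in x:
        u = (xi - m) / (9 * mad)
        a = 1.0 if abs(u) < 1 else 0.0
        num += a * (xi - m) ** 2 * (1 - u**2) ** 4
        den += a * (1 - u**2) * (1 - 5 * u**2)
    return len(x) * num / den**2


class TestRobustStats:
    def test_constant_sample_has_zero_dispersion(self):
        rs = robust_stats([5, 5, 5, 5])
        assert rs.mad == rs.nmad == rs.bwmv_sqrt == 0
        assert rs.std == rs.iqr == rs.ipr90 == rs.ipr99 == 0

    def test_unit_mad_sample(self):
        rs = robust_stats([1, 2, 3])
        assert rs.mad == 1.0
        assert rs.nmad == pytest.approx(1.4826, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_bwmv_matches_direct_summation(self, seed):
        x = np.random.default_rng(seed).normal(3, 2, 50)
        assert biweight_midvariance(x) == pytest.approx(bwmv_oracle(x), abs=1e-12)

    def test_nmad_gaussian_consistency(self):
        x = np.random.default_rng(42).standard_normal(100_000)
        assert robust_stats(x).nmad == pytest.approx(1.0, rel=0.02)

    def test_gaussian_stats(self):
        assert gaussian_stats([1, 2, 3]) == (2.0, 1.0)
        assert gaussian_stats([4.0, 4.0, 4.0])[1] == 0.0
        x = np.random.default_rng(0).normal(size=100)
        mean, std = gaussian_stats(x)
        assert mean == pytest.approx(x.mean()) and std == pytest.approx(x.std(ddof=1))

    def test_too_short_sample_rejected(self):
        with pytest.raises(SampleSizeError):
            robust_stats([1.0])
        with pytest.raises(SampleSizeError):
            gaussian_stats([1.0])

    def test_single_outlier_breaks_std_not_nmad(self):
        """A gross outlier moves the SD > 20% but the NMAD < 5% — the
        reason robust estimators are reported alongside Gaussian ones."""
        x = np.random.default_rng(3).standard_normal(100)
        clean = robust_stats(x)
        dirty = robust_stats(np.append(x, 50.0))
        assert abs(dirty.nmad - clean.nmad) / clean.nmad < 0.05
        assert abs(dirty.std - clean.std) / clean.std > 0.20

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_invariants(self, values):
        rs = robust_stats(values)
        assert rs.nmad == pytest.approx(1.4826 * rs.mad)
        assert rs.ipr99 >= rs.ipr90 - 1e-12
        assert rs.ipr90 >= rs.iqr - 1e-12
        assert rs.iqr >= 0


class TestSegmentation:
    def test_bimodal_agreement_with_truth(self):
        rng = np.random.default_rng(0)
        truth = rng.random((60, 60)) < 0.6
        nir = np.where(truth, rng.normal(55, 1, truth.shape), rng.normal(15, 1, truth.shape))
        seg = segment_vegetation(nir)
        assert (seg.mask == truth).mean() >= 0.99
        assert 15 < seg.threshold < 55

    def test_constant_image_is_degenerate(self):
        with pytest.raises(DegenerateClusteringError):
            segment_vegetation(np.full((10, 10), 7.0))

    def test_only_two_classes_supported(self):
        with pytest.raises(NumericDomainError):
            segment_vegetation(np.random.default_rng(0).random((5, 5)), k=3)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        nir = np.where(rng.random((40, 40)) < 0.5, rng.normal(55, 1, (40, 40)),
                       rng.normal(15, 1, (40, 40)))
        a = segment_vegetation(nir)
        b = segment_vegetation(0.3 * nir + 7.0)
        np.testing.assert_array_equal(a.mask, b.mask)


class TestCoverAndRows:
    def test_cover_area_arithmetic(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask.flat[:100] = True
        area, pct = canopy_cover(mask, 0.0508)
        assert area == pytest.approx(100 * 0.0508**2)
        assert pct == pytest.approx(100 * 100 / 900)

    def test_empty_and_full_masks(self):
        assert canopy_cover(np.zeros((5, 5), bool), 0.1) == (0.0, 0.0)
        assert canopy_cover(np.ones((5, 5), bool), 0.1)[1] == 100.0

    @pytest.mark.parametrize("rows_per_plot", [6, 8])
    def test_count_rows_on_synthetic_stripes(self, rows_per_plot):
        from uasyield.plotgrid import FieldSpec, build_plot_polygons, clip_raster
        from uasyield.synthdata import generate_orthomosaic, generate_truths

        spec = FieldSpec(n_cols=2, n_rows=2, rows_per_plot=rows_per_plot, seed=5)
        truths = generate_truths(spec)
        for t in truths:  # moderate cover keeps the inter-row gaps open
            t.cc_frac = 0.7
        raster, _ = generate_orthomosaic(spec, truths)
        for poly in build_plot_polygons(spec, [t.family for t in truths]):
            plot = clip_raster(raster, poly)
            assert count_rows(plot.band("NIR")) == rows_per_plot

    def test_count_rows_degenerate_input(self):
        assert count_rows(np.zeros((10, 10))) == 0

    def test_row_length_of_stripe(self):
        mask = np.zeros((10, 50), dtype=bool)
        mask[4, 5:45] = True  # 40 px long stripe
        assert row_length(mask, 0.05) == pytest.approx(1.95, abs=0.05)

    def test_row_length_two_pixels(self):
        mask = np.zeros((3, 20), dtype=bool)
        mask[1, 4] = mask[1, 14] = True
        assert row_length(mask, 0.05) == pytest.approx(0.5)

    def test_row_length_disc_equals_diameter(self):
        yy, xx = np.mgrid[-30:31, -30:31]
        mask = xx**2 + yy**2 <= 25**2
        assert row_length(mask, 1.0) == pytest.approx(50, rel=0.05)

    def test_row_length_needs_two_pixels(self):
        with pytest.raises(SampleSizeError):
            row_length(np.zeros((5, 5), bool), 0.05)


class TestVegetationIndices:
    medians_dap61 = {"G": 6.19, "R": 2.51, "RE": 32.03, "NIR": 55.42}

    def test_nir_equals_red_zeroes_difference_indices(self):
        vi = compute_vis({"G": 5.0, "R": 30.0, "RE": 32.0, "NIR": 30.0})
        assert vi["NDVI"] == 0.0 and vi["DVI"] == 0.0 and vi["RVI"] == 1.0

    def test_reference_medians(self):
        vi = compute_vis(self.medians_dap61)
        assert vi["NDVI"] == pytest.approx(0.9133, abs=5e-4)
        assert vi["RVI"] == pytest.approx(22.08, abs=5e-2)
        assert vi["CIre"] == pytest.approx(0.7302, abs=5e-4)

    def test_all_indices_present(self):
        assert set(compute_vis(self.medians_dap61)) == set(VI_NAMES)

    def test_printed_variants(self):
        vi = compute_vis(
            self.medians_dap61,
            VIParams(cig_as_printed=True, gesavi_as_printed=True),
        )
        g, nir, r = 0.0619, 0.5542, 0.0251
        assert vi["CIg"] == pytest.approx((nir - g) - 1)
        assert vi["GESAVI"] == pytest.approx((nir - 1.0) * r / (r + 0.35))

    def test_nonpositive_median_rejected(self):
        with pytest.raises(NumericDomainError):
            compute_vis({"G": 6.0, "R": 0.0, "RE": 32.0, "NIR": 55.0})


class TestPlotFeatures:
    def test_cover_matches_truth_and_schema(self, small_field):
        from uasyield.plotgrid import clip_raster

        poly, truth = small_field.polygons[0], small_field.truths[0]
        plot = clip_raster(small_field.orthomosaics["DAP61"], poly)
        feats = plot_radiometric_features(plot, plot_id=poly.plot_id)
        n_pix = plot.shape[0] * plot.shape[1]
        assert abs(feats.canopy_cover_pct - 100 * truth.cc_frac) <= 100.0 / n_pix
        row = feats.model_row()
        assert list(row) == msi_feature_columns()
        assert len(row) == 24

    def test_all_soil_plot_is_degenerate(self):
        from uasyield.rasters import MultispectralRaster

        rng = np.random.default_rng(0)
        # soil-only reflectance: NIR unimodal, no canopy present
        data = np.stack([rng.normal(m, 1.0, (20, 20)) for m in (10, 12, 14, 15)])
        plot = MultispectralRaster(data, origin=(0.0, 1.0), gsd=0.05)
        with pytest.raises(DegenerateClusteringError):
            plot_radiometric_features(plot, plot_id="soil")
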