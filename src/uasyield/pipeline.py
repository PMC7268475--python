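"""End-to-end orchestration: synthetic field -> features -> model -> report.

The stages mirror the field workflow: render/load the study inputs,
clip every plot from the orthomosaics and run the radiometric stage,
filter/register/difference the point clouds and run the geometric
stage, fuse the 60-feature table with the harvest yields, fit the two
ensemble regressors, and evaluate.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from uasyield import canopy3d, evalsuite, synthdata, triples, yieldml
from uasyield.canopy3d import HeightField, RigidTransform
from uasyield.clouds import PointCloud
from uasyield.plotgrid import (
    FieldSpec,
    PlotPolygon,
    clip_raster,
    in_any_plot_mask,
)
from uasyield.rasters import MultispectralRaster


# ---------------------------------------------------------------------------
# radiometric feature extraction
# ---------------------------------------------------------------------------


def extract_msi_features(
    raster: MultispectralRaster,
    polys: list[PlotPolygon],
    params: triples.VIParams | None = None,
) -> pd.DataFrame:
    """One radiometric feature row per plot (model columns only)."""
    rows = []
    for poly in polys:
        plot = clip_raster(raster, poly)
        feats = triples.plot_radiometric_features(plot, params, plot_id=poly.plot_id)
        rows.append({"plot_id": poly.plot_id, **feats.model_row()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# geometric feature extraction
# ---------------------------------------------------------------------------


@dataclass
class GeometryResult:
    features: pd.DataFrame                   # long form: plot_id, source, ...
    height_fields: dict[str, HeightField]
    transforms: dict[str, RigidTransform]    # recovered registration per date
    dropped_plots: list[str]
    calibration_offsets: dict[str, float]


def register_canopy(
    canopy: PointCloud,
    terrain: PointCloud,
    spec: FieldSpec,
    tie_points: tuple[np.ndarray, np.ndarray] | None = None,
    bars: pd.DataFrame | None = None,
    bar_exclusion_m: float = 0.5,
) -> tuple[PointCloud, RigidTransform]:
    """Rigidly align a canopy cloud to the terrain frame.

    Coarse alignment comes from tie points known in both frames (the
    stand-in for manually picked control points); ICP then refines on
    ground points only — points outside every plot footprint and away
    from the calibration bars.
    """
    init = (
        canopy3d.kabsch(tie_points[0], tie_points[1])
        if tie_points is not None
        else RigidTransform.identity()
    )
    coarse = init.apply(canopy.points)
    ground = ~in_any_plot_mask(spec, coarse[:, :2])
    if bars is not None and len(bars):
        from scipy.spatial import cKDTree

        bar_tree = cKDTree(bars[["x", "y"]].to_numpy())
        d, _ = bar_tree.query(coarse[:, :2])
        ground &= d > bar_exclusion_m
    moving = PointCloud(canopy.points[ground], canopy.date_tag, canopy.role)
    transform = canopy3d.icp_register(moving, terrain, init=init)
    registered = PointCloud(
        transform.apply(canopy.points), canopy.date_tag, canopy.role
    )
    return registered, transform


def extract_geometry(
    clouds: synthdata.SyntheticClouds,
    spec: FieldSpec,
    polys: list[PlotPolygon],
    grid_m: float = 0.45,
    filter_k: int = 8,
    filter_sigma: float = 2.0,
    calibration_tolerance_m: float = 0.025,
) -> GeometryResult:
    """Filter, register, difference, calibrate and mesh the study clouds."""
    bars_list = list(clouds.bars[["x", "y", "height_m"]].itertuples(index=False))
    height_fields: dict[str, HeightField] = {}
    transforms: dict[str, RigidTransform] = {}
    offsets: dict[str, float] = {}
    for date, cloud in clouds.canopy.items():
        filtered, _ = canopy3d.filter_outliers(cloud, filter_k, filter_sigma)
        registered, transform = register_canopy(
            filtered,
            clouds.terrain,
            spec,
            tie_points=clouds.tie_points.get(date),
            bars=clouds.bars,
        )
        hf = canopy3d.height_deviation(registered, clouds.terrain)
        hf = canopy3d.calibrate_heights(
            hf, bars_list, tolerance_m=calibration_tolerance_m
        )
        height_fields[date] = hf
        transforms[date] = transform
        offsets[date] = hf.calibration_offset_m
    records, dropped = canopy3d.plot_geometric_features(
        height_fields, polys, grid_m=grid_m
    )
    features = pd.DataFrame(
        [
            {
                "plot_id": r.plot_id,
                "source": r.source,
                "CV_dm3": r.cv_dm3,
                "Hmax_cm": r.hmax_cm,
                "CVvar_pct": r.cv_var_pct,
                "Hmaxvar_pct": r.hmax_var_pct,
                "Hmean_cm": r.hmean_cm,
                "Hstd_cm": r.hstd_cm,
            }
            for r in records
        ]
    )
    return GeometryResult(
        features=features,
        height_fields=height_fields,
        transforms=transforms,
        dropped_plots=dropped,
        calibration_offsets=offsets,
    )


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    field: synthdata.SyntheticField
    msi_features: dict[str, pd.DataFrame]
    geometry: GeometryResult
    table: pd.DataFrame
    fits: dict[str, yieldml.FitResult]
    reports: dict[str, dict[str, evalsuite.ErrorReport]]
    robust_fits: dict[str, evalsuite.RobustFit]
    family_tables: dict[str, pd.DataFrame]


def build_feature_table(
    field: synthdata.SyntheticField,
    geometry: GeometryResult | None = None,
    msi_features: dict[str, pd.DataFrame] | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], GeometryResult]:
    """Extract both feature families and fuse them with the yields."""
    msi_features = msi_features or {
        date: extract_msi_features(raster, field.polygons)
        for date, raster in field.orthomosaics.items()
    }
    geometry = geometry or extract_geometry(field.clouds, field.spec, field.polygons)
    rgb = geometry.features[
        ["plot_id", "source", "CV_dm3", "Hmax_cm", "CVvar_pct", "Hmaxvar_pct"]
    ]
    table = yieldml.assemble_feature_table(msi_features, rgb, field.yields)
    return table, msi_features, geometry


def run_pipeline(
    spec: FieldSpec,
    yield_sigma: float = synthdata.DEFAULT_YIELD_SIGMA,
    outlier_fraction: float = 0.01,
    height_bias_m: float = 0.0,
    model_seed: int = 42,
    test_fraction: float = 0.15,
    algorithms: tuple[str, ...] = ("forest", "boost"),
    evaluate: bool = True,
) -> PipelineResult:
    """Run the whole study on a synthetic field and return every artefact."""
    field = synthdata.generate_field(
        spec,
        yield_sigma=yield_sigma,
        outlier_fraction=outlier_fraction,
        height_bias_m=height_bias_m,
    )
    table, msi_features, geometry = build_feature_table(field)
    table = yieldml.split_train_test(table, test_fraction, seed=model_seed)

    fits: dict[str, yieldml.FitResult] = {}
    reports: dict[str, dict[str, evalsuite.ErrorReport]] = {}
    robust_fits: dict[str, evalsuite.RobustFit] = {}
    family_tables: dict[str, pd.DataFrame] = {}
    for algorithm in algorithms:
        config = yieldml.ModelConfig(
            algorithm=algorithm, seed=model_seed, test_fraction=test_fraction
        )
        fit = yieldml.fit_model(config, table)
        fits[algorithm] = fit
        if not evaluate:
            continue
        reports[algorithm] = {
            "train": evalsuite.error_metrics(fit.pred_train, fit.act_train),
            "test": evalsuite.error_metrics(fit.pred_test, fit.act_test),
        }
        if len(fit.act_test) > 3:  # studentization needs n > p + 1
            robust_fits[algorithm] = evalsuite.robust_linear_fit(
                fit.act_test.to_numpy(), fit.pred_test.to_numpy()
            )
        ae = 100.0 * (fit.pred_test - fit.act_test).abs() / fit.act_test
        family_tables[algorithm] = evalsuite.family_errors(
            ae, table.loc[ae.index, "family"]
        )
    return PipelineResult(
        field=field,
        msi_features=msi_features,
        geometry=geometry,
        table=table,
        fits=fits,
        reports=reports,
        robust_fits=robust_fits,
        family_tables=family_tables,
    )
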