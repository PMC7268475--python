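"""Synthetic soybean breeding field generator.

Stands in for the flight and harvest campaign: it emits a plot layout,
4-band reflectance orthomosaics for two study dates, terrain and canopy
point clouds (with a known rigid perturbation, injected gross outliers
and fixed calibration bars), and per-plot grain yields generated as a
linear function of the latent canopy traits plus Gaussian noise.

Every plot carries latent traits — canopy-cover fraction, per-date mean
canopy height, and a chlorophyll scalar that drives the NIR/G contrast
— standing in for genotype effects.  Default scales follow the
soybean-trial setting the pipeline targets: vegetation band medians
near (G 6.2, R 2.5, RE 32, NIR 55)% with soil NIR well separated at
15%, canopy heights near 0.58 m and 0.80 m on the two dates, and
yields with marginal mean ~3783 kg/ha and SD ~770 kg/ha.

All generators are deterministic functions of ``FieldSpec.seed`` (plus
a per-product stream key), so a rerun is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from uasyield.canopy3d import RigidTransform
from uasyield.clouds import PointCloud
from uasyield.errors import LayoutError, ParameterError
from uasyield.plotgrid import FieldSpec, PlotPolygon, build_plot_polygons
from uasyield.rasters import MultispectralRaster

DATES = ("DAP61", "DAP70")

#: round-robin family labels; list length ~n_plots/30 keeps 4-6 plots per
#: family in a 15% test split of an 840-plot trial
DEFAULT_FAMILIES = ["PI404188A", "Prohio", "LG90-2550"] + [
    f"RIL-{i:03d}" for i in range(4, 29)
]

#: vegetation band medians per date, percent reflectance
VEG_REFLECTANCE = {
    "DAP61": {"G": 6.19, "R": 2.51, "RE": 32.03, "NIR": 55.42},
    "DAP70": {"G": 5.85, "R": 2.60, "RE": 32.22, "NIR": 55.58},
}
SOIL_REFLECTANCE = {"G": 10.0, "R": 12.0, "RE": 14.0, "NIR": 15.0}

#: mean canopy heights per date (metres) matching deviation-cloud scale
HEIGHT_MEANS = {"DAP61": 0.578, "DAP70": 0.798}

#: yield model: intercept + b_cc * cc + b_h * height + b_chl * chl, chosen so
#: the marginal mean is ~3783.4 kg/ha and (with sigma) the SD is ~770 kg/ha
DEFAULT_YIELD_COEFFS = (-2102.991, 3000.0, 2800.0, 1500.0)
DEFAULT_YIELD_SIGMA = 630.0


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *stream])


@dataclass
class PlotTruth:
    """Latent traits of one plot (the generator's ground truth)."""

    plot_id: str
    family: str
    cc_frac: float                      # canopy-cover fraction, [0, 1]
    height_m: dict[str, float]          # per-date mean canopy height
    chl: float                          # chlorophyll scalar, ~1
    yield_kg_ha: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.cc_frac <= 1.0:
            raise ParameterError(f"{self.plot_id}: cc_frac outside [0, 1]")
        if any(h < 0 for h in self.height_m.values()):
            raise ParameterError(f"{self.plot_id}: negative canopy height")


def generate_truths(
    spec: FieldSpec,
    families: list[str] | None = None,
    cc_mean: float = 0.82,
    cc_sd: float = 0.08,
    height_sd: float = 0.10,
    increment_mean: float = 0.22,
    increment_sd: float = 0.05,
    chl_sd: float = 0.15,
) -> list[PlotTruth]:
    """Draw latent traits for every plot of the field."""
    rng = _rng(spec.seed, 1)
    polys = build_plot_polygons(spec, families or DEFAULT_FAMILIES)
    cc = np.clip(rng.normal(cc_mean, cc_sd, spec.n_plots), 0.30, 0.98)
    h1 = np.maximum(rng.normal(HEIGHT_MEANS["DAP61"], height_sd, spec.n_plots), 0.05)
    h2 = h1 + np.maximum(rng.normal(increment_mean, increment_sd, spec.n_plots), 0.0)
    chl = np.clip(rng.normal(1.0, chl_sd, spec.n_plots), 0.5, 1.5)
    return [
        PlotTruth(
            plot_id=p.plot_id,
            family=p.family,
            cc_frac=float(cc[i]),
            height_m={"DAP61": float(h1[i]), "DAP70": float(h2[i])},
            chl=float(chl[i]),
        )
        for i, p in enumerate(polys)
    ]


# ---------------------------------------------------------------------------
# orthomosaic
# ---------------------------------------------------------------------------


def _check_layout(polys: list[PlotPolygon]) -> None:
    """Plots must be pairwise disjoint (regular grids always are)."""
    # sort by min_x, then a linear sweep catches overlap in O(n log n)
    order = sorted(polys, key=lambda p: (p.min_y, p.min_x))
    for a, b in zip(order, order[1:]):
        if (
            a.min_x < b.max_x and b.min_x < a.max_x
            and a.min_y < b.max_y and b.min_y < a.max_y
        ):
            raise LayoutError(f"plots {a.plot_id} and {b.plot_id} overlap")


def generate_orthomosaic(
    spec: FieldSpec,
    truths: list[PlotTruth],
    date: str = "DAP61",
    noise_sigma: float = 1.0,
    chl_gain: float = 0.3,
    veg_reflectance: dict[str, float] | None = None,
    soil_reflectance: dict[str, float] | None = None,
) -> tuple[MultispectralRaster, np.ndarray]:
    """Render the 4-band orthomosaic for one date.

    Vegetation pixels are laid out as ``rows_per_plot`` stripes spaced
    ``row_spacing_m`` apart; the stripe width is set per plot so the
    vegetation pixel count equals ``round(cc_frac * plot pixels)``
    exactly.  The chlorophyll scalar shifts NIR up and G down by
    ``chl_gain`` per unit.  Per-pixel Gaussian noise is truncated at 0.
    Returns the raster and the boolean vegetation truth mask.
    """
    if len(truths) != spec.n_plots:
        raise ParameterError("truths must cover every plot in the spec")
    veg = dict(veg_reflectance or VEG_REFLECTANCE.get(date, VEG_REFLECTANCE["DAP61"]))
    soil = dict(soil_reflectance or SOIL_REFLECTANCE)
    polys = build_plot_polygons(spec, [t.family for t in truths])
    _check_layout(polys)
    by_id = {t.plot_id: t for t in truths}
    if set(by_id) != {p.plot_id for p in polys}:
        raise ParameterError("truth plot_ids do not match the layout")

    rng = _rng(spec.seed, 2, sum(map(ord, date)))
    min_x, min_y, max_x, max_y = spec.extent
    gsd = spec.gsd_msi_m
    w = int(np.ceil((max_x - min_x) / gsd))
    h = int(np.ceil((max_y - min_y) / gsd))
    origin = (min_x, max_y)

    bands = ("G", "R", "RE", "NIR")
    data = np.empty((4, h, w), dtype=np.float32)
    for bi, b in enumerate(bands):
        data[bi] = rng.normal(soil[b], noise_sigma, (h, w))
    truth_mask = np.zeros((h, w), dtype=bool)

    xs = origin[0] + (np.arange(w) + 0.5) * gsd
    ys = origin[1] - (np.arange(h) + 0.5) * gsd
    for poly in polys:
        t = by_id[poly.plot_id]
        jj = np.nonzero((xs >= poly.min_x) & (xs < poly.max_x))[0]
        ii = np.nonzero((ys >= poly.min_y) & (ys < poly.max_y))[0]
        if jj.size == 0 or ii.size == 0:
            continue
        veg_local = _stripe_mask(
            xs[jj], ys[ii], poly, spec, t.cc_frac
        )
        win = np.ix_(ii, jj)
        truth_mask[win] |= veg_local
        n_veg = int(veg_local.sum())
        if n_veg == 0:
            continue
        mod = {
            "G": max(1e-3, 1.0 - chl_gain * (t.chl - 1.0)),
            "R": 1.0,
            "RE": 1.0,
            "NIR": 1.0 + chl_gain * (t.chl - 1.0),
        }
        for bi, b in enumerate(bands):
            block = data[bi][win]
            block[veg_local] = rng.normal(veg[b] * mod[b], noise_sigma, n_veg)
            data[bi][win] = block
    np.maximum(data, 0.0, out=data)  # reflectance cannot be negative
    raster = MultispectralRaster(data, origin=origin, gsd=gsd, bands=bands)
    return raster, truth_mask


def _stripe_mask(
    xs: np.ndarray, ys: np.ndarray, poly: PlotPolygon, spec: FieldSpec, cc_frac: float
) -> np.ndarray:
    """Vegetation mask of one plot window with an exact pixel count.

    Pixels are ranked by distance to the nearest crop-row centreline
    (ties broken by distance to the plot's mid-length, then by index)
    and the closest ``round(cc_frac * n)`` are vegetation, so stripes
    widen smoothly with canopy cover and close completely at 1.
    """
    n_pix = ys.size * xs.size
    target = int(round(cc_frac * n_pix))
    if target == 0:
        return np.zeros((ys.size, xs.size), dtype=bool)
    block = spec.rows_per_plot * spec.row_spacing_m
    left = poly.min_x + (poly.max_x - poly.min_x - block) / 2
    centers = left + (np.arange(spec.rows_per_plot) + 0.5) * spec.row_spacing_m
    dist_x = np.min(np.abs(xs[None, :] - centers[:, None]), axis=0)
    mid_y = (poly.min_y + poly.max_y) / 2
    dist_y = np.abs(ys - mid_y)
    dxx = np.broadcast_to(dist_x[None, :], (ys.size, xs.size)).ravel()
    dyy = np.broadcast_to(dist_y[:, None], (ys.size, xs.size)).ravel()
    order = np.lexsort((np.arange(n_pix), dyy, dxx))
    mask = np.zeros(n_pix, dtype=bool)
    mask[order[:target]] = True
    return mask.reshape(ys.size, xs.size)


# ---------------------------------------------------------------------------
# point clouds
# ---------------------------------------------------------------------------


@dataclass
class SyntheticClouds:
    """Terrain + canopy clouds with their generation metadata."""

    terrain: PointCloud
    canopy: dict[str, PointCloud]               # delivered (perturbed) frame
    perturbations: dict[str, RigidTransform]    # applied true->delivered
    tie_points: dict[str, tuple[np.ndarray, np.ndarray]]  # (moving, fixed)
    bars: pd.DataFrame                          # x, y, height_m (surveyed)
    outlier_labels: dict[str, np.ndarray]       # True where injected outlier
    quadric: tuple[float, ...]                  # terrain surface coefficients


DEFAULT_QUADRIC = (0.0, 0.010, -0.008, 2.0e-5, -1.0e-5, 1.5e-5)
DEFAULT_PERTURBATIONS = {
    "DAP61": {"yaw_deg": 2.0, "translation": (0.5, 0.3, 0.1)},
    "DAP70": {"yaw_deg": -1.5, "translation": (-0.4, 0.25, -0.05)},
}
DEFAULT_BAR_HEIGHTS = (1.2, 1.4, 1.5, 1.6, 1.8)


def _quadric_z(coeffs, x, y):
    c0, c1, c2, c3, c4, c5 = coeffs
    return c0 + c1 * x + c2 * y + c3 * x**2 + c4 * x * y + c5 * y**2


def _yaw_transform(yaw_deg: float, translation) -> RigidTransform:
    th = np.radians(yaw_deg)
    rot = np.array(
        [[np.cos(th), -np.sin(th), 0.0], [np.sin(th), np.cos(th), 0.0], [0.0, 0.0, 1.0]]
    )
    return RigidTransform(rot, np.asarray(translation, dtype=float))


def generate_clouds(
    spec: FieldSpec,
    truths: list[PlotTruth],
    density_per_m2: float = 100.0,
    noise_z: float = 0.01,
    height_cv: float = 0.15,
    outlier_fraction: float = 0.01,
    height_bias_m: float = 0.0,
    quadric: tuple[float, ...] = DEFAULT_QUADRIC,
    perturbations: dict | None = None,
    bar_heights: tuple[float, ...] = DEFAULT_BAR_HEIGHTS,
    dates: tuple[str, ...] = DATES,
) -> SyntheticClouds:
    """Generate terrain and canopy clouds for the field.

    The terrain is a gentle quadric surface sampled uniformly at
    ``density_per_m2``.  Canopy clouds resample the surface and add the
    per-plot canopy height (with multiplicative within-plot variation
    ``height_cv``), the fixed bars, an optional systematic height bias
    of the *elevated* returns (``height_bias_m`` emulates the
    photogrammetric over/under-estimation of thin canopy and bar tops;
    ground stays unbiased, so registration cannot absorb the bias and
    bar calibration must), and a fraction of gross z outliers; the
    whole cloud is then moved by a known rigid perturbation so
    registration is exercised.  Tie
    points (4 ground locations known in both frames) support the
    coarse alignment.
    """
    if not 0 <= outlier_fraction < 1:
        raise ParameterError("outlier_fraction must be in [0, 1)")
    by_id = {t.plot_id: t for t in truths}
    min_x, min_y, max_x, max_y = spec.extent
    area = (max_x - min_x) * (max_y - min_y)
    n_pts = int(np.ceil(density_per_m2 * area))

    rng = _rng(spec.seed, 3)
    xy_t = np.column_stack(
        [rng.uniform(min_x, max_x, n_pts), rng.uniform(min_y, max_y, n_pts)]
    )
    z_t = _quadric_z(quadric, xy_t[:, 0], xy_t[:, 1]) + rng.normal(0, noise_z, n_pts)
    terrain = PointCloud(np.column_stack([xy_t, z_t]), date_tag="DAP15", role="terrain")

    # bars along the bottom margin, outside every plot
    bar_x = np.linspace(min_x + 2.0, max_x - 2.0, len(bar_heights))
    bar_y = np.full(len(bar_heights), min_y + spec.margin_m / 2)
    bars = pd.DataFrame({"x": bar_x, "y": bar_y, "height_m": bar_heights})

    pert_spec = perturbations or DEFAULT_PERTURBATIONS
    canopy: dict[str, PointCloud] = {}
    applied: dict[str, RigidTransform] = {}
    ties: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    labels: dict[str, np.ndarray] = {}
    tie_xy = np.array(
        [
            [min_x + 1.0, min_y + 1.0],
            [max_x - 1.0, min_y + 1.0],
            [max_x - 1.0, max_y - 1.0],
            [min_x + 1.0, max_y - 1.0],
        ]
    )
    tie_fixed = np.column_stack(
        [tie_xy, _quadric_z(quadric, tie_xy[:, 0], tie_xy[:, 1])]
    )

    for di, date in enumerate(dates):
        drng = _rng(spec.seed, 4, di)
        xy = np.column_stack(
            [drng.uniform(min_x, max_x, n_pts), drng.uniform(min_y, max_y, n_pts)]
        )
        z = _quadric_z(quadric, xy[:, 0], xy[:, 1]) + drng.normal(0, noise_z, n_pts)
        # add canopy height inside plots
        in_plot, plot_idx = _plot_index(spec, xy)
        if in_plot.any():
            h_mean = np.array(
                [by_id[t.plot_id].height_m.get(date, 0.0) for t in truths]
            )
            factor = np.maximum(1.0 + height_cv * drng.normal(size=in_plot.sum()), 0.0)
            z[in_plot] += h_mean[plot_idx[in_plot]] * factor
        pts = np.column_stack([xy, z])
        elevated = in_plot.copy()
        labels_d = np.zeros(len(pts), dtype=bool)
        # fixed bars: dense small discs at surveyed height above the terrain
        for bx, by, bh in bars.itertuples(index=False):
            nb = 200
            ang = drng.uniform(0, 2 * np.pi, nb)
            rad = 0.1 * np.sqrt(drng.uniform(0, 1, nb))
            bxy = np.column_stack([bx + rad * np.cos(ang), by + rad * np.sin(ang)])
            bz = _quadric_z(quadric, bxy[:, 0], bxy[:, 1]) + bh
            bz += drng.normal(0, noise_z, nb)
            pts = np.vstack([pts, np.column_stack([bxy, bz])])
            labels_d = np.concatenate([labels_d, np.zeros(nb, dtype=bool)])
            elevated = np.concatenate([elevated, np.ones(nb, dtype=bool)])
        pts[elevated, 2] += height_bias_m
        # gross outliers: isolated points displaced vertically
        n_out = int(round(outlier_fraction * len(pts)))
        if n_out:
            out_idx = drng.choice(len(pts), n_out, replace=False)
            sign = drng.choice([-1.0, 1.0], n_out)
            pts[out_idx, 2] += sign * drng.uniform(1.0, 3.0, n_out)
            labels_d[out_idx] = True
        pert = _yaw_transform(**pert_spec[date])
        canopy[date] = PointCloud(pert.apply(pts), date_tag=date, role="canopy")
        applied[date] = pert
        ties[date] = (pert.apply(tie_fixed), tie_fixed.copy())
        labels[date] = labels_d

    return SyntheticClouds(
        terrain=terrain,
        canopy=canopy,
        perturbations=applied,
        tie_points=ties,
        bars=bars,
        outlier_labels=labels,
        quadric=tuple(quadric),
    )


def _plot_index(spec: FieldSpec, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(in-plot mask, index into the top-right row-major truth ordering)."""
    pitch_x = spec.plot_width_m + spec.alley_m
    pitch_y = spec.plot_length_m + spec.alley_m
    x, y = xy[:, 0], xy[:, 1]
    in_field = (x >= 0) & (x < spec.field_width_m) & (y >= 0) & (y < spec.field_height_m)
    col_left = np.floor_divide(x, pitch_x).astype(int)
    row_bot = np.floor_divide(y, pitch_y).astype(int)
    inside = (
        in_field
        & (np.mod(x, pitch_x) < spec.plot_width_m)
        & (np.mod(y, pitch_y) < spec.plot_length_m)
    )
    col_left = np.clip(col_left, 0, spec.n_cols - 1)
    row_bot = np.clip(row_bot, 0, spec.n_rows - 1)
    c = spec.n_cols - 1 - col_left
    r = spec.n_rows - 1 - row_bot
    return inside, r * spec.n_cols + c


# ---------------------------------------------------------------------------
# yields
# ---------------------------------------------------------------------------


def generate_yield(
    truths: list[PlotTruth],
    coeffs: tuple[float, float, float, float] = DEFAULT_YIELD_COEFFS,
    sigma: float = DEFAULT_YIELD_SIGMA,
    seed: int = 0,
    floor_kg_ha: float = 100.0,
) -> pd.DataFrame:
    """Grain yields as a linear function of the latent traits + noise.

    ``yield_i = c0 + c1 cc_i + c2 mean-height_i + c3 chl_i + N(0, sigma)``,
    floored at a small positive value.  Also writes the yields back onto
    the truth records.
    """
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    if len(coeffs) != 4:
        raise ParameterError("coeffs must be (intercept, cc, height, chl)")
    rng = _rng(seed, 5)
    cc = np.array([t.cc_frac for t in truths])
    h = np.array([float(np.mean(list(t.height_m.values()))) for t in truths])
    chl = np.array([t.chl for t in truths])
    y = coeffs[0] + coeffs[1] * cc + coeffs[2] * h + coeffs[3] * chl
    if sigma > 0:
        y = y + rng.normal(0, sigma, len(truths))
    y = np.maximum(y, floor_kg_ha)
    for t, yi in zip(truths, y):
        t.yield_kg_ha = float(yi)
    return pd.DataFrame(
        {
            "plot_id": [t.plot_id for t in truths],
            "family": [t.family for t in truths],
            "yield_kg_ha": y,
        }
    )


# ---------------------------------------------------------------------------
# whole-field convenience
# ---------------------------------------------------------------------------


@dataclass
class SyntheticField:
    """Everything the downstream pipeline consumes, plus the truth."""

    spec: FieldSpec
    truths: list[PlotTruth]
    polygons: list[PlotPolygon]
    orthomosaics: dict[str, MultispectralRaster]
    truth_masks: dict[str, np.ndarray]
    clouds: SyntheticClouds
    yields: pd.DataFrame


def generate_field(
    spec: FieldSpec,
    yield_sigma: float = DEFAULT_YIELD_SIGMA,
    yield_coeffs: tuple[float, float, float, float] = DEFAULT_YIELD_COEFFS,
    noise_sigma: float = 1.0,
    outlier_fraction: float = 0.01,
    height_bias_m: float = 0.0,
    dates: tuple[str, ...] = DATES,
    families: list[str] | None = None,
) -> SyntheticField:
    """Generate the full synthetic study: layout, imagery, clouds, yields."""
    truths = generate_truths(spec, families=families)
    polys = build_plot_polygons(spec, [t.family for t in truths])
    orthos, masks = {}, {}
    for date in dates:
        raster, mask = generate_orthomosaic(spec, truths, date, noise_sigma=noise_sigma)
        orthos[date], masks[date] = raster, mask
    clouds = generate_clouds(
        spec,
        truths,
        outlier_fraction=outlier_fraction,
        height_bias_m=height_bias_m,
        dates=dates,
    )
    yields = generate_yield(truths, coeffs=yield_coeffs, sigma=yield_sigma, seed=spec.seed)
    return SyntheticField(
        spec=spec,
        truths=truths,
        polygons=polys,
        orthomosaics=orthos,
        truth_masks=masks,
        clouds=clouds,
        yields=yields,
    )


def write_field(field: SyntheticField, outdir) -> None:
    """Write the generated study to disk (GeoTIFF, PLY, GeoJSON, CSV)."""
    from pathlib import Path

    from uasyield.plotgrid import polygons_to_geojson

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for date, raster in field.orthomosaics.items():
        raster.to_tiff(out / f"msi_{date}.tif")
    field.clouds.terrain.to_ply(out / "terrain_DAP15.ply")
    for date, cloud in field.clouds.canopy.items():
        cloud.to_ply(out / f"canopy_{date}.ply")
    polygons_to_geojson(field.polygons, out / "plots.geojson")
    field.clouds.bars.to_csv(out / "bars.csv", index=False)
    field.yields.to_csv(out / "yields.csv", index=False)
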