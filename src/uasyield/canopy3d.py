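"""Geometric per-plot feature stage from photogrammetric point clouds.

The pre-emergence flight supplies a terrain-reference cloud; each study
date supplies a canopy cloud.  The stage filters isolated points,
rigidly registers canopy clouds onto the terrain frame by ICP over
ground points, computes a per-point deviation (canopy height above a
local quadric fit to the terrain), calibrates heights against fixed
bars of surveyed height, and integrates canopy volume per plot from a
Delaunay triangulation of the height field sampled on a 0.45 m grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import Delaunay, QhullError, cKDTree

from uasyield.clouds import PointCloud
from uasyield.errors import (
    CalibrationError,
    DataQualityWarning,
    MeshingError,
    ParameterError,
    RegistrationWarning,
)
from uasyield.plotgrid import PlotPolygon, in_polygon_mask


# ---------------------------------------------------------------------------
# rigid transforms and registration
# ---------------------------------------------------------------------------


@dataclass
class RigidTransform:
    """Rotation + translation, with the post-fit closest-point RMS."""

    rotation: np.ndarray       # (3, 3), orthonormal, det +1
    translation: np.ndarray    # (3,)
    rms_m: float = float("nan")

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
            self.rms_m,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation, self.rms_m)

    @property
    def yaw_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.rotation[1, 0], self.rotation[0, 0])))


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``moving`` onto ``fixed``."""
    a = np.atleast_2d(moving)
    b = np.atleast_2d(fixed)
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, cb - r @ ca)


def filter_outliers(
    cloud: PointCloud,
    k_neighbors: int = 8,
    n_sigma: float = 2.0,
    max_fraction: float = 0.05,
) -> tuple[PointCloud, np.ndarray]:
    """Statistical outlier removal on the k-nearest-neighbour distances.

    Each point's mean distance to its ``k_neighbors`` nearest neighbours
    is compared against the cloud-wide Gaussian model of those
    distances; points beyond ``mean + n_sigma * SD`` are dropped.
    Returns the filtered cloud and the boolean keep mask.  Removing
    more than ``max_fraction`` of points raises a data-quality warning.
    """
    n = len(cloud)
    if n <= k_neighbors:
        raise ParameterError("cloud must have more points than k_neighbors")
    tree = cKDTree(cloud.points)
    dists, _ = tree.query(cloud.points, k=k_neighbors + 1)
    mean_d = dists[:, 1:].mean(axis=1)  # drop self-distance
    keep = mean_d <= mean_d.mean() + n_sigma * mean_d.std()
    removed_frac = 1.0 - keep.mean()
    if removed_frac > max_fraction:
        warnings.warn(
            f"outlier filter removed {removed_frac:.1%} of points "
            f"(limit {max_fraction:.1%})",
            DataQualityWarning,
            stacklevel=2,
        )
    return cloud.select(keep), keep


def icp_register(
    moving: PointCloud,
    fixed: PointCloud,
    init: RigidTransform | None = None,
    max_iter: int = 50,
    tol: float = 1e-6,
    max_points: int = 20000,
) -> RigidTransform:
    """Point-to-point ICP refining ``init`` so ``moving`` aligns to ``fixed``.

    Run it on ground points only: vegetation has no stable counterpart
    between dates.  Iterates closest-point correspondence + rigid
    least-squares until the RMS change drops below ``tol`` metres or
    ``max_iter`` iterations.  Large clouds are subsampled evenly (the
    returned transform applies to the full cloud).
    """
    if len(moving) == 0 or len(fixed) == 0:
        raise ParameterError("both clouds must be non-empty")
    transform = init or RigidTransform.identity()

    mv = moving.points
    if len(mv) > max_points:
        mv = mv[:: len(mv) // max_points + 1]
    fx = fixed.points
    if len(fx) > 4 * max_points:
        fx = fx[:: len(fx) // (4 * max_points) + 1]
    tree = cKDTree(fx)

    cur = transform.apply(mv)
    d0, _ = tree.query(cur)
    rms_init = float(np.sqrt(np.mean(d0**2)))
    prev_rms = rms_init
    for _ in range(max_iter):
        d, idx = tree.query(cur)
        step = kabsch(cur, fx[idx])
        transform = step.compose(transform)
        cur = transform.apply(mv)
        d, _ = tree.query(cur)
        rms = float(np.sqrt(np.mean(d**2)))
        if abs(prev_rms - rms) < tol:
            prev_rms = rms
            break
        prev_rms = rms
    if prev_rms > rms_init + tol:
        warnings.warn(
            f"ICP did not improve on its initialisation "
            f"(RMS {prev_rms:.4f} m vs {rms_init:.4f} m)",
            RegistrationWarning,
            stacklevel=2,
        )
    return replace(transform, rms_m=prev_rms)


# ---------------------------------------------------------------------------
# height deviation and calibration
# ---------------------------------------------------------------------------


@dataclass
class HeightField:
    """Per-point canopy height above the terrain reference (metres, >= 0)."""

    points: np.ndarray            # (N, 3) canopy points in the terrain frame
    heights: np.ndarray           # (N,) metres
    calibration_offset_m: float = 0.0
    fallback: np.ndarray | None = None  # True where the quadric fit degenerated

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.heights = np.asarray(self.heights, dtype=float).ravel()

    def __len__(self) -> int:
        return len(self.heights)

    def select(self, mask) -> "HeightField":
        return HeightField(
            self.points[mask],
            self.heights[mask],
            self.calibration_offset_m,
            None if self.fallback is None else self.fallback[mask],
        )


def height_deviation(
    canopy: PointCloud, terrain: PointCloud, k: int = 12
) -> HeightField:
    """Deviation cloud: canopy height above a local quadric terrain model.

    For every canopy point, a 6-coefficient quadric
    ``z = c0 + c1 x + c2 y + c3 x^2 + c4 xy + c5 y^2`` is fit to its
    ``k`` nearest terrain points (in plan position) and the height is
    the point's z minus the quadric at the point's (x, y), clamped at a
    minimum height of 0 m.  A degenerate neighbourhood falls back to
    the neighbours' mean elevation and is flagged.
    """
    if len(terrain) < 6:
        raise ParameterError("terrain cloud too small for a quadric fit")
    k = min(k, len(terrain))
    tree = cKDTree(terrain.xy)
    n = len(canopy)
    z_surf = np.empty(n)
    bad = np.zeros(n, dtype=bool)
    # chunked to bound the (chunk, k, 6) design-matrix memory
    chunk = 200_000
    for s in range(0, n, chunk):
        pts = canopy.points[s : s + chunk]
        _, idx = tree.query(pts[:, :2], k=k)
        nb = terrain.points[idx]                   # (m, k, 3)
        # local frame centred on the query point for conditioning
        dx = nb[:, :, 0] - pts[:, None, 0]
        dy = nb[:, :, 1] - pts[:, None, 1]
        a = np.stack(
            [np.ones_like(dx), dx, dy, dx**2, dx * dy, dy**2], axis=-1
        )                                          # (m, k, 6)
        z = nb[:, :, 2]
        ata = np.einsum("nki,nkj->nij", a, a)
        atz = np.einsum("nki,nk->ni", a, z)
        ata += 1e-12 * np.eye(6)                   # guard exact singularity
        with np.errstate(all="ignore"):
            coef = np.linalg.solve(ata, atz[..., None])[..., 0]
        zs = coef[:, 0]                            # quadric at the centre
        b = ~np.isfinite(zs)
        if b.any():
            zs[b] = z[b].mean(axis=1)
        z_surf[s : s + chunk] = zs
        bad[s : s + chunk] = b
    heights = np.maximum(canopy.z - z_surf, 0.0)
    return HeightField(canopy.points, heights, fallback=bad if bad.any() else None)


def calibrate_heights(
    hf: HeightField,
    bars: list[tuple[float, float, float]],
    radius_m: float = 0.3,
    tolerance_m: float = 0.025,
) -> HeightField:
    """Constant-offset calibration against fixed bars of surveyed height.

    ``bars`` is a list of ``(x, y, measured_height_m)``.  The estimated
    height at a bar is the mean deviation height within ``radius_m`` of
    its position.  The offset ``mean(measured - estimated)`` is added to
    every height; the post-calibration mean absolute bar residual must
    stay below ``tolerance_m`` (default 2.5 cm, the scale at which the
    field checks of such calibrations are typically reported).
    """
    if not bars:
        raise ParameterError("at least one bar is required")
    tree = cKDTree(hf.points[:, :2])
    estimates, measured = [], []
    for x, y, h_meas in bars:
        idx = tree.query_ball_point([x, y], radius_m)
        if not idx:
            continue
        local = hf.heights[idx]
        # isolate the bar's return cluster: ground returns around the base
        # sit near 0 and would drag the mean down
        top = local[local >= 0.5 * local.max()] if local.max() > 0 else local
        estimates.append(top.mean())
        measured.append(h_meas)
    if not estimates:
        raise CalibrationError("no height-field points near any bar")
    estimates = np.asarray(estimates)
    measured = np.asarray(measured)
    offset = float(np.mean(measured - estimates))
    residual = float(np.mean(np.abs(measured - (estimates + offset))))
    if residual > tolerance_m:
        raise CalibrationError(
            f"bar residual {residual * 100:.2f} cm exceeds "
            f"{tolerance_m * 100:.2f} cm after calibration"
        )
    return HeightField(
        hf.points,
        np.maximum(hf.heights + offset, 0.0),
        calibration_offset_m=offset,
        fallback=hf.fallback,
    )


# ---------------------------------------------------------------------------
# meshing and volume
# ---------------------------------------------------------------------------


def _triangulate_heights(
    xy: np.ndarray, heights: np.ndarray, smooth_lambda: float, smooth_passes: int
):
    """2.5-D Delaunay triangulation with Laplacian smoothing of heights."""
    try:
        tri = Delaunay(xy)
    except QhullError as exc:
        raise MeshingError(f"degenerate plot geometry: {exc}") from exc
    h = heights.astype(float).copy()
    if smooth_passes and smooth_lambda:
        indptr, indices = tri.vertex_neighbor_vertices
        for _ in range(smooth_passes):
            nbr_sum = np.zeros_like(h)
            nbr_cnt = np.maximum(np.diff(indptr), 1)
            np.add.at(nbr_sum, np.repeat(np.arange(len(h)), np.diff(indptr)), h[indices])
            h = h + smooth_lambda * (nbr_sum / nbr_cnt - h)
    return tri, h


def _grid_cells(poly: PlotPolygon, grid_m: float):
    """Grid cells covering the footprint: centres and in-polygon areas.

    Edge cells are clipped to the footprint, so the cell areas always
    sum exactly to the plot area.
    """
    x_edges = np.arange(poly.min_x, poly.max_x + grid_m, grid_m)
    x_edges[-1] = poly.max_x
    if x_edges[-1] <= x_edges[-2]:
        x_edges = x_edges[:-1]
    y_edges = np.arange(poly.min_y, poly.max_y + grid_m, grid_m)
    y_edges[-1] = poly.max_y
    if y_edges[-1] <= y_edges[-2]:
        y_edges = y_edges[:-1]
    xc = (x_edges[:-1] + x_edges[1:]) / 2
    yc = (y_edges[:-1] + y_edges[1:]) / 2
    wx = np.diff(x_edges)
    wy = np.diff(y_edges)
    centers = np.stack(
        [np.repeat(xc, yc.size), np.tile(yc, xc.size)], axis=1
    )
    areas = (wx[:, None] * wy[None, :]).ravel()
    widths = np.stack(
        [np.repeat(wx, wy.size), np.tile(wy, wx.size)], axis=1
    )
    return centers, areas, widths


def mesh_volume(
    hf: HeightField,
    poly: PlotPolygon,
    grid_m: float = 0.45,
    smooth_lambda: float = 0.5,
    smooth_passes: int = 1,
    subsamples: int = 3,
    return_cells: bool = False,
):
    """Canopy volume (dm^3) of one plot from the triangulated height surface.

    The per-point heights inside the plot are Delaunay-triangulated in
    plan view, lightly Laplacian-smoothed (one pass, lambda 0.5) to damp
    photogrammetric noise, then the surface is integrated as prisms over
    a 0.45 m grid covering the plot footprint — a trade-off between
    spatial resolution and cost.  Each cell's height is the mean of the
    surface at ``subsamples x subsamples`` points within the cell; grid
    cells without triangulation support (outside the convex hull of the
    points) are filled from the nearest height, a planar hole-filling
    equivalent.
    """
    pts = hf.points[:, :2]
    if len(pts) < 3:
        raise MeshingError("need at least 3 points to mesh a plot")
    tri, h = _triangulate_heights(pts, hf.heights, smooth_lambda, smooth_passes)
    lin = LinearNDInterpolator(tri, h)
    near = NearestNDInterpolator(pts, h)
    centers, areas, widths = _grid_cells(poly, grid_m)
    offs = (np.arange(subsamples) + 0.5) / subsamples - 0.5
    ox, oy = np.meshgrid(offs, offs)
    sub = np.stack([ox.ravel(), oy.ravel()], axis=1)
    samples = centers[:, None, :] + sub[None, :, :] * widths[:, None, :]
    flat = samples.reshape(-1, 2)
    hs = lin(flat)
    nan = np.isnan(hs)
    if nan.any():
        hs[nan] = near(flat[nan])
    hc = hs.reshape(len(centers), -1).mean(axis=1)
    cell_volumes = areas * hc
    volume_dm3 = float(cell_volumes.sum() * 1000.0)
    if return_cells:
        return volume_dm3, cell_volumes * 1000.0, centers
    return volume_dm3


# ---------------------------------------------------------------------------
# per-plot features
# ---------------------------------------------------------------------------


@dataclass
class GeometricFeatures:
    """Per-plot, per-source geometric features (units as tabulated)."""

    plot_id: str
    source: str               # date tag or "INC" for the date-to-date increment
    cv_dm3: float
    hmax_cm: float
    hmean_cm: float
    hstd_cm: float
    cv_var_pct: float
    hmax_var_pct: float


RGB_FEATURE_NAMES = ("CV_dm3", "Hmax_cm", "CVvar_pct", "Hmaxvar_pct")


def rgb_feature_columns(sources: tuple[str, ...]) -> list[str]:
    return [f"{name}@{src}" for src in sources for name in RGB_FEATURE_NAMES]


def increment_field(
    hf_late: HeightField, hf_early: HeightField, pair_radius_m: float = 0.10
) -> HeightField:
    """Growth increment as per-point height differences on the late support.

    Each late-date point is paired with its nearest early-date point
    within ``pair_radius_m`` in plan position; unpaired points are
    dropped.  Differences are clamped at 0 m, consistent with the
    minimum-height convention of the deviation cloud.
    """
    if len(hf_early) == 0 or len(hf_late) == 0:
        return HeightField(np.empty((0, 3)), np.empty(0))
    tree = cKDTree(hf_early.points[:, :2])
    d, idx = tree.query(hf_late.points[:, :2])
    paired = d <= pair_radius_m
    dh = np.maximum(hf_late.heights[paired] - hf_early.heights[idx[paired]], 0.0)
    return HeightField(hf_late.points[paired], dh)


def _one_source_features(
    hf_plot: HeightField, poly: PlotPolygon, plot_id: str, source: str, grid_m: float
) -> GeometricFeatures:
    h = hf_plot.heights
    volume, cell_vol, centers = mesh_volume(hf_plot, poly, grid_m, return_cells=True)
    # per-cell height maxima for the within-plot variation percentages
    xy = hf_plot.points[:, :2]
    ix = np.clip(((xy[:, 0] - poly.min_x) // grid_m).astype(int), 0, None)
    iy = np.clip(((xy[:, 1] - poly.min_y) // grid_m).astype(int), 0, None)
    cell_key = ix * (iy.max() + 1) + iy
    order = np.argsort(cell_key)
    keys, starts = np.unique(cell_key[order], return_index=True)
    cell_hmax = np.maximum.reduceat(h[order], starts)

    def var_pct(v: np.ndarray) -> float:
        m = v.mean()
        return float(100.0 * v.std(ddof=1) / m) if v.size > 1 and m != 0 else 0.0

    return GeometricFeatures(
        plot_id=plot_id,
        source=source,
        cv_dm3=volume,
        hmax_cm=float(h.max() * 100),
        hmean_cm=float(h.mean() * 100),
        hstd_cm=float(h.std(ddof=1) * 100) if h.size > 1 else 0.0,
        cv_var_pct=var_pct(cell_vol),
        hmax_var_pct=var_pct(cell_hmax),
    )


def plot_geometric_features(
    height_fields: dict[str, HeightField],
    plots: list[PlotPolygon],
    grid_m: float = 0.45,
    pair_radius_m: float = 0.10,
) -> tuple[list[GeometricFeatures], list[str]]:
    """Per-plot geometric features for each date plus the increment source.

    ``height_fields`` maps the two date tags (early first) to calibrated
    height fields in the terrain frame.  Returns the feature records and
    the plot ids dropped for lack of points (flagged, excluded from the
    model).
    """
    if len(height_fields) != 2:
        raise ParameterError("expected exactly two dated height fields")
    (d1, hf1), (d2, hf2) = height_fields.items()
    sources: dict[str, HeightField] = {
        d1: hf1,
        d2: hf2,
        "INC": increment_field(hf2, hf1, pair_radius_m),
    }
    records: list[GeometricFeatures] = []
    dropped: list[str] = []
    for poly in plots:
        per_plot = []
        for src, hf in sources.items():
            sub = hf.select(in_polygon_mask(hf.points[:, :2], poly))
            if len(sub) < 3:
                per_plot = []
                break
            per_plot.append(
                _one_source_features(sub, poly, poly.plot_id, src, grid_m)
            )
        if per_plot:
            records.extend(per_plot)
        else:
            dropped.append(poly.plot_id)
    return records, dropped
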