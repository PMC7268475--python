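"""Plot-polygon grid construction and per-plot clipping.

A breeding trial is a regular grid of rectangular plots separated by
alleys.  The layout script mirrors the field-map convention: it starts
from the top-right plot and proceeds row-major toward the bottom-left.
Clipping rules are chosen so adjacent plots partition space exactly:
raster clipping uses the pixel-centre-in rule and point clipping uses
half-open ``[min, max)`` bounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import box

from uasyield.clouds import PointCloud
from uasyield.errors import EmptyClipError, ParameterError
from uasyield.rasters import MultispectralRaster


@dataclass
class FieldSpec:
    """Geometry and sampling parameters of a (synthetic) breeding field.

    Crop rows run along the y axis; within a plot they are spaced
    ``row_spacing_m`` apart across the plot width (x).  ``plot_width_m``
    defaults to ``rows_per_plot * row_spacing_m``.
    """

    n_cols: int = 45
    n_rows: int = 20
    plot_length_m: float = 2.4
    plot_width_m: float | None = None
    alley_m: float = 0.5
    row_spacing_m: float = 0.76
    rows_per_plot: int = 6
    gsd_msi_m: float = 0.0508
    gsd_rgb_m: float = 0.0254
    margin_m: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plot_width_m is None:
            self.plot_width_m = self.rows_per_plot * self.row_spacing_m
        for name in (
            "plot_length_m", "plot_width_m", "alley_m", "row_spacing_m",
            "gsd_msi_m", "gsd_rgb_m",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.n_cols < 1 or self.n_rows < 1 or self.rows_per_plot < 1:
            raise ParameterError("n_cols, n_rows and rows_per_plot must be >= 1")

    @property
    def n_plots(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def field_width_m(self) -> float:
        return self.n_cols * self.plot_width_m + (self.n_cols - 1) * self.alley_m

    @property
    def field_height_m(self) -> float:
        return self.n_rows * self.plot_length_m + (self.n_rows - 1) * self.alley_m

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """Ground extent including the soil margin (min_x, min_y, max_x, max_y)."""
        m = self.margin_m
        return -m, -m, self.field_width_m + m, self.field_height_m + m


@dataclass
class PlotPolygon:
    """Axis-aligned rectangular plot footprint with identity."""

    plot_id: str
    family: str
    min_x: float
    min_y: float
    max_x: float
    max_y: float
    rows_per_plot: int = 6

    def __post_init__(self) -> None:
        if not (self.max_x > self.min_x and self.max_y > self.min_y):
            raise ParameterError(f"{self.plot_id}: degenerate polygon bounds")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.min_x, self.min_y, self.max_x, self.max_y

    @property
    def area(self) -> float:
        return (self.max_x - self.min_x) * (self.max_y - self.min_y)

    @property
    def center(self) -> tuple[float, float]:
        return (self.min_x + self.max_x) / 2, (self.min_y + self.max_y) / 2

    def as_shapely(self):
        return box(*self.bounds)

    def shrunk(self, margin: float) -> "PlotPolygon":
        """Symmetric border shrink to suppress edge effects."""
        return replace(
            self,
            min_x=self.min_x + margin, max_x=self.max_x - margin,
            min_y=self.min_y + margin, max_y=self.max_y - margin,
        )


def build_plot_polygons(
    spec: FieldSpec,
    families: list[str] | None = None,
    shrink_margin_m: float = 0.0,
) -> list[PlotPolygon]:
    """Build the plot grid, ordered top-right, row-major, to bottom-left.

    Families are assigned round-robin from ``families`` (all plots get
    family ``"F000"`` when none are given).  ``shrink_margin_m`` is
    applied symmetrically to every polygon after layout.
    """
    polys: list[PlotPolygon] = []
    pitch_x = spec.plot_width_m + spec.alley_m
    pitch_y = spec.plot_length_m + spec.alley_m
    k = 0
    for r in range(spec.n_rows):          # top to bottom
        max_y = spec.field_height_m - r * pitch_y
        for c in range(spec.n_cols):      # right to left
            max_x = spec.field_width_m - c * pitch_x
            family = families[k % len(families)] if families else "F000"
            poly = PlotPolygon(
                plot_id=f"P{r + 1:02d}_{c + 1:02d}",
                family=family,
                min_x=max_x - spec.plot_width_m,
                min_y=max_y - spec.plot_length_m,
                max_x=max_x,
                max_y=max_y,
                rows_per_plot=spec.rows_per_plot,
            )
            if shrink_margin_m:
                poly = poly.shrunk(shrink_margin_m)
            polys.append(poly)
            k += 1
    return polys


def clip_raster(raster: MultispectralRaster, poly: PlotPolygon) -> MultispectralRaster:
    """Sub-raster of the pixels whose centres fall inside the polygon.

    Pixel-centre-in with half-open bounds: a centre on the min edge is
    in, on the max edge is out, so adjacent plots never share a pixel.
    """
    xs, ys = raster.pixel_centers()
    jin = np.nonzero((xs >= poly.min_x) & (xs < poly.max_x))[0]
    iin = np.nonzero((ys >= poly.min_y) & (ys < poly.max_y))[0]
    if jin.size == 0 or iin.size == 0:
        raise EmptyClipError(f"{poly.plot_id}: polygon contains no pixel centres")
    return raster.window(iin[0], iin[-1] + 1, jin[0], jin[-1] + 1)


def raster_window(raster: MultispectralRaster, poly: PlotPolygon):
    """Pixel index bounds (i0, i1, j0, j1) of :func:`clip_raster`."""
    xs, ys = raster.pixel_centers()
    jin = np.nonzero((xs >= poly.min_x) & (xs < poly.max_x))[0]
    iin = np.nonzero((ys >= poly.min_y) & (ys < poly.max_y))[0]
    if jin.size == 0 or iin.size == 0:
        raise EmptyClipError(f"{poly.plot_id}: polygon contains no pixel centres")
    return iin[0], iin[-1] + 1, jin[0], jin[-1] + 1


def clip_cloud(cloud: PointCloud, poly: PlotPolygon) -> PointCloud:
    """Points with (x, y) inside the half-open ``[min, max)`` bounds."""
    return cloud.select(in_polygon_mask(cloud.xy, poly))


def in_polygon_mask(xy: np.ndarray, poly: PlotPolygon) -> np.ndarray:
    xy = np.atleast_2d(xy)
    return (
        (xy[:, 0] >= poly.min_x) & (xy[:, 0] < poly.max_x)
        & (xy[:, 1] >= poly.min_y) & (xy[:, 1] < poly.max_y)
    )


def in_any_plot_mask(spec: FieldSpec, xy: np.ndarray) -> np.ndarray:
    """Vectorised membership test against the *unshrunk* regular grid.

    Uses the layout arithmetic directly, so it is O(N) regardless of the
    number of plots; used to split ground from canopy points.
    """
    xy = np.atleast_2d(xy)
    pitch_x = spec.plot_width_m + spec.alley_m
    pitch_y = spec.plot_length_m + spec.alley_m
    x, y = xy[:, 0], xy[:, 1]
    in_field = (x >= 0) & (x < spec.field_width_m) & (y >= 0) & (y < spec.field_height_m)
    # offset within the (plot + alley) pitch; the alley sits above/right of
    # each plot except on the field border
    off_x = np.mod(x, pitch_x)
    off_y = np.mod(y, pitch_y)
    return in_field & (off_x < spec.plot_width_m) & (off_y < spec.plot_length_m)


# -- layout I/O ------------------------------------------------------------


def polygons_to_geojson(polys: list[PlotPolygon], path) -> None:
    features = []
    for p in polys:
        ring = [
            [p.min_x, p.min_y], [p.max_x, p.min_y],
            [p.max_x, p.max_y], [p.min_x, p.max_y], [p.min_x, p.min_y],
        ]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "plot_id": p.plot_id,
                    "family": p.family,
                    "rows_per_plot": p.rows_per_plot,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def polygons_from_geojson(path) -> list[PlotPolygon]:
    with open(path) as fh:
        fc = json.load(fh)
    polys = []
    for feat in fc["features"]:
        coords = np.asarray(feat["geometry"]["coordinates"][0])
        props = feat.get("properties", {})
        polys.append(
            PlotPolygon(
                plot_id=props.get("plot_id", f"plot{len(polys)}"),
                family=props.get("family", "F000"),
                min_x=float(coords[:, 0].min()),
                min_y=float(coords[:, 1].min()),
                max_x=float(coords[:, 0].max()),
                max_y=float(coords[:, 1].max()),
                rows_per_plot=int(props.get("rows_per_plot", 6)),
            )
        )
    return polys
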