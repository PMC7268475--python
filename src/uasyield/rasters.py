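"""Georeferenced multispectral raster container and GeoTIFF I/O.

The raster is a 4-band (G, R, RE, NIR) reflectance grid in percent,
georeferenced by a north-up affine: the world coordinate of the centre
of pixel ``(i, j)`` is ``(origin_x + (j + 0.5) * gsd,
origin_y - (i + 0.5) * gsd)``.  Coordinates are metres in a local
planar frame; a projected CRS (the field campaign used EPSG 32616) is
carried as metadata only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

BAND_NAMES = ("G", "R", "RE", "NIR")


@dataclass
class MultispectralRaster:
    """4-band reflectance grid in percent, with north-up georeferencing.

    Parameters
    ----------
    data : ndarray, shape (4, H, W)
        Band-major reflectance in percent.
    origin : (float, float)
        World (x, y) of the *top-left corner* of pixel (0, 0).
    gsd : float
        Ground sample distance, metres per pixel.
    """

    data: np.ndarray
    origin: tuple[float, float]
    gsd: float
    bands: tuple[str, ...] = BAND_NAMES
    crs: str = "local"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.bands):
            raise ValueError(
                f"expected ({len(self.bands)}, H, W) band-major array, "
                f"got {self.data.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(min_x, min_y, max_x, max_y) of the covered ground footprint."""
        h, w = self.shape
        ox, oy = self.origin
        return ox, oy - h * self.gsd, ox + w * self.gsd, oy

    def band(self, name: str) -> np.ndarray:
        return self.data[self.bands.index(name)]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """World coordinates of pixel centres as (x of columns, y of rows)."""
        h, w = self.shape
        ox, oy = self.origin
        xs = ox + (np.arange(w) + 0.5) * self.gsd
        ys = oy - (np.arange(h) + 0.5) * self.gsd
        return xs, ys

    def window(self, i0: int, i1: int, j0: int, j1: int) -> "MultispectralRaster":
        """Sub-raster over pixel rows [i0, i1) and columns [j0, j1)."""
        ox, oy = self.origin
        return MultispectralRaster(
            data=self.data[:, i0:i1, j0:j1],
            origin=(ox + j0 * self.gsd, oy - i0 * self.gsd),
            gsd=self.gsd,
            bands=self.bands,
            crs=self.crs,
        )

    # -- I/O ---------------------------------------------------------------

    def to_tiff(self, path) -> None:
        """Write as a band-major TIFF with georeferencing in the description."""
        meta = {
            "origin": list(self.origin),
            "gsd": self.gsd,
            "bands": list(self.bands),
            "crs": self.crs,
            "units": "percent reflectance",
        }
        tifffile.imwrite(
            path,
            self.data.astype(np.float32),
            description=json.dumps(meta),
            photometric="minisblack",
        )

    @classmethod
    def from_tiff(cls, path) -> "MultispectralRaster":
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            desc = tif.pages[0].tags.get("ImageDescription")
            meta = json.loads(desc.value) if desc is not None else {}
        return cls(
            data=np.asarray(data),
            origin=tuple(meta.get("origin", (0.0, 0.0))),
            gsd=float(meta.get("gsd", 1.0)),
            bands=tuple(meta.get("bands", BAND_NAMES)),
            crs=meta.get("crs", "local"),
        )
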