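"""Radiometric per-plot feature stage ("Triple S").

For each clipped plot raster: segment soybean canopy from soil by 1-D
k-means on the NIR band, compute Gaussian and robust statistics of the
canopy pixels per band, canopy cover, row count (Canny edge map) and
row length (PCA), and a set of eleven vegetation indices from the
per-band median reflectances.

Robust scale estimators
-----------------------
Reflectance samples within a plot are contaminated by mixed soil/canopy
pixels and shadows, so alongside the mean and standard deviation the
stage reports estimators that tolerate such departures from normality:

* ``NMAD = 1.4826 * MAD`` with ``MAD = median(|x_i - median(x)|)``; the
  1.4826 factor makes NMAD consistent with the standard deviation for
  Gaussian data.
* the square root of the biweight midvariance (BwMv), which smoothly
  downweights points more than 9 MAD from the median,

  ``BwMv = n * sum a_i (x_i - m)^2 (1 - U_i^2)^4
           / (sum a_i (1 - U_i^2)(1 - 5 U_i^2))^2``

  with ``U_i = (x_i - m) / (9 MAD)`` and ``a_i = 1`` iff ``|U_i| < 1``.
* interpercentile ranges at 50% (IQR), 90% (P95-P5) and 99%
  (P99.5-P0.5) confidence, plus the 2.5/25/75/97.5 percentiles.

All percentiles use linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from skimage.feature import canny
from skimage.filters import sobel, threshold_otsu

from uasyield.errors import (
    DegenerateClusteringError,
    NumericDomainError,
    SampleSizeError,
)
from uasyield.rasters import MultispectralRaster

NMAD_FACTOR = 1.4826

VI_NAMES = (
    "NDVI", "SAVI", "MSAVI", "GESAVI", "CIre", "CIg",
    "VARI", "RVI", "DVI", "RDVI", "TVI",
)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


@dataclass
class RobustStats:
    """Gaussian + robust statistics of one value sample (sample units)."""

    mean: float
    std: float
    median: float
    mad: float
    nmad: float
    bwmv_sqrt: float
    p2_5: float
    q25: float
    q75: float
    p97_5: float
    iqr: float
    ipr90: float
    ipr99: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def gaussian_stats(values) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise SampleSizeError("need at least 2 values")
    return float(x.mean()), float(x.std(ddof=1))


def biweight_midvariance(values) -> float:
    """Biweight midvariance about the sample median (9-MAD cutoff).

    Returns 0 for a zero-MAD sample, where every deviation from the
    median is itself median-zero and the estimator degenerates.
    """
    x = np.asarray(values, dtype=float).ravel()
    m = np.median(x)
    mad = np.median(np.abs(x - m))
    if mad == 0:
        return 0.0
    u = (x - m) / (9.0 * mad)
    a = np.abs(u) < 1.0
    num = x.size * np.sum(a * (x - m) ** 2 * (1 - u**2) ** 4)
    den = np.sum(a * (1 - u**2) * (1 - 5 * u**2)) ** 2
    if den == 0:
        return float("nan")
    return float(num / den)


def robust_stats(values) -> RobustStats:
    """Full Gaussian + robust statistics vector for a 1-D sample."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise SampleSizeError("need at least 2 values")
    mean, std = gaussian_stats(x)
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    p = np.percentile(x, [0.5, 2.5, 5, 25, 75, 95, 97.5, 99.5])
    p0_5, p2_5, p5, q25, q75, p95, p97_5, p99_5 = map(float, p)
    return RobustStats(
        mean=mean,
        std=std,
        median=med,
        mad=mad,
        nmad=NMAD_FACTOR * mad,
        bwmv_sqrt=float(np.sqrt(biweight_midvariance(x))),
        p2_5=p2_5,
        q25=q25,
        q75=q75,
        p97_5=p97_5,
        iqr=q75 - q25,
        ipr90=p95 - p5,
        ipr99=p99_5 - p0_5,
    )


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


class Segmentation(NamedTuple):
    mask: np.ndarray        # True where soybean canopy
    threshold: float        # midpoint between the two k-means centroids
    centroids: tuple[float, float]  # (soil, canopy)


def segment_vegetation(
    nir_band: np.ndarray,
    k: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
    min_separation: float = 4.0,
) -> Segmentation:
    """Classify pixels into canopy and soil by 1-D k-means on NIR.

    k is fixed at 2 (vegetation and ground).  Initialisation is
    deterministic at the 10th and 90th percentiles of the band, which
    removes seed sensitivity from this two-cluster 1-D problem; the
    cluster with the higher centroid is labelled soybean and the
    decision threshold is the centroid midpoint.

    A plot with no real canopy/soil contrast (e.g. bare soil) is
    rejected: the centroid separation must exceed ``min_separation``
    times the pooled within-cluster spread, otherwise k-means is just
    splitting unimodal noise.
    """
    if k != 2:
        raise NumericDomainError("segmentation is defined for k = 2")
    img = np.asarray(nir_band, dtype=float)
    flat = img.ravel()
    if flat.size == 0 or np.ptp(flat) == 0:
        raise DegenerateClusteringError("constant NIR band cannot be clustered")
    c_lo, c_hi = np.percentile(flat, [10, 90])
    if c_lo == c_hi:  # heavy ties; fall back to extrema
        c_lo, c_hi = float(flat.min()), float(flat.max())
    for _ in range(max_iter):
        mid = 0.5 * (c_lo + c_hi)
        lo = flat < mid
        if not lo.any() or lo.all():
            raise DegenerateClusteringError("one k-means cluster is empty")
        new_lo, new_hi = flat[lo].mean(), flat[~lo].mean()
        shift = max(abs(new_lo - c_lo), abs(new_hi - c_hi))
        c_lo, c_hi = new_lo, new_hi
        if shift < tol:
            break
    threshold = 0.5 * (c_lo + c_hi)
    lo = flat < threshold
    pooled = np.sqrt((np.var(flat[lo]) * lo.sum() + np.var(flat[~lo]) * (~lo).sum()) / flat.size)
    if pooled > 0 and (c_hi - c_lo) < min_separation * pooled:
        raise DegenerateClusteringError(
            "no canopy/soil bimodality: centroid separation "
            f"{c_hi - c_lo:.3g} below {min_separation} x within-cluster spread"
        )
    return Segmentation(
        mask=img >= threshold,
        threshold=float(threshold),
        centroids=(float(c_lo), float(c_hi)),
    )


def canopy_cover(mask: np.ndarray, gsd_m: float) -> tuple[float, float]:
    """Canopy area (m^2) and cover percentage from a canopy mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise SampleSizeError("empty mask")
    count = int(mask.sum())
    return count * gsd_m**2, 100.0 * count / mask.size


# ---------------------------------------------------------------------------
# row geometry
# ---------------------------------------------------------------------------


def count_rows(
    nir_band: np.ndarray,
    completeness: float = 0.9,
    sigma: float = 1.0,
) -> int:
    """Count complete crop rows from a Canny edge map of the NIR band.

    Crop rows run along the image's vertical (y) axis.  Edge responses
    are projected across the row direction onto the x axis; a column
    whose edge support spans at least ``completeness`` of the plot
    length marks one side of a complete row, and each row contributes
    two such boundary edges.  Canny thresholds: high = Otsu threshold
    of the gradient magnitude, low = high / 2.
    """
    img = np.asarray(nir_band, dtype=float)
    if img.size == 0 or np.ptp(img) == 0:
        return 0
    grad = sobel(img)
    if np.ptp(grad) == 0:
        return 0
    high = threshold_otsu(grad)
    edges = canny(img, sigma=sigma, low_threshold=high / 2, high_threshold=high)
    support = edges.sum(axis=0)
    # an edge localises to 1-2 adjacent columns; merge contiguous non-zero
    # columns into one candidate boundary and pool their support
    nonzero = support > 0
    padded = np.concatenate(([False], nonzero, [False]))
    starts = np.nonzero(~padded[:-1] & padded[1:])[0]
    ends = np.nonzero(padded[:-1] & ~padded[1:])[0]
    n_edges = 0
    for s, e in zip(starts, ends):
        if support[s:e].sum() >= completeness * img.shape[0]:
            n_edges += 1
    return n_edges // 2


def row_length(mask: np.ndarray, gsd_m: float) -> float:
    """Row length: projected extent of canopy pixels on the first
    principal axis of their coordinates, scaled by the GSD."""
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask).astype(float)
    if coords.shape[0] < 2:
        raise SampleSizeError("need at least 2 canopy pixels")
    centred = coords - coords.mean(axis=0)
    cov = centred.T @ centred / (coords.shape[0] - 1)
    _, vecs = np.linalg.eigh(cov)
    proj = centred @ vecs[:, -1]  # first eigenvector = largest eigenvalue
    return float(proj.max() - proj.min()) * gsd_m


# ---------------------------------------------------------------------------
# vegetation indices
# ---------------------------------------------------------------------------


@dataclass
class VIParams:
    """Soil-adjustment parameters for SAVI/GESAVI plus formula variants.

    ``L`` and ``z`` are defined on the 0-1 reflectance scale.  The
    as-printed flags restore subtractive/product variants of CIg,
    MSAVI and GESAVI that circulate in the applied literature; the
    defaults use the canonical ratio/soil-line forms.
    """

    L: float = 0.5
    a: float = 1.0
    b: float = 0.0
    z: float = 0.35
    cig_as_printed: bool = False
    msavi_as_printed: bool = False
    gesavi_as_printed: bool = False

    def __post_init__(self) -> None:
        if self.L < 0:
            raise NumericDomainError("SAVI L must be >= 0")


def compute_vis(medians: dict[str, float], params: VIParams | None = None) -> dict[str, float]:
    """Eleven vegetation indices from per-band median reflectance (percent).

    Band medians arrive in percent (as tabulated); they are converted to
    the 0-1 reflectance scale internally so that the additive constants
    in SAVI, MSAVI and GESAVI keep their literature meaning.  Ratio
    indices are unaffected by the scale.
    """
    params = params or VIParams()
    if any(medians[b] <= 0 for b in ("G", "R", "RE", "NIR")):
        raise NumericDomainError("band medians must be positive")
    g, r, re_, nir = (medians[b] / 100.0 for b in ("G", "R", "RE", "NIR"))
    if nir + r == 0 or g + r == 0 or r + params.z == 0:
        raise NumericDomainError("zero denominator in vegetation index")

    msavi_term = (2 * nir + 1) ** 2 - 8 * ((nir - r) ** 2 if params.msavi_as_printed else (nir - r))
    if msavi_term < 0:
        raise NumericDomainError("negative MSAVI discriminant")
    if params.gesavi_as_printed:
        gesavi = (nir - params.a) * (r - params.b) / (r + params.z)
    else:
        gesavi = (nir - params.a * r - params.b) / (r + params.z)
    return {
        "NDVI": (nir - r) / (nir + r),
        "SAVI": (1 + params.L) * (nir - r) / (nir + r + params.L),
        "MSAVI": (2 * nir + 1 - np.sqrt(msavi_term)) / 2,
        "GESAVI": gesavi,
        "CIre": nir / re_ - 1,
        "CIg": ((nir - g) - 1) if params.cig_as_printed else (nir / g - 1),
        "VARI": (g - r) / (g + r),
        "RVI": nir / r,
        "DVI": nir - r,
        "RDVI": (nir - r) / np.sqrt(nir + r),
        "TVI": 0.5 * (120 * (nir - g) - 200 * (r - g)),
    }


# ---------------------------------------------------------------------------
# per-plot orchestration
# ---------------------------------------------------------------------------


@dataclass
class RadiometricFeatures:
    """One spreadsheet row of radiometric features for a plot."""

    plot_id: str
    canopy_cover_pct: float
    canopy_cover_m2: float
    band_stats: dict[str, RobustStats]
    n_rows: int
    row_length_m: float
    vi: dict[str, float]

    def model_row(self) -> dict[str, float]:
        """The per-date model feature columns (1 cover + 12 band stats + 11 VIs).

        Row length is computed but excluded from the model features:
        it shows too little variation between plots to be informative.
        """
        row: dict[str, float] = {"CC_pct": self.canopy_cover_pct}
        for band in ("G", "R", "RE", "NIR"):
            st = self.band_stats[band]
            row[f"{band}_mean"] = st.mean
            row[f"{band}_median"] = st.median
            row[f"{band}_std"] = st.std
        row.update(self.vi)
        return row


#: number of model feature columns emitted per date
N_MSI_FEATURES_PER_DATE = 1 + 12 + len(VI_NAMES)


def msi_feature_columns() -> list[str]:
    cols = ["CC_pct"]
    for band in ("G", "R", "RE", "NIR"):
        cols += [f"{band}_mean", f"{band}_median", f"{band}_std"]
    return cols + list(VI_NAMES)


def plot_radiometric_features(
    plot_raster: MultispectralRaster,
    params: VIParams | None = None,
    plot_id: str = "",
) -> RadiometricFeatures:
    """Run the full radiometric stage on one clipped plot raster."""
    try:
        seg = segment_vegetation(plot_raster.band("NIR"))
        area_m2, pct = canopy_cover(seg.mask, plot_raster.gsd)
        stats = {
            b: robust_stats(plot_raster.band(b)[seg.mask])
            for b in plot_raster.bands
        }
        medians = {b: stats[b].median for b in plot_raster.bands}
        vi = compute_vis(medians, params)
        nrows = count_rows(plot_raster.band("NIR"))
        length = (
            row_length(seg.mask, plot_raster.gsd) if seg.mask.sum() >= 2 else 0.0
        )
    except Exception as exc:
        exc.args = (f"plot {plot_id}: {exc}",) if plot_id else exc.args
        raise
    return RadiometricFeatures(
        plot_id=plot_id,
        canopy_cover_pct=pct,
        canopy_cover_m2=area_m2,
        band_stats=stats,
        n_rows=nrows,
        row_length_m=length,
        vi=vi,
    )
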