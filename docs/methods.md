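# Methods

This note documents the models, parameter choices and numerical
conventions behind `uasyield`, and what the synthetic study does and
does not establish about real flight data.

## The measurement model

A breeding trial is an axis-aligned grid of rectangular plots separated
by alleys; crop rows run along the plot length, spaced 0.76 m apart
(6 or 8 rows per plot). Two sensors observe it:

* a 4-band multispectral camera producing a reflectance orthomosaic in
  percent (bands G, R, RE, NIR) at ~5.1 cm ground sample distance;
* an RGB photogrammetric reconstruction producing dense point clouds
  (>100 points/m²) — a pre-emergence terrain reference and one cloud
  per study date.

Ground truth is destructive per-plot grain yield in kg/ha.

## Radiometric stage

**Segmentation.** Canopy and soil are separated by 1-D k-means (k = 2)
on the NIR band, where the two end-members differ most. Initialisation
is deterministic at the 10th/90th percentiles — a 1-D two-cluster
problem has no seed sensitivity worth keeping — and the decision
threshold is the centroid midpoint. A plot whose centroid separation is
below 4× the pooled within-cluster spread (e.g. bare soil) is rejected
as degenerate rather than silently split.

**Statistics.** Mixed pixels and shadows make reflectance samples
heavy-tailed, so alongside mean/SD each band is summarised by robust
estimators: median, NMAD = 1.4826 · MAD (Gaussian-consistent),
the square root of the biweight midvariance (9-MAD cutoff), and
interpercentile ranges at 50/90/99% confidence plus the
2.5/25/75/97.5 percentiles. Percentiles use linear interpolation
between order statistics; a zero-MAD sample has all robust dispersions
defined as 0.

**Row geometry.** The row count comes from a Canny edge map of the NIR
band (high threshold = Otsu of the gradient magnitude, low = half of
it), projected across the row direction; contiguous non-zero columns
are pooled into one candidate boundary and boundaries supported over at
least 90% of the plot length count, two per complete row. Row length is
the projected extent of canopy pixels on their first principal axis
times the GSD (a projected range, not a pixel count — the two coincide
for a solid row). Both are computed per plot but excluded from the
model features: row length varies too little between plots to inform
the model, and row count is a design constant within a size class.

**Vegetation indices.** Eleven indices are computed from the per-band
median reflectances. Medians arrive in percent but are converted to the
0–1 scale internally: the additive constants in SAVI (L = 0.5), GESAVI
(z = 0.35) and MSAVI's "+1" are defined on that scale, and MSAVI's
discriminant is negative on the percent scale. Ratio indices are scale
free. Three formula variants that circulate in the applied literature
are exposed as flags but default to the canonical forms:
CIg = NIR/G − 1 (flag restores the subtractive (NIR−G)−1),
MSAVI with 8(NIR−R) under the root (flag squares it), and
GESAVI = (NIR − aR − b)/(R + z) with soil-line defaults a = 1, b = 0
(flag restores a product form). VARI is implemented exactly as
(G−R)/(G+R); the sensor has no blue band.

## Geometric stage

**Outlier filtering.** Each point's mean distance to its k = 8 nearest
neighbours is modelled as Gaussian across the cloud; points beyond
mean + 2 SD are dropped. Removing more than 5% raises a data-quality
warning rather than failing: dense photogrammetric clouds should not
lose more than a few percent.

**Registration.** Registration is rigid (rotation + translation), not
affine: terrain differencing requires scale preservation, and scale is
already fixed by the surveyed control points. A coarse alignment from
tie points known in both frames is refined by point-to-point ICP on
ground points only (vegetation has no stable counterpart between
dates), iterating to an RMS change below 1e-6 m or 50 iterations.
Clouds above 20k points are subsampled evenly for the iteration. On
independently sampled clouds of the same terrain the recovered
transform is good to ~5 mm and well under 0.1° of yaw — the residual
floor is the mean point spacing, not the estimator; on resampled
copies recovery is exact to 1e-3 m.

**Height deviation.** For each canopy point a 6-coefficient quadric
z(x, y) is fit to its k = 12 nearest terrain points (≥6 needed for the
fit, doubled against noise) in a locally centred frame, and the height
is the point's z minus the quadric, clamped at a minimum height of
0 m. Degenerate neighbourhoods fall back to the neighbours' mean
elevation and are flagged. The terrain surface in the generator is a
gentle quadric, deliberately non-planar so this local model is
exercised non-trivially.

**Bar calibration.** Heights are calibrated against 5 fixed bars of
surveyed height: the estimate at a bar is the mean deviation height of
the bar's return cluster (points within 0.1 m in plan, above half the
local maximum — ground returns around the base would drag the mean
down), and a constant offset mean(measured − estimated) is applied.
The post-calibration mean absolute bar residual must stay below 2.5 cm,
the scale at which such field checks are typically reported. Note that
registration absorbs any whole-cloud vertical bias; what calibration
corrects is the reconstruction bias of elevated surfaces, and the
generator injects exactly that kind of bias.

**Canopy volume.** Per-plot heights are Delaunay-triangulated in plan
view, Laplacian-smoothed (one pass, λ = 0.5) to damp photogrammetric
noise, and integrated as prisms over a 0.45 m grid covering the plot —
a trade-off between spatial resolution and cost. Each cell's height is
the mean of the surface at 3×3 points within the cell; edge cells are
clipped to the footprint so cell areas sum exactly to the plot area;
cells outside the triangulation's convex hull are filled from the
nearest height (a planar hole-filling equivalent). Volume integrates
*above the terrain* (consistent with the deviation cloud), not above
the plot's minimum height. Uniform-height fields reproduce the analytic
prism volume exactly; curved surfaces agree with a fine-grid Riemann
sum to a few percent, and the estimate is rotation-invariant to ~2%.

**Features.** Per plot and per source — the two dates plus an
"increment" field of per-point height differences (late-date support,
nearest-neighbour pairing within 10 cm, clamped at 0) — the model
receives canopy volume (dm³), maximum height (cm), and the within-plot
variation percentages of cell volume and cell maximum height
(100 · SD/mean over grid cells): 4 features × 3 sources = 12. Mean and
SD of height are computed and reported as auxiliaries but kept out of
the default schema to preserve the 60-column contract.

## Yield model

The fused table has 60 features: 2 dates × (1 canopy cover + 12 band
statistics + 11 indices) = 48 multispectral, plus the 12 geometric.
The split is a uniform random 15% test fraction (round-half-even on
n × 0.15; 840 plots give 714/126) with a fixed integer seed recorded in
all outputs; no stratification by family or block. Both regressors use
1000 trees and depth 5 — depth 5 applied to the boosting model too,
although its library default is 6, to curb complexity uniformly — and
boosting uses learning rate 0.06 and subsample 0.8. No hyperparameter
search is performed; these are protocol constants, not tuned values.

The headline "accuracy" statistic is 100 minus the mean percent
deviation with the *predicted* value in the denominator and *signed*
deviations, so opposite-sign errors cancel and the statistic is not
bounded by 100; because that cancellation makes it easy to over-read,
the absolute-deviation variant is always computed alongside and both
appear in reports. Feature importances are normalised to sum to 1, and
the importance report flags the minimal prefix of the ranking that
carries a given cumulative share (default 71%). Ablations refit the
same split on feature subsets (RGB-only, MSI-only, per-date) and report
the percent change in test MAE against the full model.

## Evaluation

Error metrics are MBE, AMBE, RMSE, the NMAD of residuals, signed and
absolute mean percent errors (actual-value denominator), and the
Nash–Sutcliffe index η. η defaults to the standard form with
Σ(actual − mean actual)² in the denominator — the form for which a
perfect prediction gives exactly 1 — with the variant that deviates
about the predictions available behind a flag; both are reported in
the evaluation outputs and neither is asserted against the other.

The predicted-vs-measured scatter is fit by iteratively reweighted
least squares with Tukey bisquare weights (tuning constant 4.685 for
95% Gaussian efficiency, scale re-estimated each iteration as the NMAD
of residuals, 50 iterations, tol 1e-8). Outliers are flagged from the
externally studentized residuals — residual over its leave-one-out
standard error, using the closed-form leave-one-out residual mean
square and the straight-line hat leverages — against the two-tailed t
quantile with n − p − 1 degrees of freedom at α = 0.05. This is a
*per-point* test: on clean data it flags ≈5% of points by
construction, which matches how such outlier counts are reported in
practice; it is not a family-wise test. R² is reported after outlier
removal. The robust-normality check is the MAD-scaled Jarque–Bera
variant, J = sqrt(π/2) · mean|x − median| with skewness/kurtosis terms
weighted 1/6 and 1/64 against a χ²(2) critical value; the exact
constants are a documented choice among the robust-JB family.

Family-grouped errors average the absolute percent error over test
plots per family, restricted to families with 4–6 test plots.

## The synthetic study

The generator emulates: row-striped vegetation/soil reflectance with
band medians near (G 6.2, R 2.5, RE 32, NIR 55)% for vegetation and
soil NIR at 15% (≥10σ separation at the default σ = 1 noise, so
segmentation has a well-defined optimum); per-plot latent traits —
canopy cover (mean 0.82, SD 0.08), per-date heights (0.578 m and
+0.22 m increment), and a chlorophyll scalar (mean 1, SD 0.15) that
moves NIR up and G down by 30% per unit, driving the CIg contrast;
terrain as a gentle quadric sampled at 100 points/m² with 1 cm z-noise;
known rigid perturbations, 1% gross z-outliers, five calibration bars;
and yields = −2103 + 3000·cc + 2800·height + 1500·chl + N(0, 630),
floored at 100, giving marginal mean ≈ 3783 kg/ha and SD ≈ 770 kg/ha —
the scale of a real soybean trial. Stripe pixel counts are exact
(round(cc · plot pixels)), so measured cover equals the latent trait to
one pixel. The within-plot height variation (15% CV) is a free
parameter: real canopy roughness is not something the source protocol
pins down.

What it does **not** emulate: the imaging process itself (no camera
model, bundle adjustment, BRDF, atmosphere or irradiance drift), weed
or lodging patches, phenology dynamics, spatial field trends in
fertility, or genotype structure beyond round-robin family labels.
Passing tests therefore demonstrate that the *algorithms* recover known
structure under realistic noise scales — not that the feature set
predicts yield in a particular real field, which depends on agronomy
the generator deliberately leaves out.

Default problem sizes: unit tests run fields of 4–12 plots; the
end-to-end recovery study uses a 42 × 20 = 840-plot field with
noise-free yields, where both models reach a held-out absolute error
below 5% and ablating the multispectral features (which carry two of
the three latent traits) costs more accuracy than ablating the
geometric ones.

## Known limitations

* Plot polygons are axis-aligned; rotated or hand-digitised layouts are
  out of scope.
* Point clipping uses half-open [min, max) bounds and raster clipping
  the pixel-centre-in rule — adjacent plots partition space exactly,
  at the cost of a one-sided boundary convention.
* The increment field is defined on the late date's support; growth in
  regions the late flight did not sample is invisible.
* ICP assumes enough stable ground (alleys, margins) is visible on the
  study dates.
* The per-point outlier test over-flags slightly under non-Gaussian
  residuals; the bisquare fit already limits their influence on the
  reported line.
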