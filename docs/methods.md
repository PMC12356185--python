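# Methods

## Model

The package implements the classic light-use-efficiency decomposition of gross
primary productivity: GPP = PAR × fAPAR × ε_LUE, with the effective efficiency
ε_LUE = ε_LUEmax × T_scalar × W_scalar. Its assumptions are the standard ones
of the LUE/VPM model family: carbon fixation is linear in absorbed
photosynthetically active radiation; the absorbed fraction is an affine
function of NDVI; temperature and canopy water status act as independent
multiplicative down-regulations; and the biome-specific maximum efficiency
ε_LUEmax is constant in space and time within a biome.

All pixel arithmetic is float64 with NaN as nodata; integer quantization
happens only at GPP output.

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| NDVI_min / NDVI_max | 0.03 / 0.96 | – | endpoints of the fAPAR stretch (2%/98% of the global NDVI distribution) |
| fAPAR_min / fAPAR_max | 0.001 / 0.95 | – | theoretical fAPAR bounds for all vegetation |
| T_min / T_opt / T_max | 0.0 / 20.3 / 48.0 | °C | quadratic temperature response of photosynthesis |
| LSWI_max window | calendar year | – | normalization window of the water scalar |
| ε_LUEmax | per-biome table; GRA 0.860 | gC m⁻²d⁻¹MJ⁻¹ | maximum conversion efficiency |
| storage step | 0.1 | gC m⁻²d⁻¹ | integer quantization step |
| footprint radius | 250 | m | tower/model comparison disc |
| gap-fill screen | 0.20 | – | maximum gap-filled share of a tower record |
| DT/NT gap | 3 | gC m⁻²d⁻¹ | daily partitioning-disagreement discard threshold |

### Numerical and boundary choices

- **T_scalar outside (T_min, T_max).** The response is set to 0 exactly at or
  below 0 °C. Behavior above T_max is not fixed by the formula's rationale;
  the raw quadratic is 0 at T_max and we extend it continuously by 0 beyond.
  Any negative in-range value is clamped to 0, and the scalar is capped at 1.
- **W_scalar form.** The default is 1 − (1 − LSWI)/(1 + LSWI_max). The more
  common VPM variant (1 + LSWI)/(1 + LSWI_max) is available via
  `formula="vpm"` for sensitivity analysis. Pixels with 1 + LSWI_max ≤ 0 are
  nodata.
- **LSWI_max window.** "Maximum LSWI per pixel" needs a window to be
  executable: a single bimonthly composite has exactly one LSWI per pixel,
  under which the water scalar degenerates to a function of LSWI alone. The
  default window is the calendar year (the VPM convention); `"bimonthly"` and
  `"full-series"` are selectable.
- **fAPAR clamping.** NDVI outside [0.03, 0.96] maps to the corresponding
  fAPAR bound; the bounds are theoretical limits, so extrapolation beyond them
  has no physical meaning. Negative reflectances are accepted (normalized
  products can produce them); only zero normalized-difference denominators
  yield nodata.
- **Quantization.** Stored values are round-half-even of value/0.1 in uint16
  with nodata 65535 (max representable 6553.4 gC m⁻²d⁻¹, far above physical
  GPP). Negative GPP (possible only via degenerate inputs) is clamped to 0
  with a logged count. Round-half-even is unbiased at step boundaries and
  makes tests bit-exact.
- **Calibration is metadata-only.** Grassland calibration masks pixels and
  multiplies the metadata scale by ε_LUEmax(GRA): stored integers are copied
  bit-for-bit. This preserves the re-calibratability of the uncalibrated
  product: any user can substitute their own land-cover map and ε table.
- **Annualization** uses the mean over *valid* periods × 365 rather than
  requiring all six periods, because winter data gaps (polar night, snow)
  would otherwise empty high-latitude pixels; the per-pixel coverage counts
  are logged.
- **Compositing weights.** Scenes are merged per bimonthly period with weight
  1 − cloud_cover, renormalized over the scenes where each pixel is clear
  (clearer scenes weigh more; weighting toward cloudier scenes would be
  nonsensical). If all contributing scenes carry zero weight the composite
  falls back to the unweighted mean with a warning.
- **Driver bucketing.** An 8-day LST composite is assigned its window
  midpoint, a monthly PAR raster its month midpoint; membership in a bimonthly
  period tests that midpoint against the half-open [start, end) interval.
  This is order-independent and unambiguous.
- **Downscaling** interpolates coarse cell-center values with a bicubic
  spline (degree lowered automatically below four cells per axis; a single
  cell becomes a constant fill). Nodata cells are pre-filled from the nearest
  valid cell, since a rectilinear spline cannot skip knots. Evaluation
  coordinates are clamped to the coarse-center hull — nearest extension at
  edges, no extrapolated overshoot — and residual negative PAR is clamped to
  0 with a log count.
- **Gap-filling hook.** Full time-series reconstruction is out of scope; the
  shipped default fills a missing pixel-period from the most recent valid
  same-bimonth value of an *earlier* year only (causal), leaving untried gaps
  as nodata. Any stronger algorithm can be plugged in behind the same
  signature.
- **Tiling** partitions pixels by the tile containing each pixel center
  (1° × 1° in production coordinates; arbitrary size in tests); mosaicking is
  a disjoint paste that refuses overlapping writes and round-trips bit-exactly.
- **Validation conventions.** Gap-fill screening applies to the full record
  ("≤ 20%", boundary inclusive); the DT/NT discard is strict ("more than 3");
  the even-count median is the midpoint of the central pair; footprint
  membership is pixel-center-in-circle (a brute-force enumeration oracle in
  the tests pins this down; area-weighting partial pixels would suggest more
  precision than an empirically chosen radius supports); R² is the squared
  Pearson correlation, with 1 − SSres/SStot about the 1:1 line available as a
  labeled alternative; bias is model − observed; a (model, observed) pair
  exists only when both sides are present for a period.

## GeoTIFF I/O

Rasters are written through tifffile with standard GeoTIFF georeferencing tags
(ModelPixelScale, ModelTiepoint, GeoKeyDirectory) plus the GDAL_NODATA and
GDAL_METADATA tags carrying the nodata sentinel, `scale_factor` and `units`,
so GDAL, QGIS and rasterio read the products with correct geolocation, masking
and scaling. One projected CRS per scene is assumed throughout; reprojection
is out of scope.

## Synthetic data

The generators reproduce the statistical *structure* the pipeline depends on,
not sensor physics:

- **Reflectance**: per-pixel NDVI follows a sinusoidal seasonal cycle
  (hemisphere-dependent phase, peak mid-July north / mid-January south) around
  spatially autocorrelated mid and amplitude fields, spanning roughly
  NDVI 0.05–0.9 at defaults; red is a flat 0.05 baseline, NIR is solved from
  the target NDVI, SWIR1 from a target LSWI that co-varies with greenness
  (LSWI ≈ 0.5 × NDVI). Four 16-day scenes per bimonthly period; additive
  Gaussian band noise (`noise_sd`, default 0 — enabled per experiment);
  Bernoulli cloud gaps at `cloud_gap_fraction` with the realized cloudy share
  recorded per scene as its cloud_cover, which is what the compositing weights
  act on.
- **Climate**: smooth coarse-grid fields (default 240 m at coarse_factor 8,
  standing in for the km-scale native products) with seasonal sinusoids —
  LST mean 12 °C, amplitude 15 °C (winter minima below 0 °C, a mid-latitude
  pattern), PAR mean 8, amplitude 4 MJ m⁻²d⁻¹, clipped at 0 — on the native
  8-day / monthly cadences. Constant-field options exist to force
  T_scalar = 1 in recovery tests.
- **Masks**: thresholded smooth Gaussian fields, so patches are spatially
  autocorrelated and the areal share equals the requested fraction to within
  a pixel count.
- **Towers**: daily truth plus independent N(0, σ²) DT and NT noise, an exact
  count of gap-filled flags, and an optional exact count of injected
  |DT − NT| > 3 days (with the remaining days clipped inside the gap so that
  count is deterministic). The known-answer truth is the forward model's own
  250 m footprint mean, converted by the site's biome factor — a tower
  measures actual GPP, so this is the quantity the protocol compares.

Everything is driven by `numpy.random.default_rng(seed)`: identical configs
give bit-identical outputs.

**What the synthetic tests show — and do not.** Passing the recovery and
known-answer suites demonstrates that the arithmetic chain (indices, scalars,
compositing, quantization, footprint extraction, statistics) is internally
consistent and self-inverting under the stated conventions. It says nothing
about how well the LUE model describes real canopies: real reflectance has
sensor noise structure, topographic and BRDF effects, and gap patterns the
generator does not emulate, and real tower GPP embeds partitioning
uncertainty. Published-scale accuracy against real towers cannot be inferred
from these tests.

## Problem sizes

Tests and the acceptance script run on desk-scale scenes chosen as the
smallest sizes that exercise every code path: 24–48 px grids (0.7–1.4 km at
30 m), one to three years, up to twelve towers (≥ 200 matched bimonthly pairs
for the noise-recovery check), and a 0.01 °C grid (4,801 points) for the
temperature-scalar search. All generators scale to arbitrarily larger grids
and year ranges with linear cost.

## Known limitations

- No reprojection: all inputs must share one projected CRS and grid origin.
- The causal same-season gap fill is a placeholder contract, far weaker than a
  full seasonal-weighted reconstruction.
- The water scalar inherits the printed formula's behavior at extreme LSWI;
  no VPD-based alternative is provided.
- Tower ingestion assumes daily DT/NT columns with a binary gap-fill flag;
  upstream partitioning and u*-threshold handling are consumed, not modeled.
- ε_LUEmax is a per-biome constant; per-pixel efficiency maps and tower
  re-optimization are out of scope.
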