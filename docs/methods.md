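# Methods

This note documents the models, parameter choices and numerical
decisions behind `canopytrait`, and what the synthetic-data tests do
and do not establish about real field data.

## Sensors and data model

Two band sets are built in. The "uav" set has 47 bands, 450–910 nm at
10 nm spacing with 10 nm FWHM, standing for a pushbroom imaging
spectrometer flown at 80 m (≈0.2 m pixels). The "ground" set has 11
bands (490, 530, 550, 570, 670, 700, 710, 740, 750, 780, 870 nm),
standing for a handheld radiometer read 1 m above the canopy with a 28°
field of view (0.5 m footprint, 0.20 m²). Reflectance is stored as a
fraction; values above 1 are tolerated but flagged. Missing values are
`nan` and excluded from all means. Rasters are row-major, top-left
origin, pixel-center coordinates — stated explicitly because nothing
downstream works without a convention.

Bands are resolved by nearest center within a 10 nm tolerance, ties to
the shorter wavelength; there is no spectral-response convolution. The
index library carries separate nominal centers per sensor (e.g. NDVI
uses 800 nm on the UAV set but 780 nm on the ground set, which has no
800 nm band; MTCI uses 670/710/750 on the ground set and 680/710/755 on
the UAV set). Two printed-source ambiguities were resolved toward the
formulas: CI_g is R780/R550 − 1 (the green-band replacement of CI_re),
and MCARI2 carries the square roots of its original definition in the
stabilizing denominator. The Bhattacharyya coefficient is implemented
with the radical, BC = ∫√(t₁t₂)dx, because only that form is bounded by
1 as its use as an overlap measure requires.

## Hemispherical-photograph inversion

Segmentation uses excess green (2G − R − B) with an Otsu threshold — a
deliberate simplification of published color-transform optimizations;
it is adequate for the high-contrast synthetic imagery and replaceable
behind `classify_vegetation`. The fisheye projection is ideal
equidistant (zenith ∝ radius), with the image circle mapping to the
sampled 0–37.5° range; lens calibration is out of scope.

The angular grid is fixed at 15 × 2.5° zenith rings and 72 × 5° azimuth
cells. Clumping per ring is the Lang–Xiang log-gap-average ratio,
count-weighted over the cells of all photos of a plot. Saturated
(fully vegetated) cells are replaced by the model gap of an LAI = 10
canopy at the candidate *effective* leaf inclination; in practice all
gaps are clipped to [P_sat, 1] so ln 0 never occurs.

The LUT spans LAI 0–10 step 0.01, ALA 10–80° step 2°, effective ALA
likewise (1001 × 36 × 36 triples). The cited cost function is not
printed in the source literature, so the package defines it as the
count-weighted root-mean-square difference between measured and
modeled ring gap fractions, with deterministic tie-breaking toward the
lowest LAI, then ALA, then effective ALA. The per-ring Ω(θᵢ) profile
(not a scalar) enters the forward model, matching the θ-indexed
estimator. The χ↔ALA link uses the standard ellipsoidal
approximations G(θ,χ) = cosθ·√(χ²+tan²θ)/(χ+1.774(χ+1.182)^(−0.733))
and ALA_rad = 9.65(3+χ)^(−1.65); at χ = 1 the G function is within
10⁻³ of 0.5 at all angles, and the χ↔ALA relation is accurate to about
a degree near the spherical value (the tests allow that).

Retrieved "LAI" is a plant area index: optical inversion cannot
separate leaves from stems, and no azimuthal-anisotropy correction is
applied. Ground cover is 1 minus the count-weighted mean raw gap over
the rings fully inside 0–20°.

## Synthetic campaign

The generator's defaults are the study conditions, not tuning knobs: 3
blocks × 2 treatments ("non-mixed" resistant monoculture vs "mixed"
variety mixture) × 2 replicates = 12 plots, observed at 43, 62, 75, 84
and 99 days after planting. Expected leaf chlorophyll declines
linearly 48 → 30 µg·cm⁻² over the season; LAI interpolates control
points (1.2, 3.0, 3.5, 3.4, 2.6 m²·m⁻²) peaking mid-season; on the
final date the mixed treatment loses an extra 0.8 m²·m⁻² of LAI and
4 µg·cm⁻² of chlorophyll, emulating late-blight impact. Noise:
plot-level random effects at half the residual sd, residual sds of 2.0
µg·cm⁻² (chlorophyll), 0.20 (LAI), 0.02 (ground cover). Ground cover
before noise is 1 − exp(−0.5·LAI); canopy chlorophyll is computed
exactly from the noisy leaf chlorophyll and LAI (×0.01 for units).

The spectral forward model is a parametric stand-in for
radiative-transfer simulation, chosen to keep the package desk-scale:
a chlorophyll-controlled visible trough (Beer-type, floor 0.03,
amplitude 0.25, rate 0.045 per µg·cm⁻²) with a Gaussian green bump at
550 nm, a logistic red edge at 720 nm (width 12 nm), and an NIR plateau
0.28 + 0.20(1 − e^(−0.6·LAI)). Observations are linear
vegetation/soil mixtures: UAV pixels use f_veg = ground cover; the
ground radiometer's four footprints use f_veg = min(1, cover ×
row_concentration) with row_concentration 1.6, carrying the study's
sampling contrast (row-centered readings see more vegetation at
incomplete cover). The soil endmember brightens linearly toward the
NIR (0.10 at 450 nm, slope 2.5·10⁻⁴ per nm), giving a soil-line ratio
C ≈ 1.3. Spectral noise sd is 0.01. The model reproduces rank and
shape behaviors (trough deepening, red-edge shift, NIR saturation,
sensor contrast), not absolute reflectance magnitudes — so passing
tests demonstrate the statistical machinery, not radiometric fidelity
on real canopies.

Gap fields are built ring by ring: the ring mean follows the clumped
Poisson model, and heterogeneity is a two-density cell mixture (a
solved fraction of wide-open cells against a denser remainder, found
by bisection) calibrated so the Lang–Xiang estimator returns the target
Ω exactly on the noise-free field. Cell counts are uniform (200
pixels/cell, 4 photos). The parameter-recovery study draws LAI on the
LUT's 0.01 grid so that the noise-free forward field is exactly
representable — the appropriate oracle for the search machinery; real
measurements add discretization error of at most half a grid step.

The strip mosaic places 3 × 10 m plots (value 0.6) in a row with 5 m
soil buffers (value 0.1) at 0.2 m pixels, plus Gaussian noise (sd
0.02).

## Plot extraction

Canny edge detection runs per horizontal image segment (4 segments
along the strip axis) with absolute hysteresis thresholds: high = mean
gradient magnitude of the segment, low = 40 % of it, Gaussian sigma
0.5. The threshold statistic is computed with the same
Gaussian-then-Sobel gradient the detector uses internally, so the mean
is on the detector's own scale. Across-track plot sides snap to the
best-supported boundary between adjacent pixel columns (a thinned step
edge lands on one of the two neighboring columns per row, so support
is pooled over column pairs) within a ±1 m window, requiring support
on ≥60 % of the plot's rows; otherwise the nominal side is kept with a
warning. Along-track sides always stay nominal. This replaces a
visual boundary choice with a reproducible rule. Pixel-in-polygon
extraction uses half-open pixel-center containment, making counts
deterministic and adjacent rectangles a partition.

## Retrieval statistics

Simple OLS regressions; R² on the full fit (equal to squared Pearson
correlation). Cross-validated RMSE: per repeat, a fresh uniform
random partition into 10 near-equal folds; squared errors pooled
across held-out folds, rooted, then averaged over 100 repeats
(conventions stated because several exist). Fold rngs derive from a
root seed via spawned substreams. Confidence and prediction bands use
the standard t-based OLS formulas at the 95 % level on the full fit
only. Mean error per date is observed − predicted, so positive means
underestimation. SPAD→chlorophyll conversion is an exponential
calibration a·e^(b·SPAD) whose coefficients live in configuration —
published calibrations differ by crop and environment, and the package
deliberately ships no authoritative constants (examples use a = 5.0
µg·cm⁻², b = 0.04 per SPAD unit, a plausible potato-scale curve).

## Cross-sensor statistics

The intercomparison regression takes the UAV value as predictor and
the ground value as response by convention (the direction flips DS;
the API leaves it to the caller). DS = 1 − slope, zero meaning
slope-consistency with the 1:1 line. Treatment discrimination fits a
normal distribution per treatment (sample sd, n − 1) and integrates
√(t₁t₂) adaptively; the numeric integral agrees with the normal-normal
closed form √(2s₁s₂/(s₁²+s₂²))·exp(−Δμ²/(4(s₁²+s₂²))) to 10⁻⁸, which
is the dual-route check in the tests.

## Solar geometry

The ephemeris is the NOAA general solar position series (mean
longitude/anomaly polynomials, equation of time, apparent declination);
no refraction correction is applied beyond the series' own apparent
longitude. Azimuth is clockwise from north. An independently coded
PSA-style ephemeris serves as the cross-check in the tests (agreement
≤0.2° away from the horizon). Acquisition-geometry reproduction uses
the experiment's site coordinate since per-flight image-center
coordinates are unavailable; the ±0.5° check tolerance absorbs that.

## Pipeline and reproducibility

Stages hand off through plain files (CSV, JSON, text rasters); every
stage runs standalone. A single global seed feeds per-stage substreams
derived through a stable digest of the stage name, so identical
config + seed reproduces byte-identical outputs across processes. The
run manifest records tool version, config hash, seed and per-stage
outputs.

Default problem sizes are desk-scale by design: 12 plots × 5 dates,
120 UAV pixels and 4 ground footprints per plot, 4 photos × 1080 cells
per gap field, 6-plot mosaics, and a 1.3M-triple LUT vectorized over
its LAI axis (one inversion ≈ 0.2 s).

## Known limitations

- The spectral forward model is not a radiative-transfer model; no
  BRDF, illumination-geometry or diffuse-fraction effects, so
  illumination-driven artifacts reported for real campaigns cannot be
  reproduced.
- Leaf-angle retrieval is weakly identifiable at low LAI within the
  0–37.5° zenith window; off-grid truths can trade ALA against LAI by
  one or two grid steps there.
- Radiometric calibration, georeferencing and fisheye lens calibration
  are out of scope; inputs are assumed calibrated reflectance and an
  ideal projection.
- Band matching is by nearest center only; transferring indices across
  sensors with very different FWHM would need response convolution.
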