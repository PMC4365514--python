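# Methods

This note records the models, the numerical choices and the known limits of
the package, in the order the pipeline runs.

## Flight optics

All geometry is thin-lens similar-triangles arithmetic: a sensor dimension
`s` (mm) behind focal length `f` (mm) at altitude `h` (m) covers `s/f·h`
metres of ground; one pixel covers the instantaneous field of view
`IFoV = (s/n_px)/f·h`. Motion blur is ground speed × shutter time,
expressed in ground pixels by dividing by the pixel footprint and rounding
to the nearest integer. Survey throughput scales a measured
reference (a 0.4 ha field imaged in 10 s) linearly in area. Operations
return full precision; table-style rounding (1 dm on footprints, 3–4
decimals on IFoV) lives in a formatting helper, because a footprint derived
from a *rounded* IFoV differs in the last digit from the direct formula
(both conventions are exposed). The built-in camera set: a 4282×2848 B+NIR
and a 3898×2595 RGB camera, both 22.2×14.8 mm behind 60 mm lenses, and a
640×480, 14.9×11.2 mm thermal camera behind 75 mm with a 50 ms shutter.
An optional pixel-pitch override covers vendor-quoted thermal pitches that
disagree with die-size/pixel-count arithmetic.

## Registration

Fiducials are high-contrast circles, so detection is deliberately simple:
threshold the detection channel at a configurable quantile (default 2%) of
the dark (optical) or bright (thermal) tail, gated at the midpoint between
the background median and the extreme value — without the gate, smooth
scene texture (e.g. thermal noise blurred by up-scaling) floods a pure
quantile mask. Connected components (4-connectivity, so diagonal speckle
does not attach to a marker blob) are filtered by area (π r² within the
expected-radius window), circularity (4πA/P² ≥ 0.6) and solidity (≥ 0.8);
centres are contrast-weighted centroids (sub-pixel, validated to ±0.5 px);
blobs are scored by normalized contrast depth. Fewer than four surviving
markers raises an error that carries the partial list, so a manual marker
file can take over — mirroring field practice, where automatic marker
identification is inspected and occasionally corrected by hand.

NCC refinement slides a (2w+1)² template from the reference (B+NIR) image
over a search window (slack default 1.5× marker radius) and takes the
correlation peak; ties break by smallest offset, then row-major. The
pipeline applies it between sensors that share a ground pixel to within
2%; across different pixel scales the sub-pixel centroid is used directly
(rescaling-based NCC would add its own interpolation error of the same
order as what it removes).

Homographies are fitted by normalized DLT
(`skimage.transform.ProjectiveTransform`) and, for over-determined
systems, refined by Levenberg–Marquardt on the target-plane residuals;
with four exact pairs the fit interpolates. Degenerate configurations
(any three collinear points among four; globally collinear clouds) are
rejected naming the offending points. Detections are paired with the known
AoI marker positions by optimal assignment (Hungarian) under a
scale-initialized guess. Warping into the AoI frame is bicubic; output
pixels whose support touches the outside of the source are NaN and stay
out of every downstream statistic. Thermal frames are up-scaled first with
align-corners bilinear sampling, which reproduces constants and linear
ramps exactly (including borders) and preserves the global mean to ≪0.1%
for integer factors.

Coordinates are 0-based (row, col) with pixel centres at integers;
homographies act on homogeneous (row, col, 1) and are normalized to
H[2,2]=1. Plot rectangles are half-open (low edge closed); the design-to-
polygon conversion nudges polygons by 10⁻⁶ px toward the origin so strict
point-in-polygon containment realizes exactly that convention even when a
boundary lands on a pixel centre.

## Segmentation

Blue-band NDVI with a season-constant plant threshold of 0.1 (strict
inequality; ties are soil), ANDed with a grey-intensity mask — mean of the
B and NIR digital numbers rescaled to [0, 1] — whose threshold must be set
per campaign because it tracks the radiation conditions at capture.
Digital numbers are divided by 65535 before thresholding so intensity
thresholds have a fixed scale; NDVI itself is scale-invariant. The band
0.1 < NDVI ≤ 0.2 isolates senescent plant material (the permissive
threshold keeps it, the stricter one drops it). The RGB route uses
HSB = HSV with hue in degrees [0, 360) (circular intervals may wrap) and
brightness = max(R, G, B).

## Plot traits

Median with even-size midpoint convention; skewness is the population
third standardized moment exactly (no bias correction) and is undefined
(error) for n < 2 or zero variance. `T_C` is the median of *all* valid
thermal pixels of a plot — at a 0.1 m thermal pixel no plant/soil
segmentation is feasible, so the plot signal is a plant–soil mixture and
`T_C` correlates negatively with canopy cover across plots; the mean is
available behind a flag. `dT` uses the single station air temperature of
the campaign (one on-site station; no spatial interpolation). Plots whose
valid-pixel fraction falls below 0.8 are flagged, not dropped; plots with
zero valid pixels produce error records and the run continues.

## Trial statistics

For a balanced g × r genotype × block table (one observation per cell),
blocks fixed and genotypes random:
`σ̂²_ε = MS_res`, `σ̂²_gen = max(0, (MS_gen − MS_res)/r)`,
`h² = σ̂²_gen/(σ̂²_gen + σ̂²_ε/r)` — algebraically `1 − MS_res/MS_gen`
when unclamped. For balanced data these moment estimators coincide in
expectation with REML; unbalanced layouts are rejected loudly rather than
approximated. Note the finite-sample behaviour of the *ratio*: with
g = 16, r = 4 its mean sits below the plug-in value by roughly
`(σ²_ε/(rσ²_gen+σ²_ε))·df/(df−2)` (Jensen), e.g. 0.445 vs 0.50 at
σ²_gen/σ²_ε = 0.25 and 0.911 vs 0.923 at ratio 3 — the tests assert the
finite-sample means, frozen from a 200 000-replicate simulation.
Correlations are Pearson r with two-sided p from the t distribution on
n−2 df; HSD is `q(1−α; g, df_res)·√(MS_res/r)` with a greedy
insert-and-absorb compact letter display (adequate at 16 genotypes). The
noiseless limit (MS_res = 0) declares all distinct means different.

## Weather formulas

Thermal time clamps each day at zero before summing (so it is additive
over concatenated ranges and non-decreasing), base 8 °C for maize. SVP is
computed in Pa, VPD reported in kPa. The LAI calibration is read as
`LAI = (SLW − 3.96)/27.4` with `SLW = biomass/(SL·70 cm)·1000` in
mg cm⁻²; the alternative parenthesization (subtracting 3.96/27.4) yields
LAI in the tens, dimensionally absurd for m² m⁻², so the linear-calibration
reading (27.4 mg cm⁻² per unit LAI over a 3.96 intercept, fitted at
r² = 0.98 on n = 24) is adopted. Negative LAI clamps to zero with a
warning. Note that some published instantaneous VPD tables are mutually
inconsistent with this formula at their own printed temperature/humidity
pairs; only the formula is implemented.

## The synthetic scene

The generator emulates the trial, not photorealism. What it reproduces:

* the split-plot layout — 16 genotypes (6 hybrids, 5 dent, 5 flint inbred
  lines, hybrids and inbreds in separate sub-blocks), rows-per-plot
  (1–4) as whole-plot factor in randomized order per block, 4 blocks,
  4 m plots at 0.75 m spacing, the field cut into three sub-array
  rectangles, and eight fiducials at the sub-array corner lines (so every
  sub-array has four and the field has eight);
* genotype-specific seasonal curves: canopy cover rising logistically to a
  plateau (hybrids close near the onset of flowering at ~540 °C d) and
  declining after a senescence onset near 892 °C d; plant NDVI rising to
  ~0.62–0.68 and declining late; dT negative mid-season (−1 to −2.3 °C)
  and slightly positive at 1275 °C d;
* plot-level residual variance scaling as 1/rows_per_plot — the
  generator's *mechanism* for the observed plot-size → repeatability
  effect, a modelling choice, not an empirical claim;
* per-pixel distributions: plant NDVI ~ N(genotype level, 0.05), soil
  ~ N(−0.35, 0.03), both clipped to [−1, 1]; digital numbers are
  back-computed from NDVI and a common reflection-intensity level (0.55)
  so that the NDVI of a mixed pixel interpolates linearly and the
  plant/soil midpoint straddles the 0.1 threshold — edge pixels then
  round to plant and soil in equal measure instead of biasing canopy
  cover; 3% of soil pixels are deep shade (×0.15 intensity), which the
  intensity filter must remove (simulator campaigns document an intensity
  threshold of 0.2);
* canopy geometry: each crop row is a strip whose width makes the
  plant-area fraction of the plot equal the plot's true cover; the strip
  edge carries a ±4 cm triangle-wave raggedness (leaf tips) whose base is
  adjusted in closed form where the wave clips at bare or closed rows, so
  the expected fraction stays exact, and whose uniform dithering makes
  pixel quantization of the fraction average out; closed canopies overhang
  the plot edge into the alley, as real maize does, so the plant/soil
  transition of a closed plot falls outside the polygon;
* thermal rendering at a coarse pixel by 4×4 sub-sampling and averaging
  (true plant/soil mixing), markers 15 °C above air, soil 3 °C above air,
  0.3 °C pixel noise;
* known per-sensor projective distortions (small rotation, translation and
  perspective terms around the ground-pixel scale map) and full
  determinism: one master seed, per-purpose streams at fixed offsets, so
  adding a campaign never perturbs earlier draws, and identical seeds give
  bit-identical rasters.

What it does **not** emulate: radiometric miscalibration and vignetting,
tassels (the mid-season cover dip), lens distortion, atmospheric effects,
within-plot spatial trends, and point-spread blur beyond what warping
introduces. Passing the recovery tests therefore shows the *pipeline* is
faithful at realistic contrasts and geometry, not that segmentation of
real imagery achieves these accuracies.

## Problem sizes and tolerances

Unit tests run the scene at a 0.075 m optical / 0.3 m thermal pixel; the
end-to-end recovery checks and the acceptance script run at the native
pixel set of the instrument table at 290 m altitude — 0.025 m (B+NIR),
0.0275 m (RGB), 0.1 m (thermal) — two campaigns (371 and 727 °C d). Both
optical evaluation pixels divide the 0.75 m row spacing, so plot
boundaries align with the raster grid; misaligned pixels would add an
O(pixel/plot-width) rasterization bias to canopy cover that has nothing
to do with pipeline fidelity. At these scales recovered CC is within
±0.02 and NDVI_Plant within ±0.01 of truth per plot, fitted homographies
reproject markers to ≤1 px (measured ~0.1–0.2 px), and extracted T_C is
within ±0.3 °C of the rendered-mixture reference (a noise-free twin of
the thermal scene warped through the *true* homography — the correct
reference, since the coarse thermal mixture itself, not the pure plant
temperature, is what the sensor renders). Coarser pixels degrade CC
gracefully and honestly: at 0.075 m the ~1-px soil gaps of nearly closed
canopies are smeared above threshold and per-plot errors reach ~0.05,
the small-object limit (≈3 pixels) familiar from remote-sensing practice.

## Known limitations

* The balanced-ANOVA estimator rejects unbalanced data by design; there is
  no REML path for missing plots.
* `dT` from the coarse thermal mixture under-states pure-canopy cooling at
  partial cover (by construction; take CC into account when comparing
  genotypes).
* Late-season scenes (plant NDVI approaching the 0.1 threshold) shift the
  mixed-edge balance and bias CC slightly low; recovery claims are made
  for the early and flowering campaigns.
* The compact letter display is greedy; for very large genotype sets a
  graph-colouring CLD would be preferable.
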