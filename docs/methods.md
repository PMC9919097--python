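# Methods

This note documents the models implemented in `cwsibench`, the defaults
and why they were chosen, the numerical conventions, and what the
synthetic scenes can and cannot demonstrate.

## The measurement model

A scanning infrared thermometer with a conical field of view reads one
object temperature per grid cell — the mean surface temperature over the
circular footprint of radius `h·tan(θ)` (sensor height h = 50 mm above
the canopy; half angle θ). The bare sensor has a 90° cone; the default
θ = 10° models a collimator tube, without which a 50 mm-radius footprint
averages whole plant rows together with the soil between them and the
resulting leaf temperatures are dominated by soil. Footprint membership
is whole-pixel (a pixel belongs to the footprint iff its center lies in
the disc): simple, resolution-controlled, and checkable against a
brute-force enumeration, which the test suite does to 1e−9 °C. Sensor
noise is Gaussian with σ = 0.25 °C, so ~95 % of readings fall within the
±0.5 °C precision typical of low-cost IR thermometers. Emissivity
(default 0.98, the standard value for leaves) is carried as instrument
metadata only; no radiance model is applied.

The scan grid defaults to 61 × 22 cells of 20 × 20 mm. The default
synthetic scene covers exactly this span (1.22 m × 0.44 m at
2.5 mm/pixel), so the resize-and-overlay fusion is registered: both the
thermal raster and the plant mask describe the same physical extent.
If a user supplies a grid covering a sub-region of the image, the fusion
inherits that misregistration — the same limitation as the physical
resize-and-overlay procedure.

## Synthetic scenes

Leaves are overlapping ellipses (default 36 × 14–18 mm axes, size and
orientation jittered) placed at 50 mm intervals along rows 200 mm apart,
drawn in a Gaussian-perturbed green over a Gaussian-perturbed brown soil
background. The truth mask marks exactly the drawn pixels. The true
temperature field assigns soil `T_A + 3 °C` (soil in sunlit benches runs
warmer than transpiring leaves) and leaves
`T_A + a + b·VPD(T_A, RH) + offset_treatment + noise`, i.e. unstressed
leaves sit on the non-water-stressed baseline and stressed treatments
are warmed additively. Default baseline coefficients are a grape-type
pair (a = 2.54 °C, b = −1.71 °C kPa⁻¹), a mid-range published baseline
for a transpiring crop. Default treatment offsets (0, +1, +2 °C) impose
a known stress ladder across the three irrigation treatments.

What the scenes do **not** emulate: plant growth over the cycle, leaf
angle and self-shading, specular highlights and mixed illumination,
wind- or dew-driven departures from the baseline, soil heterogeneity,
and sensor drift. Tests passing on these scenes therefore demonstrate
the correctness of the algorithms (segmentation, fusion, normalization,
charting) under controlled contrast and noise — not field performance of
any particular sensor.

## Environment, moisture and the stress cycle

Ambient series are sinusoidal diurnal cycles (T_A peak at 14:00, RH in
anti-phase, clipped to [0, 1]) plus Gaussian noise, at 10-minute cadence
for 30 days (4320 records) by default. Soil moisture is a sawtooth per
treatment: linear drydown (default 0.05 FC/day) with a fixed recharge
(0.10 FC, standing in for the fixed 0.7 L irrigation volume) whenever a
trace crosses its treatment threshold (0.85 / 0.75 / 0.55 of field
capacity) from above, sampled every 20 minutes. For cycle-level
monitoring, the daily leaf warming is coupled to the moisture deficit as
`offset = coupling · (1 − VWC/FC)` with coupling 8 °C — enough to span
the CWSI range across treatments; this coupling is the mechanism by
which stress and moisture are anticorrelated in the simulation, so the
negative Spearman correlation the tests assert verifies the pipeline's
bookkeeping, not a biological discovery.

## Segmentation

ExG uses chromaticity normalization with the zero-sum pixel mapped to
ExG = 0 (the achromatic limit; avoids 0/0). The thresholding rule is
Otsu on a 256-bin histogram of the ExG values (deterministic, standard
practice for ExG), with a fixed-threshold override. The
manual-reference labelling computes per-channel mean ± 1 sd over the
sampled pixels and labels a pixel plant iff **all three** channels lie
inside their bands (conjunction chosen as the strictest reading; a
disjunction would label most of the image). Metric edge cases follow
the convention that 0/0 ratios are 0 and the F-score is 0 whenever
TP = 0, so the score runs from 0 (no true positives) to 1 (perfect).

## Thermal fusion and validation

Bilinear resizing uses corner-aligned coordinates (first/last output
samples coincide with source corners) via
`scipy.interpolate.RegularGridInterpolator`; outputs are convex
combinations of source samples and never exceed the source extrema.
Masks are resized nearest-neighbour to stay strictly binary. Non-plant
LTM pixels carry NaN, not 0 — 0 °C is a legal temperature, and the
multiply-by-zero description of mask fusion conflates the two.
Validation against a reference raster reports the per-pixel relative
error `(S − C)/C` over plant pixels (pixels with C = 0 excluded with a
logged count), its arithmetic mean, the standard error of that mean,
and the mean absolute difference in °C alongside (the relative and
absolute conventions are both in circulation for this quantity).

## Baseline and CWSI

Saturation vapor pressure uses the Tetens-type form
`es(T) = 0.6108·10^(7.5T/(273.3+T))` kPa. RH is a fraction internally;
values above 1 are rejected as probable percentages rather than
silently rescaled. The baseline is ordinary least squares with
intercept (statsmodels), with residual diagnostics attached: residual
mean (zero by construction), slope of residuals on fitted values, and a
Breusch–Pagan homoscedasticity p-value. A daily-mean aggregation is the
default convenience path (appropriate when maps are produced once a
day); an hour-of-day stratification is available for the time-resolved
variant.

The upper limit uses the potential-VPD construction: a non-transpiring
canopy at zero ambient VPD warms by the intercept `a`, creating the
vapor-pressure gradient `es(T_A) − es(T_A + a)` (≤ 0 for a > 0);
re-entering it in the baseline gives `UL = a + b·(es(T_A) − es(T_A+a))`,
which exceeds every lower limit whenever a > 0 and b < 0. This
construction is isolated in one function (`upper_limit`) so an
alternative parameterization can be swapped in.

CWSI uses the canonical normalization `(dT − LL)/(UL − LL)`, the only
form for which the anchors CWSI(LL) = 0 and CWSI(UL) = 1 both hold; a
`denominator="literal"` variant with `(UL − dT)` in the denominator is
exposed for comparison. Limits are evaluated once per scan (scan-level
T_A and RH), not per pixel. Clipping to [0, 1] happens after map
construction and the clip counts are retained on the map. The empirical
method takes scan-level wet/dry reference temperatures (scalars, as
averages over a few reference leaves would be).

## EWMA monitoring

`z_t = λ·x_t + (1 − λ)·z_{t−1}` with `z_0` = center (series mean by
default) and exact time-varying limits
`center ± L·σ·√(λ/(2−λ)·(1−(1−λ)^{2t}))`. Defaults λ = 0.2, L = 3 per
standard control-chart practice; σ is the sample standard deviation
(moving-range estimate available). Violation comparison carries an
absolute tolerance of 1e−9 (scaled by the center magnitude) so float
round-off in the recursion cannot flag a constant series against its
zero-width limits. Charts are built on daily per-treatment means.

## Problem sizes and determinism

Default test and acceptance problem sizes — 176 × 488-pixel scenes,
61 × 22 scans, 30-day series, 100 replicates for recovery and ordering
checks — were chosen so the full suite runs in seconds on one core
while keeping Monte-Carlo assertions comfortably away from their
thresholds. Every stochastic component takes an explicit seed
(`numpy.random.default_rng`); identical seeds and parameters produce
byte-identical scenes, scans, series and pipeline artifacts.

## Known limitations

- Fusion assumes the thermal grid and the image are co-extensive; there
  is no feature-based registration.
- The footprint average is unweighted over member pixels; no optical
  point-spread weighting.
- The potential-VPD upper limit is one published construction among
  several; with a ≤ 0 it degenerates (UL ≤ LL) and stress mapping
  refuses to proceed rather than emit unbounded indices.
- Segmentation applies no morphology or smoothing; heavily speckled
  scenes will show salt-and-pepper mask noise.
- The moisture–stress coupling is a one-parameter surrogate for plant
  water relations; it orders treatments correctly but has no hydraulic
  interpretation.
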