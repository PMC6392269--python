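# Methods

## Coordinate, sign and unit conventions

The axial coordinate z is millimetres caudal of the foramen magnum
(FM), z = 0 at the FM, increasing toward the sacrum; slice positions
derive from 0-based voxel indices as `(index − fm_index) × axial
spacing`. Caudal (foot-ward, CSF-systolic) flow is negative; cranial
(diastolic) flow positive. Units are fixed at the I/O boundary: mm,
mm², ml, s, cm/s, ml/s; conversions (1 ml/s = 100 cm/s·mm⁻² of area,
1 ml = 1000 mm³, 1 cm² = 100 mm²) happen inside the computations and
are exact.

## Geometry estimation

Cross-sections are taken on native image planes; the imaging protocol
this targets orients slices approximately perpendicular to the canal,
and oblique re-slicing along a centerline is out of scope (a small bias
source at curved levels). Areas are pixel counts × pixel area.
Perimeters are marching-squares contour lengths at the 0.5 level of the
mask after a Gaussian blur of 1 px: contouring the raw binary mask
yields staircase polygons that overestimate a circle's perimeter by up
to ~8%, while the blurred field restores sub-pixel boundary placement
(error ≪ 1% for radii ≳ 8 px, with a curvature bias of order σ²/2r that
becomes the accuracy floor at very fine pixels). If the blur erases a
structure thinner than ~2 px the raw-mask contour is used as fallback.

Accuracy caveat: pixel-count areas of digitized disks fluctuate with
the number-theoretic luck of the boundary (the Gauss circle problem).
At radii near 10 px the typical error is a few tenths of a percent, but
isolated radii can exceed 2–3%. Tests therefore assert the 2% bound at
representative radii and assert convergence of the *mean* error under
pixel-size refinement rather than per-radius monotonicity.

Whole-spine totals use the rectangle rule over the 1-mm profile
(exact for the discrete sums it represents): volumes `Σ A Δz`, lateral
surface areas `Σ P Δz` (end caps ignored). An STL-mesh alternative
(`surface_area_from_mesh`, triangle-area summation via trimesh) exists
for segmentations exported as meshes; the mask path is the default.
The profile terminates at the last plane with at least one dura pixel;
planes with dura but no cord (filum/caudal region) contribute
`A_c = P_c = 0`. Hydraulic diameter is NaN where `P_sas = 0`; NaN marks
"undefined" throughout and is excluded from downstream statistics.

## Flow analysis

`Q(t) = Σ A_pixel V_pixel(t)` over the ROI, per cardiac phase. Offset
correction subtracts the cycle mean (phases are uniform, so the mean is
the zero-net-flow offset); the offset is also reported as a percentage
of the mean |Q| after correction for QC against eddy-current
contamination. Heart-rate normalization rescales the time axis to a
common cycle, which for equal phase counts leaves sampled amplitudes
untouched; resampling to a different phase count uses periodic linear
interpolation.

Stroke volume integrates |Q| by the trapezoid rule with periodic
closure (for uniform phases this equals mean(|Q|)·T). The printed
convention `SV = ∫|Q| dt` counts both flow directions; a `sv_half`
flag halves it for the displaced-volume-per-direction convention.
At 24 phases the sinusoid oracle (`SV = 2Q₀T/π`, `Q_a = 2Q₀`) is met
within 0.5% for generic alignment of the waveform relative to the phase
grid; if waveform zeros coincide exactly with samples the |Q| kinks
cost ~0.6%, and if extrema fall exactly between samples `Q_a` loses
~0.9% — both degenerate alignments, noted here because synthetic tests
can accidentally construct them.

Viscosity: CSF at body temperature is treated as μ = 0.693 mPa·s
dynamic viscosity with ρ = 1000 kg/m³, giving ν = 0.693×10⁻⁶ m²/s.
(The number is sometimes quoted as a "kinematic viscosity" in mPa·s,
which is dimensionally a dynamic viscosity; with water-like density the
two readings agree numerically, and back-computing α from reference
hydraulic diameters and cycle periods confirms this interpretation.)
`Re = |Ū_sys| D_h / ν` uses the magnitude of the (negative) systolic
mean velocity. `α = (D_h/2)√(ω/ν)` uses the gap half-scale D_h/2; this
convention reproduces reference α ranges (≈ 4–8 for D_h ≈ 2–3.7 mm and
T ≈ 0.45–0.65 s).

## Spatio-temporal surface and PWV

Slices share a rectangular (z, t) grid after heart-rate normalization,
so the surface is a FITPACK bivariate spline (`RectBivariateSpline`)
over the cycle flanked by time-shifted copies (periodic handling), with
cubic order in both axes (z order reduced when < 4 slices). Each
evaluated z-row is re-offset to zero mean, so zero net flow survives
smoothing. The surface is evaluated within the measured span only — no
extrapolation.

The smoothing parameter s (FITPACK residual budget) defaults to
leave-one-interior-slice-out cross-validation over a small
multiplicative grid including s = 0 (interpolation), with the selected
value logged and a fixed override available for reproducibility. With
six slices and ROI-averaged (hence low-noise) waveforms, CV typically
selects s = 0.

Peak-systolic arrival per z is the discrete minimum (ties broken to the
earliest phase) refined by a three-point parabola over periodic
neighbours — 24 phases give ~23 ms resolution, so sub-sample refinement
materially reduces quantization bias in wave-speed estimates — then
unwrapped across z modulo the cycle. Flat rows are excluded. PWV is
1/slope of the OLS fit of arrival time on z (z is the controlled
variable), over the full measured span by default; slopes ≤ 10⁻⁹ s/mm
flag PWV as undefined (standing wave) instead of raising.

A design point worth knowing: between widely spaced slices the spline
blends time-shifted pulses, and the minimum of a blend of shifted
pulses wobbles around the true interpolated timing (up to ~0.03 s for
~90 mm slice gaps at ~1 m/s wave speed). Arrival times *at* the
measured slices are undistorted (the interpolating surface reproduces
them to machine precision). The subject pipeline therefore fits PWV on
the measured slices' own arrival times (`arrival_from_waveforms`),
keeping the surface's per-z peak line (`peak_arrival`) for
visualization and QC. On noise-free phantoms this recovers prescribed
PWV in [0.5, 5] m/s within 0.2% from six slices over 300 mm; at 5%
pixel noise, 20-replicate means stay within ~1%. PWV can be computed
per subject and averaged, or on a cohort-averaged surface; per-subject
is the default reading of cohort tables.

## Cohort statistics and reliability

Profiles are compared after linear rescaling of each subject's z-axis
to the cohort-mean `L_sas` and 1-mm resampling (linear interpolation;
values, hence extrema, are preserved up to resampling). Summary scalars
per parameter: "average" is the z-mean of the cross-subject mean
profile; "maximum"/"minimum" are that mean profile's extrema along the
spine — not extrema of any individual subject. Totals (volumes, surface
areas, lengths, PWV) are averaged as scalars. Extrema are additionally
reported with the first 5 mm omitted, since profiles can be steep right
at the FM. Sample (n−1) standard deviations throughout.

Reliability pools (baseline, follow-up) pairs over subjects × axial
locations per parameter and fits OLS of follow-up on baseline. R² is
invariant under swapping the axes; the slope is not — the reported
slope is follow-up regressed on baseline. NaN pairs are dropped; < 3
surviving pairs is an error.

The vertebral lookup returns the level whose tabulated mean distance
below the FM is nearest to z (ties to the more cranial level). The
bundled table is for the cynomolgus monkey; other species supply their
own `VertebralTable`.

## The digital phantom

The phantom emulates the two inputs, not the MR physics (no partial
volume, phase wrapping or k-space effects).

**Geometry.** Concentric circular cord/dura cross-sections with radii
following monotone-cubic (PCHIP) curves through control points:
cervical cord enlargement, tight upper-thoracic annulus (A_sas minimum
≈ 7 mm² near z = 70 mm), caudal taper, cord ending at 260 mm inside a
300 mm dural sac. Defaults were set so the key study-scale quantities
land near reported non-human-primate values: A_sas spans ≈ 7–75 mm²,
V_c ≈ 4.5 ml, V_d ≈ 11.6 ml, V_sas ≈ 7.1 ml. In-plane pixels are
0.375 mm (the anatomical-scan resolution this emulates) on a 64² grid,
slices every 1 mm. Rasterization is pixel-centre inclusion; ground
truth uses exact circle formulas per slice and fine-grid quadrature of
the radius curves for totals. Note the annulus gap near the A_sas
minimum is ~1 pixel wide, so rasterized A_sas can err by ~10–20%
locally there — real acquisitions of tight annuli share this limit, and
accuracy claims are therefore made where structures are ≥ 10 px.

**Flow.** A caudally travelling pulse
`Q*(z,t) = Q_a(z)·shape(((t − z/PWV) mod T)/T)` with:

* `shape`: a zero-mean, unit peak-to-peak cycle built from a von Mises
  bump, `shape(u) = (m − e^{κ(cos 2π(u−0.2)−1)})/(1 − e^{−2κ})` with
  κ = 1.1145 and m = I₀(κ)e^{−κ}, giving a sharp systolic minimum at
  0.2 T, a broad diastolic lobe, and |Q_sys|/Q_dia = 1.7 — the
  two-lobe morphology of cardiac-gated spinal CSF flow. The constant
  ∫|shape| du = 0.30943 is frozen from high-resolution quadrature.
* `Q_a(z)`: a squared-gamma-style bump peaking at z = 25 mm (amplitude
  0.9 ml/s by default, hence peak systolic flow ≈ 0.57 ml/s in the
  cervical spine) on a 15% caudal floor, so the most caudal slices
  still carry usable signal, as observed in vivo.
* default cycle T = 0.55 s, 24 phases; default PWV 1.13 m/s; velocity
  exports at six planes matching FM, C2-C3, C5-C6, T4-T5, T10-T11 and
  L3-L4 disk positions.

Velocities distribute Q* uniformly over the annulus pixels (plug
profile — consistent with α ≈ 4–8; a Womersley-magnitude-shaped option
exists, rescaled to preserve the flow integral exactly). A constant
per-slice velocity bias models eddy-current offsets (matching the
correction the pipeline applies) and i.i.d. Gaussian pixel noise is
drawn from a per-slice substream of the seeded generator, so identical
config + seed gives identical output. "5% noise" means pixel-velocity
sd = 5% of the phantom's peak plug speed (`peak_pixel_speed_cm_s`).

**What passing phantom tests does not show:** real SAS cross-sections
are eccentric crescents with nerve roots and denticulate ligaments, not
concentric annuli; real velocity profiles are not plugs; segmentation
error, motion, partial volume and aliasing are absent. Phantom recovery
validates the estimator chain, not the MR measurement itself.

## Problem sizes and runtime choices

Default test and acceptance runs use the 300-mm phantom at 0.375 mm ×
64² × 301 slices, six velocity slices × 24 phases, and 20 noise
replicates per prescribed PWV — the full suite runs in a few seconds.
These sizes were chosen to exercise every code path at the study's own
scale; phantom length, pixel size and replicate counts are all
configurable.

## Known limitations

* No oblique re-slicing along the canal centerline; areas at curved
  levels are slightly overestimated.
* The supplementary-workbook importer maps sheets by name pattern and
  was written against a synthetic stand-in layout; real deposited
  workbooks may need a mapping tweak (the mapping is logged).
* Velocity aliasing (venc overrun) is not unwrapped; the venc is
  carried as metadata only.
* Respiration-driven flow is outside the cardiac-gated model.
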