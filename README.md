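# csfhydro

Quantification of intrathecal cerebrospinal-fluid (CSF) geometry and
hydrodynamics from MRI, aimed at researchers characterizing the spinal
subarachnoid space (SAS) in non-human primates or other subjects — e.g.
for intrathecal drug-delivery studies, where the CSF space's size and
pulsatile motion control how an injected therapeutic spreads.

The package consumes two kinds of input:

* **segmented label volumes** (NIfTI) of the spinal canal, with labels
  for the spinal cord and the dura-enclosed region, spanning the foramen
  magnum (FM, z = 0) to the SAS termination;
* **per-pixel through-plane velocity exports** from cardiac-gated
  phase-contrast MRI, one CSV (+ JSON sidecar) per axial slice, with 24
  cardiac phases.

and produces axial profiles at 1-mm intervals, whole-spine totals, a
spatio-temporal flow reconstruction, pulse wave velocity, cohort
summaries and test–retest reliability regressions. An annular digital
phantom with analytic ground truth validates every stage.

## What is computed

Geometry, per z (mm caudal of the FM):

* cross-sectional areas `A_c(z)`, `A_d(z)`, `A_sas(z) = A_d − A_c` (mm²),
  from in-plane pixel counts;
* perimeters `P_c(z)`, `P_d(z)`, `P_sas(z) = P_c + P_d` (mm), as
  marching-squares contour lengths;
* hydraulic diameter `D_h(z) = 4 A_sas(z) / P_sas(z)`;
* totals: volumes `V_x = Σ A_x Δz` (ml), lateral surface areas
  `SA_x = Σ P_x Δz` (cm²), with `V_sas = V_d − V_c` and
  `SA_sas = SA_c + SA_d`, and the SAS length `L_sas`.

Flow, per measured slice and per interpolated z:

* `Q(t) = Σ A_pixel · V_pixel(t)` (ml/s), offset-corrected to zero net
  flow over the cycle (caudal/systolic flow is negative);
* a bivariate smoothing-spline surface `Q(z, t)` on a 1-mm × 24-phase
  grid, after heart-rate normalization to a common cycle;
* peak flows `Q_sys = min Q`, `Q_dia = max Q`, amplitude
  `Q_a = Q_dia − Q_sys`; stroke volume `SV = ∫|Q| dt`;
* mean velocities `Ū = Q / A_sas` (cm/s), Reynolds number
  `Re = |Ū_sys| D_h / ν` and Womersley number `α = (D_h/2)·√(ω/ν)`
  with `ω = 2π/T` and CSF kinematic viscosity `ν = 0.693×10⁻⁶ m²/s`;
* pulse wave velocity `PWV = 1/slope` of the ordinary-least-squares fit
  of peak-systolic arrival time against z.

Cohort tools rescale each subject's profiles to the mean `L_sas`,
compute mean ± sd profiles with spine-wise average/max/min, map z to
vertebral levels, and regress follow-up against baseline values pooled
over all axial locations.

## Worked example

`examples/phantom_pipeline.py` generates a 300-mm annular phantom with
5%-scale pixel noise, a 0.05 ml/s per-slice offset and a prescribed PWV
of 1.13 m/s, then runs the full analysis:

```
SAS volume          7.16 ml   (analytic 7.10 ml)
SAS surface area   102.2 cm^2
PWV recovered      1.153 m/s  (prescribed 1.13, R^2 = 0.9987)
SV peak            0.152 ml at z = 24 mm (C3; prescribed peak at 25 mm)
flow offsets      recovered 0.0498 ml/s (injected 0.05)
```

The SAS volume matches the phantom's analytic value to within the
rasterization error, the pulse wave velocity is recovered within a few
percent despite the noise, the stroke-volume peak lands at the
prescribed cervical location (vertebral level C3), and the injected
eddy-current-like offsets are recovered almost exactly. The other
example scripts walk through geometry-only profiling, single-slice flow
analysis, and cohort statistics/reliability.

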