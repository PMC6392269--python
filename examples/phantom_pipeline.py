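"""Full pipeline on a noisy digital phantom with known ground truth.

Generates an annular spine phantom (segmentation volume + six per-slice
velocity exports with 5%-scale pixel noise and an eddy-current-like
offset), runs the complete subject analysis, and compares the recovered
pulse wave velocity, stroke-volume peak and flow offset to the
prescribed values.
"""

import numpy as np

import csfhydro as ch
from csfhydro.phantom import peak_pixel_speed_cm_s

cfg = ch.PhantomConfig(
    noise_cm_s=0.05 * peak_pixel_speed_cm_s(ch.PhantomConfig()),
    offset_ml_s=0.05,
    seed=1,
)
seg, geo_truth = ch.generate_geometry(cfg)
series, flow_truth = ch.generate_flow(cfg)

result = ch.analyze_subject(seg, series)

tot = result.global_geometry
print(f"SAS volume        {tot.v_sas:6.2f} ml   (analytic "
      f"{geo_truth.v_dura_ml - geo_truth.v_cord_ml:.2f} ml)")
print(f"SAS surface area  {tot.sa_sas:6.1f} cm^2")
print(f"PWV recovered     {result.pulse_wave.pwv_m_s:6.3f} m/s  "
      f"(prescribed {cfg.pwv_m_s}, R^2 = {result.pulse_wave.r_squared:.4f})")

h = result.hydrodynamic
z_peak = h.z[np.nanargmax(h.sv)]
print(f"SV peak           {np.nanmax(h.sv):6.3f} ml at z = {z_peak:.0f} mm "
      f"({ch.vertebral_lookup(z_peak)}; prescribed peak at "
      f"{flow_truth.sv_peak_z_mm:.0f} mm)")
print(f"flow offsets      recovered "
      f"{np.mean([o.offset_ml_s for o in result.offsets]):.4f} ml/s "
      f"(injected {cfg.offset_ml_s})")
# The PWV should land within a few percent of the prescription and the
# SV peak within ~1-2 mm: that is the phantom's recovery guarantee.
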