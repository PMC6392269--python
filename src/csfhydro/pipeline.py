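"""End-to-end subject analysis: files in, profiles and PWV out."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry, spatiotemporal
from .errors import ValidationError
from .flow import (CSF_DEFAULT, FluidProperties, OffsetResult, offset_correct,
                   resample_cycle, waveform_from_pixels)
from .io import SegmentationVolume, StudyConfig, VelocityROISeries, read_segmentation, read_velocity_csv


@dataclass
class SubjectResult:
    """Everything the pipeline derives for one subject/session."""

    geometric: geometry.GeometricProfile
    global_geometry: geometry.GlobalGeometry
    offsets: list[OffsetResult]
    stf: spatiotemporal.SpatioTemporalFlow
    arrival: spatiotemporal.ArrivalCurve
    pulse_wave: spatiotemporal.PulseWave
    hydrodynamic: spatiotemporal.HydrodynamicProfile


def analyze_subject(
    seg: SegmentationVolume,
    roi_series: list[VelocityROISeries],
    fluid: FluidProperties = CSF_DEFAULT,
    dz: float = 1.0,
    smoothing: float | None = None,
    sv_half: bool = False,
) -> SubjectResult:
    """Run the full analysis for one subject.

    Steps: axial geometric profiles and totals; per-slice flow waveforms
    with zero-net-flow offset correction and heart-rate normalization to
    the mean cycle; spatio-temporal smoothing-spline surface; peak
    systolic arrival curve and PWV over the full measured span; per-1-mm
    hydrodynamic profile using local geometry.
    """
    if not roi_series:
        raise ValidationError("no velocity series supplied")
    prof = geometry.slice_profiles(seg, dz=dz)
    glob = geometry.totals(prof)

    offsets = [offset_correct(waveform_from_pixels(roi)) for roi in roi_series]
    t_mean = float(np.mean([o.waveform.period_s for o in offsets]))
    waveforms = [resample_cycle(o.waveform, t_mean) for o in offsets]

    stf = spatiotemporal.fit_spatiotemporal(waveforms, dz=dz, smoothing=smoothing)
    # PWV from the measured slices' own peak timing (FM to the most
    # caudal slice); the surface's peak line is kept for plotting/QC
    arrival = spatiotemporal.arrival_from_waveforms(waveforms)
    pw = spatiotemporal.pulse_wave_velocity(arrival)
    hydro = spatiotemporal.hydrodynamic_profile(stf, prof, fluid=fluid, sv_half=sv_half)
    return SubjectResult(
        geometric=prof, global_geometry=glob, offsets=offsets,
        stf=stf, arrival=arrival, pulse_wave=pw, hydrodynamic=hydro,
    )


def analyze_subject_from_config(config: StudyConfig) -> SubjectResult:
    """File-path driven variant of :func:`analyze_subject`."""
    if config.segmentation_path is None:
        raise ValidationError("config has no segmentation path")
    seg = read_segmentation(config.segmentation_path, label_map=config.label_map)
    rois = [read_velocity_csv(csv, sidecar) for csv, sidecar in config.velocity_paths]
    fluid = (FluidProperties(mu_mpa_s=config.viscosity_mpa_s)
             if config.viscosity_mpa_s else CSF_DEFAULT)
    return analyze_subject(
        seg, rois, fluid=fluid, dz=config.dz_mm,
        smoothing=config.smoothing, sv_half=config.sv_half,
    )
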