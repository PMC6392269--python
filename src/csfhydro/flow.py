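"""Flow waveforms and per-location hydrodynamic features from pixel velocities.

The volumetric flow waveform at one axial plane is the ROI sum

    Q(t) = sum_pixels A_pixel * V_pixel(t)

(pixel area mm^2, velocities cm/s, Q in ml/s).  Spinal CSF flow is
oscillatory with ~zero net flow over a cardiac cycle, so each waveform
is offset-corrected by subtracting its cycle mean; the removed constant
is the eddy-current-like offset and is reported for QC as a percentage
of the mean absolute corrected flow.

Sign convention: caudal (foot-ward, systolic) flow is negative, so
Q_sys = min Q <= 0 and Q_dia = max Q >= 0.

Per-location features: stroke volume SV = integral |Q| dt over one
cycle (trapezoid with periodic closure; a ``sv_half`` flag applies the
per-direction 1/2 factor), flow amplitude Q_a = Q_dia - Q_sys, spatial
mean velocities U = Q / A_sas, Reynolds number Re = |U_sys| D_h / nu
and Womersley number alpha = (D_h / 2) sqrt(omega / nu), omega = 2 pi / T.

CSF is treated as water-like: dynamic viscosity 0.693 mPa s at body
temperature with density 1000 kg/m^3, giving nu = 0.693e-6 m^2/s.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import VelocityROISeries

logger = logging.getLogger(__name__)

__all__ = [
    "FluidProperties",
    "FlowWaveform",
    "WaveformFeatures",
    "OffsetResult",
    "waveform_from_pixels",
    "offset_correct",
    "resample_cycle",
    "waveform_features",
    "CSF_DEFAULT",
]


@dataclass(frozen=True)
class FluidProperties:
    """CSF fluid properties; nu is derived as mu / rho."""

    mu_mpa_s: float = 0.693   # dynamic viscosity, mPa s
    rho_kg_m3: float = 1000.0

    def __post_init__(self) -> None:
        if self.mu_mpa_s <= 0 or self.rho_kg_m3 <= 0:
            raise ValidationError("fluid properties must be positive")

    @property
    def nu_m2_s(self) -> float:
        """Kinematic viscosity (m^2/s)."""
        return self.mu_mpa_s * 1e-3 / self.rho_kg_m3


CSF_DEFAULT = FluidProperties()


@dataclass
class FlowWaveform:
    """Volumetric flow over one cardiac cycle at one axial location.

    ``q_ml_s`` holds uniform phase samples on [0, T); caudal flow is
    negative.
    """

    z_mm: float
    q_ml_s: np.ndarray
    period_s: float

    def __post_init__(self) -> None:
        self.q_ml_s = np.asarray(self.q_ml_s, dtype=float)
        if self.q_ml_s.ndim != 1 or self.q_ml_s.size < 2:
            raise ValidationError("waveform needs at least two phase samples")
        if self.period_s <= 0:
            raise ValidationError("cycle period must be positive")

    @property
    def n_phases(self) -> int:
        return self.q_ml_s.size

    @property
    def times(self) -> np.ndarray:
        """Uniform phase times on [0, T)."""
        return np.arange(self.n_phases) * (self.period_s / self.n_phases)

    @property
    def omega(self) -> float:
        return 2.0 * math.pi / self.period_s


@dataclass
class OffsetResult:
    waveform: FlowWaveform
    offset_ml_s: float
    offset_pct: float  # |offset| as % of mean |Q| after correction


@dataclass
class WaveformFeatures:
    """Scalar hydrodynamic features of one offset-corrected waveform."""

    q_sys: float    # ml/s, <= 0 (caudal peak)
    q_dia: float    # ml/s, >= 0 (cranial peak)
    q_a: float      # ml/s
    sv: float       # ml
    u_sys: float    # cm/s
    u_dia: float    # cm/s
    re: float       # -
    alpha: float    # -


def waveform_from_pixels(roi: VelocityROISeries) -> FlowWaveform:
    """Q(t) = sum A_pixel V_pixel(t), in ml/s; not yet offset-corrected.

    mm^2 * cm/s = 10 mm^3/s = 0.01 ml/s.
    """
    if roi.n_pixels < 1:
        raise ValidationError("ROI has no pixels")
    q = roi.pixel_area_mm2 * roi.velocities.sum(axis=0) * 0.01
    return FlowWaveform(z_mm=roi.z_mm, q_ml_s=q, period_s=roi.period_s)


def offset_correct(w: FlowWaveform) -> OffsetResult:
    """Remove the cycle-mean flow so the corrected waveform has zero net flow.

    Phases are uniform, so the cycle mean is the arithmetic mean.  The
    offset magnitude is also expressed relative to the arithmetic mean
    of |Q| after correction, the conventional QC number for
    eddy-current offsets.
    """
    offset = float(np.mean(w.q_ml_s))
    corrected = FlowWaveform(z_mm=w.z_mm, q_ml_s=w.q_ml_s - offset, period_s=w.period_s)
    denom = float(np.mean(np.abs(corrected.q_ml_s)))
    pct = abs(offset) / denom * 100.0 if denom > 0 else math.inf if offset else 0.0
    return OffsetResult(waveform=corrected, offset_ml_s=offset, offset_pct=pct)


def resample_cycle(w: FlowWaveform, period_s: float, n_phases: int | None = None) -> FlowWaveform:
    """Re-express the waveform on uniform phases of a cycle of ``period_s``.

    The time axis is scaled t -> t * (T_target / T) (heart-rate
    normalization), which leaves normalized phase untouched; amplitudes
    are unchanged.  With the same phase count this is a pure relabeling
    of the period; a different count uses periodic linear interpolation
    in normalized phase.
    """
    if period_s <= 0:
        raise ValidationError("target period must be positive")
    n_out = w.n_phases if n_phases is None else int(n_phases)
    if n_out == w.n_phases:
        q = w.q_ml_s.copy()
    else:
        phase_in = np.arange(w.n_phases + 1) / w.n_phases
        q_in = np.append(w.q_ml_s, w.q_ml_s[0])  # periodic closure
        phase_out = np.arange(n_out) / n_out
        q = np.interp(phase_out, phase_in, q_in)
    return FlowWaveform(z_mm=w.z_mm, q_ml_s=q, period_s=float(period_s))


def _sv_trapezoid_periodic(q: np.ndarray, period_s: float) -> float:
    # uniform phases + periodic wrap: trapezoid degenerates to mean * T
    dt = period_s / q.size
    wrapped = np.append(np.abs(q), abs(q[0]))
    return float(np.trapezoid(wrapped, dx=dt))


def waveform_features(
    w: FlowWaveform,
    a_sas_mm2: float,
    fluid: FluidProperties = CSF_DEFAULT,
    d_h_mm: float | None = None,
    sv_half: bool = False,
) -> WaveformFeatures:
    """Features of one offset-corrected waveform at local geometry.

    Area-dependent quantities are NaN when A_sas <= 0, and Re/alpha are
    NaN when D_h is missing or <= 0 (undefined-value markers that
    downstream statistics exclude).
    """
    q = w.q_ml_s
    q_sys = float(np.min(q))
    q_dia = float(np.max(q))
    q_a = q_dia - q_sys
    sv = _sv_trapezoid_periodic(q, w.period_s)
    if sv_half:
        sv *= 0.5

    nu = fluid.nu_m2_s
    if a_sas_mm2 is None or a_sas_mm2 <= 0:
        logger.info("A_sas <= 0 at z=%.1f mm: velocity features undefined", w.z_mm)
        u_sys = u_dia = re = math.nan
    else:
        # ml/s per mm^2 = 1000 mm/s per ... -> 1 ml/s / 1 mm^2 = 100 cm/s
        u_sys = 100.0 * q_sys / a_sas_mm2
        u_dia = 100.0 * q_dia / a_sas_mm2
        re = math.nan

    if d_h_mm is None or d_h_mm <= 0 or not math.isfinite(d_h_mm):
        if d_h_mm is not None and not (d_h_mm > 0):
            logger.info("D_h invalid at z=%.1f mm: Re and alpha undefined", w.z_mm)
        alpha = math.nan
    else:
        alpha = (d_h_mm * 1e-3 / 2.0) * math.sqrt(w.omega / nu)
        if not math.isnan(u_sys):
            re = abs(u_sys) * 1e-2 * d_h_mm * 1e-3 / nu

    return WaveformFeatures(
        q_sys=q_sys, q_dia=q_dia, q_a=q_a, sv=sv,
        u_sys=u_sys, u_dia=u_dia, re=re, alpha=alpha,
    )
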