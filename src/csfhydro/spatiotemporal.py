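"""Spatio-temporal fusion of per-slice waveforms and pulse wave velocity.

Flow is measured at a handful of axial planes; a bivariate smoothing
spline over (z, t) turns those slices into a continuous Q(z, t) surface
sampled every 1 mm.  Time is handled periodically (the fitted block is
flanked by shifted copies of the cycle) and each interpolated z-row is
re-offset to zero mean, so the zero-net-flow property survives
smoothing.

The cardiac pulse drives a flow wave that travels caudally.  Its speed
(pulse wave velocity, PWV) is estimated from the arrival time of peak
systolic (most negative) flow at each z: arrival times are refined to
sub-phase precision with a 3-point parabola, unwrapped across the
cycle, and regressed against z by ordinary least squares; PWV = 1/slope.
PWV is inversely related to the compliance of the intrathecal space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RectBivariateSpline
from scipy.stats import linregress

from .errors import ValidationError
from .flow import CSF_DEFAULT, FlowWaveform, FluidProperties, waveform_features
from .geometry import GeometricProfile

logger = logging.getLogger(__name__)

__all__ = [
    "SpatioTemporalFlow",
    "ArrivalCurve",
    "PulseWave",
    "HydrodynamicProfile",
    "fit_spatiotemporal",
    "peak_arrival",
    "arrival_from_waveforms",
    "pulse_wave_velocity",
    "hydrodynamic_profile",
]


@dataclass
class SpatioTemporalFlow:
    """Q(z, t) surface on a uniform 1-mm x n-phase grid within the data span."""

    z: np.ndarray           # mm, uniform
    t: np.ndarray           # s, uniform phases on [0, T)
    q: np.ndarray           # (nz, nt) ml/s
    period_s: float
    smoothing: float        # spline smoothing actually used
    source_z: np.ndarray    # z of the fitted slices

    def row(self, i: int) -> FlowWaveform:
        return FlowWaveform(z_mm=float(self.z[i]), q_ml_s=self.q[i], period_s=self.period_s)

    def to_long_frame(self):
        """Long-format (z, t, Q) table for heatmap-style plotting."""
        import pandas as pd

        zz, tt = np.meshgrid(self.z, self.t, indexing="ij")
        return pd.DataFrame({"z": zz.ravel(), "t": tt.ravel(), "q": self.q.ravel()})


@dataclass
class ArrivalCurve:
    """Time of peak systolic flow per z; NaN where the row is flat."""

    z: np.ndarray
    t_arrival: np.ndarray
    valid: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.isfinite(self.t_arrival)


@dataclass
class PulseWave:
    """OLS fit of arrival time vs z and the implied wave speed."""

    slope_s_per_mm: float
    intercept_s: float
    pwv_m_s: float          # NaN when the arrival curve is flat (standing wave)
    r_squared: float
    z_range: tuple[float, float]
    n_points: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.pwv_m_s)


def _fit_surface(z, t_pad, q_pad, s, kx):
    return RectBivariateSpline(z, t_pad, q_pad, kx=kx, ky=3, s=s)


def fit_spatiotemporal(
    waveforms: list[FlowWaveform],
    dz: float = 1.0,
    smoothing: float | None = None,
) -> SpatioTemporalFlow:
    """Fit a smoothing-spline surface Q(z, t) through per-slice waveforms.

    All waveforms must already share one cycle (same period and phase
    count; see :func:`csfhydro.flow.resample_cycle`).  The surface is
    evaluated on a ``dz``-spaced z grid spanning the measured slices
    only (no extrapolation) and the original phase grid.

    ``smoothing`` is the spline residual budget ``s`` of the underlying
    FITPACK fit; ``None`` selects it by leave-one-slice-out cross
    validation over a small grid (including 0 = pure interpolation) and
    logs the choice.
    """
    if len(waveforms) < 3:
        raise ValidationError("need at least 3 slices to fit a surface")
    z_src = np.array([w.z_mm for w in waveforms], dtype=float)
    if np.unique(z_src).size != z_src.size:
        raise ValidationError("duplicate slice z-positions")
    order = np.argsort(z_src)
    z_src = z_src[order]
    ws = [waveforms[i] for i in order]
    n_phases = ws[0].n_phases
    period = ws[0].period_s
    for w in ws:
        if w.n_phases != n_phases or abs(w.period_s - period) > 1e-9:
            raise ValidationError(
                "waveforms must share one cycle; resample to a common period first"
            )
    q_src = np.stack([w.q_ml_s for w in ws])  # (nz, nt)

    t = np.arange(n_phases) * (period / n_phases)
    # periodic handling: fit the cycle flanked by shifted copies
    t_pad = np.concatenate([t - period, t, t + period])
    q_pad = np.tile(q_src, (1, 3))
    kx = min(3, len(ws) - 1)

    if smoothing is None:
        smoothing = _cross_validate_smoothing(z_src, t_pad, q_pad, t, kx)
        logger.info("smoothing selected by leave-one-slice-out CV: s=%.4g", smoothing)

    spline = _fit_surface(z_src, t_pad, q_pad, smoothing, kx)
    z_grid = np.arange(z_src[0], z_src[-1] + 1e-9, dz)
    q = spline(z_grid, t)
    q -= q.mean(axis=1, keepdims=True)  # restore zero net flow per row
    return SpatioTemporalFlow(
        z=z_grid, t=t, q=q, period_s=period, smoothing=float(smoothing), source_z=z_src
    )


def _cross_validate_smoothing(z_src, t_pad, q_pad, t, kx) -> float:
    """Leave-one-interior-slice-out CV over a small multiplicative s grid."""
    nz = len(z_src)
    interior = list(range(1, nz - 1))
    scale = q_pad.size * float(np.var(q_pad))
    candidates = [0.0] + [scale * f for f in (1e-5, 1e-4, 1e-3, 3e-3, 1e-2, 3e-2)]
    if nz - 1 < max(kx + 1, 4) or not interior:
        return 0.0
    best, best_err = 0.0, np.inf
    for s in candidates:
        errs = []
        for hold in interior:
            keep = [i for i in range(nz) if i != hold]
            try:
                sp = _fit_surface(z_src[keep], t_pad, q_pad[keep], s,
                                  min(kx, len(keep) - 1))
            except Exception:
                errs = None
                break
            pred = sp(z_src[hold:hold + 1], t)[0]
            errs.append(np.mean((pred - q_pad[hold, len(t):2 * len(t)]) ** 2))
        if errs is None:
            continue
        err = float(np.mean(errs))
        if err < best_err:
            best, best_err = s, err
    return best


def _refined_minimum_time(row: np.ndarray, period_s: float) -> float:
    """Time of the discrete minimum refined by a periodic 3-point parabola."""
    nt = row.size
    dt = period_s / nt
    k = int(np.argmin(row))  # first occurrence = earliest-phase tie-break
    y1, y2, y3 = row[(k - 1) % nt], row[k], row[(k + 1) % nt]
    denom = y1 - 2.0 * y2 + y3
    delta = 0.5 * (y1 - y3) / denom if denom > 0 else 0.0
    delta = float(np.clip(delta, -0.5, 0.5))
    return ((k + delta) * dt) % period_s


def arrival_from_waveforms(waveforms: list[FlowWaveform],
                           rel_tol: float = 1e-12) -> ArrivalCurve:
    """Peak-systolic arrival times at the measured slice locations.

    Same minimum-plus-parabola refinement as :func:`peak_arrival`, applied
    to the per-slice waveforms themselves.  Between widely spaced slices
    an interpolated surface blends time-shifted pulses, which perturbs
    the location of interpolated minima; the measured slices carry the
    undistorted timing, so this curve is what the PWV fit should use.
    """
    z = np.array([w.z_mm for w in waveforms], dtype=float)
    order = np.argsort(z)
    z = z[order]
    ws = [waveforms[i] for i in order]
    period = ws[0].period_s
    scale = max(float(np.max(np.abs(w.q_ml_s))) for w in ws) or 1.0
    t_arr = np.full(z.size, np.nan)
    for i, w in enumerate(ws):
        if np.ptp(w.q_ml_s) > rel_tol * scale:
            t_arr[i] = _refined_minimum_time(w.q_ml_s, period)
    valid = np.isfinite(t_arr)
    if valid.sum() >= 2:
        t_arr[valid] = np.unwrap(t_arr[valid], period=period)
    return ArrivalCurve(z=z, t_arrival=t_arr, valid=valid)


def peak_arrival(stf: SpatioTemporalFlow, rel_tol: float = 1e-12) -> ArrivalCurve:
    """Arrival time of the systolic (minimum-Q) peak per z-row.

    The discrete minimum (ties broken toward the earliest phase) is
    refined by a 3-point parabola over the periodic neighbours, then
    unwrapped across z so the curve is continuous modulo the cycle.
    Flat rows yield NaN and are excluded from the PWV fit.
    """
    scale = float(np.max(np.abs(stf.q))) or 1.0
    t_arr = np.full(stf.z.size, np.nan)
    for i, row in enumerate(stf.q):
        if np.ptp(row) > rel_tol * scale:
            t_arr[i] = _refined_minimum_time(row, stf.period_s)
    valid = np.isfinite(t_arr)
    if valid.sum() >= 2:
        t_arr[valid] = np.unwrap(t_arr[valid], period=stf.period_s)
    return ArrivalCurve(z=stf.z.copy(), t_arrival=t_arr, valid=valid)


def pulse_wave_velocity(
    arrival: ArrivalCurve,
    z_range: tuple[float, float] | None = None,
    slope_tol: float = 1e-9,
) -> PulseWave:
    """PWV from the OLS slope of arrival time vs z over ``z_range``.

    Defaults to the full measured span (FM to the most caudal slice).
    Time is regressed on z (z is the controlled variable); PWV =
    1/slope, converted to m/s.  A slope at or below ``slope_tol`` s/mm
    (standing wave) flags PWV as undefined rather than raising.
    """
    mask = arrival.valid.copy()
    if z_range is not None:
        mask &= (arrival.z >= z_range[0]) & (arrival.z <= z_range[1])
    z = arrival.z[mask]
    t = arrival.t_arrival[mask]
    if z.size < 2:
        raise ValidationError("need at least 2 valid arrival points in range")
    fit = linregress(z, t)
    slope = float(fit.slope)
    pwv = 1.0 / slope / 1000.0 if slope > slope_tol else np.nan  # mm/s -> m/s
    if not np.isfinite(pwv):
        logger.info("arrival-time slope %.3g s/mm at or below tolerance: PWV undefined", slope)
    return PulseWave(
        slope_s_per_mm=slope,
        intercept_s=float(fit.intercept),
        pwv_m_s=float(pwv),
        r_squared=float(fit.rvalue) ** 2,
        z_range=(float(z.min()), float(z.max())),
        n_points=int(z.size),
    )


@dataclass
class HydrodynamicProfile:
    """Per-z hydrodynamic parameters on the same grid discipline as geometry."""

    z: np.ndarray
    sv: np.ndarray
    q_sys: np.ndarray
    q_dia: np.ndarray
    q_a: np.ndarray
    u_sys: np.ndarray
    u_dia: np.ndarray
    re: np.ndarray
    alpha: np.ndarray

    def __len__(self) -> int:
        return self.z.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "z": self.z, "sv": self.sv,
                "q_sys": self.q_sys, "q_dia": self.q_dia, "q_a": self.q_a,
                "u_sys": self.u_sys, "u_dia": self.u_dia,
                "re": self.re, "alpha": self.alpha,
            }
        )


def hydrodynamic_profile(
    stf: SpatioTemporalFlow,
    geom: GeometricProfile,
    fluid: FluidProperties = CSF_DEFAULT,
    sv_half: bool = False,
) -> HydrodynamicProfile:
    """Per-1-mm waveform features using the local SAS area and hydraulic diameter.

    Evaluated on the overlap of the flow surface's and the geometric
    profile's z grids.
    """
    zg = np.round(geom.z, 6)
    zf = np.round(stf.z, 6)
    common, gi, fi = np.intersect1d(zg, zf, return_indices=True)
    if common.size == 0:
        raise ValidationError("geometry and flow z-grids do not overlap")
    a_sas = geom.a_sas[gi]
    d_h = geom.d_h[gi]
    feats = [
        waveform_features(
            stf.row(int(j)), a_sas_mm2=float(a_sas[k]), fluid=fluid,
            d_h_mm=float(d_h[k]) if np.isfinite(d_h[k]) else None, sv_half=sv_half,
        )
        for k, j in enumerate(fi)
    ]
    arr = lambda name: np.array([getattr(f, name) for f in feats], dtype=float)
    return HydrodynamicProfile(
        z=common.astype(float),
        sv=arr("sv"), q_sys=arr("q_sys"), q_dia=arr("q_dia"), q_a=arr("q_a"),
        u_sys=arr("u_sys"), u_dia=arr("u_dia"), re=arr("re"), alpha=arr("alpha"),
    )
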