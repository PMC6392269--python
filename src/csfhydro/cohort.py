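"""Cohort statistics, length normalization, reliability, vertebral lookup.

Subjects differ in subarachnoid-space length, so axial profiles are
compared after linearly rescaling each subject's z-axis to the cohort
mean length and resampling at 1 mm.  Cohort summaries report, per
parameter, the pointwise mean +/- sd profile and three scalars: the
z-average of the mean profile and its extrema along the spine (totals
such as volumes are averaged as scalars instead).  Because profiles
can be steep right at the foramen magnum, extrema are also reported
with the first 5 mm omitted.

Test-retest reliability pools (baseline, follow-up) pairs over subjects
and all axial locations per parameter and fits ordinary least squares;
R^2 is symmetric under swapping the axes, the slope is not (follow-up
is regressed on baseline).

A reference chart maps axial distance below the foramen magnum to
vertebral levels for the cynomolgus monkey; other species can supply
their own table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

from .errors import ValidationError

__all__ = [
    "VertebralTable",
    "CYNOMOLGUS_VERTEBRAL_TABLE",
    "ParameterSummary",
    "CohortSummary",
    "ReliabilityResult",
    "normalize_length",
    "cohort_stats",
    "scalar_stats",
    "reliability_regression",
    "vertebral_lookup",
]


@dataclass
class VertebralTable:
    """Ordered vertebral-level labels with mean +/- sd axial position (mm)."""

    labels: list[str]
    z_mean: np.ndarray
    z_sd: np.ndarray

    def __post_init__(self) -> None:
        self.z_mean = np.asarray(self.z_mean, dtype=float)
        self.z_sd = np.asarray(self.z_sd, dtype=float)
        if not (len(self.labels) == self.z_mean.size == self.z_sd.size):
            raise ValidationError("labels and positions must have equal length")
        if np.any(np.diff(self.z_mean) <= 0):
            raise ValidationError("mean z must be strictly increasing")


# Disk locations (mm caudal of the foramen magnum) for the cynomolgus
# monkey, mean +/- sd across animals.
CYNOMOLGUS_VERTEBRAL_TABLE = VertebralTable(
    labels=["FM", "C1", "C2", "C3", "C4", "C5", "C6", "C7",
            "T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8", "T9", "T10", "T11", "T12",
            "L1", "L2", "L3", "L4", "L5", "Sacrum", "coccyx"],
    z_mean=[0.0, 5.7, 10.3, 22.3, 29.0, 35.2, 42.2, 48.7,
            56.1, 63.4, 72.0, 79.8, 88.5, 97.9, 107.4, 117.6, 128.8, 141.4, 156.3, 172.0,
            189.6, 207.5, 227.1, 247.0, 268.9, 289.4, 301.0],
    z_sd=[0.0, 2.4, 2.6, 3.9, 3.6, 3.8, 3.4, 3.8,
          4.2, 4.4, 4.2, 4.2, 4.5, 4.9, 4.5, 4.8, 4.5, 5.4, 5.0, 5.1,
          5.4, 5.8, 6.8, 7.0, 6.2, 6.7, 6.8],
)


def normalize_length(
    z: np.ndarray,
    values: np.ndarray,
    l_subject: float,
    l_mean: float,
    dz: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale a subject's z-axis to the cohort mean length and resample.

    z' = z * (l_mean / l_subject); values are linearly interpolated onto
    a ``dz``-spaced grid on [0, l_mean].  Only positions change; values
    (hence profile extrema) are preserved wherever grid nodes align.
    """
    if l_subject <= 0 or l_mean <= 0:
        raise ValidationError("lengths must be positive")
    z = np.asarray(z, dtype=float)
    values = np.asarray(values, dtype=float)
    z_scaled = z * (l_mean / l_subject)
    z_out = np.arange(0.0, l_mean + 1e-9, dz)
    return z_out, np.interp(z_out, z_scaled, values)


@dataclass
class ParameterSummary:
    """Mean +/- sd profile and spine-wise scalars for one parameter."""

    name: str
    z: np.ndarray
    mean_profile: np.ndarray
    sd_profile: np.ndarray
    average: float          # z-mean of the mean profile
    maximum: float          # extrema of the mean profile over z
    minimum: float
    maximum_no_fm: float    # extrema omitting the first 5 mm below the FM
    minimum_no_fm: float
    n_subjects: int


@dataclass
class CohortSummary:
    parameters: dict[str, ParameterSummary]

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "parameter": p.name, "average": p.average,
                "maximum": p.maximum, "minimum": p.minimum,
                "maximum_no_fm": p.maximum_no_fm, "minimum_no_fm": p.minimum_no_fm,
                "n": p.n_subjects,
            }
            for p in self.parameters.values()
        ]
        return pd.DataFrame(rows)


def cohort_stats(
    profiles: dict[str, np.ndarray],
    z: np.ndarray,
    fm_omit_mm: float = 5.0,
) -> CohortSummary:
    """Pointwise mean/sd and spine-wise scalars per parameter.

    ``profiles`` maps a parameter name to a (n_subjects, n_z) array on
    the common normalized grid.  The scalar ``average`` is the z-mean of
    the cross-subject mean profile; ``maximum``/``minimum`` are that mean
    profile's extrema along the spine (also reported with the first
    ``fm_omit_mm`` millimetres omitted).  Sample (n-1) sd; NaNs mark
    undefined values and are excluded pointwise.
    """
    z = np.asarray(z, dtype=float)
    out: dict[str, ParameterSummary] = {}
    for name, mat in profiles.items():
        mat = np.atleast_2d(np.asarray(mat, dtype=float))
        if mat.shape[1] != z.size:
            raise ValidationError(f"{name}: profile grid does not match z (got {mat.shape})")
        mean = np.nanmean(mat, axis=0)
        sd = (np.nanstd(mat, axis=0, ddof=1) if mat.shape[0] > 1
              else np.zeros_like(mean))
        inner = z >= fm_omit_mm
        finite = np.isfinite(mean)
        if not np.any(inner & finite):  # short profile: nothing below the FM zone
            inner = np.ones_like(inner, dtype=bool)
        out[name] = ParameterSummary(
            name=name, z=z, mean_profile=mean, sd_profile=sd,
            average=float(np.nanmean(mean)),
            maximum=float(np.nanmax(mean)),
            minimum=float(np.nanmin(mean)),
            maximum_no_fm=float(np.nanmax(mean[inner & finite])),
            minimum_no_fm=float(np.nanmin(mean[inner & finite])),
            n_subjects=int(mat.shape[0]),
        )
    return CohortSummary(parameters=out)


def scalar_stats(values: np.ndarray) -> tuple[float, float, float]:
    """(mean, max, min) across subjects for whole-spine totals."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("no values")
    return float(np.nanmean(v)), float(np.nanmax(v)), float(np.nanmin(v))


@dataclass
class ReliabilityResult:
    """Follow-up vs baseline OLS per parameter, pooled over subjects x z."""

    slope: dict[str, float]
    intercept: dict[str, float]
    r_squared: dict[str, float]
    n_points: dict[str, int]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "parameter": list(self.slope),
                "slope": list(self.slope.values()),
                "intercept": list(self.intercept.values()),
                "r_squared": list(self.r_squared.values()),
                "n": list(self.n_points.values()),
            }
        )


def reliability_regression(
    baseline: dict[str, np.ndarray],
    followup: dict[str, np.ndarray],
) -> ReliabilityResult:
    """OLS of follow-up on baseline, pooling subjects and axial locations.

    Arrays are (n_subjects, n_z) per parameter, matched subject order
    and common grid.  Pairs with a NaN on either side are dropped;
    fewer than 3 surviving pairs is an error.
    """
    slope, intercept, r2, npts = {}, {}, {}, {}
    for name, base in baseline.items():
        if name not in followup:
            raise ValidationError(f"parameter {name!r} missing from follow-up")
        b = np.asarray(base, dtype=float).ravel()
        f = np.asarray(followup[name], dtype=float).ravel()
        if b.size != f.size:
            raise ValidationError(f"{name}: baseline/follow-up sizes differ")
        ok = np.isfinite(b) & np.isfinite(f)
        if ok.sum() < 3:
            raise ValidationError(f"{name}: fewer than 3 valid baseline/follow-up pairs")
        fit = linregress(b[ok], f[ok])
        slope[name] = float(fit.slope)
        intercept[name] = float(fit.intercept)
        r2[name] = float(fit.rvalue) ** 2
        npts[name] = int(ok.sum())
    return ReliabilityResult(slope=slope, intercept=intercept, r_squared=r2, n_points=npts)


def vertebral_lookup(z_mm: float, table: VertebralTable = CYNOMOLGUS_VERTEBRAL_TABLE) -> str:
    """Vertebral-level label whose tabulated mean z is nearest ``z_mm``.

    Ties resolve to the more cranial (earlier) level; negative z (above
    the FM) is rejected.
    """
    if z_mm < 0:
        raise ValidationError("z must be nonnegative (caudal of the FM)")
    dist = np.abs(table.z_mean - z_mm)
    return table.labels[int(np.argmin(dist))]  # argmin returns the first (cranial) tie
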