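"""Axial geometric profiles of the spinal subarachnoid space.

Cross-sections are taken on native image planes (slices are assumed
approximately perpendicular to the canal).  Per 1-mm z-location the
module measures cord and dura cross-sectional areas (pixel count x
pixel area) and perimeters (marching-squares contour length), derives
the SAS annulus quantities

    A_sas(z) = A_d(z) - A_c(z)
    P_sas(z) = P_c(z) + P_d(z)
    D_h(z)   = 4 A_sas(z) / P_sas(z)

and accumulates whole-spine totals: volumes as sum(A dz) and lateral
surface areas as sum(P dz).

Perimeters are contour lengths at the 0.5 level of the mask after a
light Gaussian blur (sigma = 1 px).  Contouring the raw binary mask
produces staircase polygons that overestimate a circle's perimeter by
up to ~8%; the blurred field restores sub-pixel placement and is
accurate to well under 1% for radii above ~8 px.  For very small
structures whose blurred peak falls below 0.5 the raw-mask contour is
used as a fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .errors import ValidationError
from .io import SegmentationVolume

logger = logging.getLogger(__name__)

__all__ = [
    "GeometricProfile",
    "GlobalGeometry",
    "slice_profiles",
    "hydraulic_diameter",
    "totals",
    "mask_perimeter",
    "surface_area_from_mesh",
]


@dataclass
class GeometricProfile:
    """Per-z geometric parameters on a uniform axial grid (mm, mm^2)."""

    z: np.ndarray        # mm caudal of FM, uniform, strictly increasing
    a_cord: np.ndarray   # mm^2
    a_dura: np.ndarray   # mm^2
    p_cord: np.ndarray   # mm
    p_dura: np.ndarray   # mm

    def __post_init__(self) -> None:
        for name in ("z", "a_cord", "a_dura", "p_cord", "p_dura"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.z.size and np.any(np.diff(self.z) <= 0):
            raise ValidationError("z grid must be strictly increasing")
        n = self.z.size
        for name in ("a_cord", "a_dura", "p_cord", "p_dura"):
            if getattr(self, name).size != n:
                raise ValidationError(f"{name} length must match the z grid")
        if np.any(self.a_dura - self.a_cord < -1e-9):
            raise ValidationError("A_sas = A_d - A_c must be nonnegative everywhere")

    @property
    def a_sas(self) -> np.ndarray:
        return self.a_dura - self.a_cord

    @property
    def p_sas(self) -> np.ndarray:
        return self.p_cord + self.p_dura

    @property
    def d_h(self) -> np.ndarray:
        """Hydraulic diameter 4A/P; NaN where the perimeter vanishes."""
        return hydraulic_diameter(self.a_sas, self.p_sas)

    @property
    def dz(self) -> float:
        if self.z.size < 2:
            raise ValidationError("profile needs at least two z points for a spacing")
        return float(self.z[1] - self.z[0])

    def __len__(self) -> int:
        return self.z.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z": self.z,
                "a_cord": self.a_cord, "a_dura": self.a_dura, "a_sas": self.a_sas,
                "p_cord": self.p_cord, "p_dura": self.p_dura, "p_sas": self.p_sas,
                "d_h": self.d_h,
            }
        )


@dataclass
class GlobalGeometry:
    """Whole-spine totals: lateral surface areas (cm^2), volumes (ml), length (mm)."""

    sa_cord: float
    sa_dura: float
    v_cord: float
    v_dura: float
    l_sas: float

    def __post_init__(self) -> None:
        if self.v_dura - self.v_cord <= 0:
            raise ValidationError("V_sas = V_d - V_c must be positive")
        if self.l_sas <= 0:
            raise ValidationError("L_sas must be positive")

    @property
    def sa_sas(self) -> float:
        return self.sa_cord + self.sa_dura

    @property
    def v_sas(self) -> float:
        return self.v_dura - self.v_cord


def mask_perimeter(mask: np.ndarray, spacing: tuple[float, float] = (1.0, 1.0),
                   sigma_px: float = 1.0) -> float:
    """Total iso-contour length (mm) of a binary in-plane mask.

    Marching squares at level 0.5 on the Gaussian-blurred mask; sums
    over all closed contours (an annular region contributes both its
    boundaries when passed as a single mask).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    field = ndimage.gaussian_filter(mask.astype(float), sigma_px)
    contours = measure.find_contours(field, 0.5)
    if not contours:  # structure thinner than the blur: fall back to raw mask
        contours = measure.find_contours(mask.astype(float), 0.5)
    total = 0.0
    scale = np.asarray(spacing, dtype=float)
    for contour in contours:
        steps = np.diff(contour, axis=0) * scale  # rows, cols -> physical mm
        total += float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))
    return total


def slice_profiles(seg: SegmentationVolume, dz: float = 1.0) -> GeometricProfile:
    """Measure areas and perimeters on axial planes every ``dz`` mm from the FM.

    The profile runs from the FM slice to the last plane with a nonempty
    dura mask; each requested z is served by the nearest native plane.
    A plane with dura but no cord (filum / caudal region) contributes
    A_c = P_c = 0.
    """
    if dz <= 0:
        raise ValidationError("dz must be positive")
    if not seg.dura_slice(seg.fm_index).any():
        raise ValidationError("dura mask empty at the FM slice")

    # caudal termination: last native plane with >= 1 dura pixel
    axial_any = np.any(
        seg.dura, axis=tuple(i for i in range(seg.dura.ndim) if i != seg.axial_axis)
    )
    last = int(np.max(np.nonzero(axial_any)[0]))
    z_max = seg.z_of(last)
    z_grid = np.arange(0.0, z_max + 1e-9, dz)

    spacing = seg.in_plane_spacing
    pixel_area = seg.pixel_area
    a_c = np.zeros_like(z_grid)
    a_d = np.zeros_like(z_grid)
    p_c = np.zeros_like(z_grid)
    p_d = np.zeros_like(z_grid)
    missing_cord = 0
    for i, z in enumerate(z_grid):
        k = seg.fm_index + int(round(z / seg.axial_spacing))
        k = min(k, seg.n_slices - 1)
        cord = seg.cord_slice(k)
        dura = seg.dura_slice(k)
        a_d[i] = np.count_nonzero(dura) * pixel_area
        p_d[i] = mask_perimeter(dura, spacing)
        if cord.any():
            a_c[i] = np.count_nonzero(cord) * pixel_area
            p_c[i] = mask_perimeter(cord, spacing)
        elif dura.any():
            missing_cord += 1
    if missing_cord:
        logger.info(
            "cord absent at %d plane(s) with dura present (filum/caudal region); "
            "A_c = P_c = 0 there", missing_cord,
        )
    return GeometricProfile(z=z_grid, a_cord=a_c, a_dura=a_d, p_cord=p_c, p_dura=p_d)


def hydraulic_diameter(a_sas, p_sas):
    """D_h = 4 A_sas / P_sas (mm); NaN where P_sas <= 0 (excluded downstream)."""
    a = np.asarray(a_sas, dtype=float)
    p = np.asarray(p_sas, dtype=float)
    if np.any(a < 0):
        raise ValidationError("A_sas must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(p > 0, 4.0 * a / np.where(p > 0, p, 1.0), np.nan)
    n_bad = int(np.count_nonzero(~(p > 0)))
    if n_bad:
        logger.info("hydraulic diameter undefined at %d location(s) with P_sas <= 0", n_bad)
    if np.isscalar(a_sas) and np.isscalar(p_sas):
        return float(d)
    return d


def totals(profile: GeometricProfile, dz: float | None = None) -> GlobalGeometry:
    """Whole-spine totals by the rectangle rule over the 1-mm profile.

    Volumes: V = sum(A dz) / 1000 (ml); lateral surface areas:
    SA = sum(P dz) / 100 (cm^2); L_sas = z_last - z_first (mm).
    """
    if len(profile) == 0:
        raise ValidationError("empty profile")
    step = profile.dz if dz is None else float(dz)
    return GlobalGeometry(
        sa_cord=float(np.sum(profile.p_cord) * step / 100.0),
        sa_dura=float(np.sum(profile.p_dura) * step / 100.0),
        v_cord=float(np.sum(profile.a_cord) * step / 1000.0),
        v_dura=float(np.sum(profile.a_dura) * step / 1000.0),
        l_sas=float(profile.z[-1] - profile.z[0]),
    )


def surface_area_from_mesh(path_or_mesh) -> float:
    """Surface area (cm^2) of an STL mesh in mm units; alternative to sum(P dz)."""
    import trimesh

    mesh = path_or_mesh
    if not isinstance(mesh, trimesh.Trimesh):
        mesh = trimesh.load(str(path_or_mesh), force="mesh")
    return float(mesh.area) / 100.0
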