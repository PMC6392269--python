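"""Readers and writers for the external formats the pipeline consumes and emits.

Units are fixed at this boundary: lengths mm, areas mm^2, volumes ml,
times s, velocities cm/s, flow rates ml/s.  All science lives in the
other modules; this one only parses, validates and round-trips.

Segmentation label volumes are NIfTI files with integer labels:
0 background, ``cord_label`` spinal cord, ``dura_label`` the remaining
dura-enclosed region (CSF space).  The dura-enclosed mask is the union
of the two labels, so the cord is a subset of it by construction;
cord voxels not enclosed by the CSF label in their slice are kept and
flagged with a warning.

Per-slice velocity exports are CSV files with header ``x,y,v00..vNN``
(pixel indices plus one through-plane velocity column per cardiac
phase, cm/s) accompanied by a JSON sidecar carrying the acquisition
metadata the scanner keeps in the image header: pixel area (mm^2),
R-R interval (ms), slice position (mm caudal of the foramen magnum)
and optionally the velocity-encoding limit (cm/s).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationVolume",
    "VelocityROISeries",
    "StudyConfig",
    "read_segmentation",
    "write_segmentation",
    "read_velocity_csv",
    "write_velocity_csv",
    "write_profiles",
    "read_profiles",
    "read_s1_table",
]


@dataclass
class SegmentationVolume:
    """Segmented spinal canal: cord and dura-enclosed boolean masks.

    The axial (slice) axis runs caudally: slice index ``fm_index`` is the
    foramen magnum (z = 0) and z increases toward the sacrum as
    ``(index - fm_index) * spacing[axial_axis]``.
    """

    cord: np.ndarray          # bool, same shape as dura
    dura: np.ndarray          # bool, dura-enclosed region including cord
    spacing: tuple[float, float, float]  # mm per axis
    axial_axis: int = 2
    fm_index: int = 0

    def __post_init__(self) -> None:
        self.cord = np.asarray(self.cord, dtype=bool)
        self.dura = np.asarray(self.dura, dtype=bool)
        if self.cord.shape != self.dura.shape:
            raise ValidationError("cord and dura masks must share a shape")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"voxel spacing must be positive, got {self.spacing}")
        if not (0 <= self.axial_axis < self.cord.ndim):
            raise ValidationError("axial_axis out of range")
        n = self.cord.shape[self.axial_axis]
        if not (0 <= self.fm_index < n):
            raise ValidationError(f"FM slice index {self.fm_index} outside volume (n={n})")
        if np.any(self.cord & ~self.dura):
            # enforce the containment invariant rather than reject
            self.dura = self.dura | self.cord

    @property
    def n_slices(self) -> int:
        return self.cord.shape[self.axial_axis]

    @property
    def axial_spacing(self) -> float:
        return float(self.spacing[self.axial_axis])

    @property
    def in_plane_spacing(self) -> tuple[float, float]:
        sp = [s for i, s in enumerate(self.spacing) if i != self.axial_axis]
        return (float(sp[0]), float(sp[1]))

    @property
    def pixel_area(self) -> float:
        """In-plane pixel area (mm^2)."""
        a, b = self.in_plane_spacing
        return a * b

    def z_of(self, index: int) -> float:
        """Axial position (mm caudal of FM) of slice ``index``."""
        return (index - self.fm_index) * self.axial_spacing

    def cord_slice(self, index: int) -> np.ndarray:
        return np.take(self.cord, index, axis=self.axial_axis)

    def dura_slice(self, index: int) -> np.ndarray:
        return np.take(self.dura, index, axis=self.axial_axis)


@dataclass
class VelocityROISeries:
    """Cardiac-phase-resolved through-plane velocities for one ROI.

    ``velocities`` has shape (n_pixels, n_phases) in cm/s; phases are
    uniform samples of one cardiac cycle of period ``period_s``.
    """

    z_mm: float
    pixel_area_mm2: float
    pixel_xy: np.ndarray       # (n_pixels, 2) integer in-plane indices
    velocities: np.ndarray     # (n_pixels, n_phases) cm/s
    period_s: float
    venc_cm_s: float | None = None

    def __post_init__(self) -> None:
        self.pixel_xy = np.asarray(self.pixel_xy, dtype=int)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.velocities.ndim != 2 or self.velocities.shape[0] < 1:
            raise ValidationError("ROI must contain at least one pixel")
        if self.pixel_xy.shape != (self.velocities.shape[0], 2):
            raise ValidationError("pixel_xy must be (n_pixels, 2) and match velocities")
        if self.period_s <= 0:
            raise ValidationError(f"cycle period must be positive, got {self.period_s}")
        if self.pixel_area_mm2 <= 0:
            raise ValidationError("pixel area must be positive")

    @property
    def n_pixels(self) -> int:
        return self.velocities.shape[0]

    @property
    def n_phases(self) -> int:
        return self.velocities.shape[1]


@dataclass
class StudyConfig:
    """Paths and analysis options for one subject/session."""

    subject_id: str
    session: str = "baseline"          # "baseline" | "follow-up"
    segmentation_path: str | None = None
    velocity_paths: list[tuple[str, str]] = field(default_factory=list)  # (csv, sidecar)
    label_map: dict[str, int] = field(default_factory=lambda: {"cord": 1, "dura": 2})
    dz_mm: float = 1.0
    sv_half: bool = False
    smoothing: float | None = None     # None -> cross-validated
    viscosity_mpa_s: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dz_mm <= 0:
            raise ValidationError("dz_mm must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["velocity_paths"] = [tuple(p) for p in raw.get("velocity_paths", [])]
        return cls(**raw)


def read_segmentation(
    path: str | Path,
    label_map: dict[str, int] | None = None,
    axial_axis: int = 2,
    fm_index: int = 0,
) -> SegmentationVolume:
    """Load a NIfTI label volume into cord/dura masks.

    ``label_map`` assigns the ``cord`` and ``dura`` roles to integer
    labels (default ``{"cord": 1, "dura": 2}``).  The dura-enclosed mask
    is the union of both labels; cord voxels not surrounded by the dura
    label in their slice are reported with a warning but kept in both
    masks.
    """
    label_map = label_map or {"cord": 1, "dura": 2}
    for role in ("cord", "dura"):
        if role not in label_map:
            raise ValidationError(f"label_map must assign the {role!r} role")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several types
        raise FormatError(f"could not read NIfTI label volume {path}: {exc}") from exc
    labels = np.rint(data).astype(int)
    cord = labels == label_map["cord"]
    dura_only = labels == label_map["dura"]
    if not cord.any():
        raise ValidationError(f"no voxels carry the cord label {label_map['cord']} in {path}")
    if not dura_only.any():
        raise ValidationError(f"no voxels carry the dura label {label_map['dura']} in {path}")
    dura = dura_only | cord

    # flag cord voxels that the dura label does not enclose in-plane
    stray = 0
    enclosed = ndimage.binary_fill_holes(
        dura_only, structure=_in_plane_structure(dura_only.ndim, axial_axis)
    )
    stray = int(np.count_nonzero(cord & ~enclosed))
    if stray:
        logger.warning(
            "%d cord voxel(s) outside the dura-enclosed region; added to the dura mask", stray
        )

    zooms = img.header.get_zooms()[:3]
    return SegmentationVolume(
        cord=cord,
        dura=dura,
        spacing=tuple(float(z) for z in zooms),
        axial_axis=axial_axis,
        fm_index=fm_index,
    )


def _in_plane_structure(ndim: int, axial_axis: int) -> np.ndarray:
    """4-connectivity structuring element confined to planes ⟂ axial axis."""
    structure = ndimage.generate_binary_structure(ndim, 1)
    sl = [slice(None)] * ndim
    for off in (0, 2):
        sl[axial_axis] = off
        structure[tuple(sl)] = False
    return structure


def write_segmentation(seg: SegmentationVolume, path: str | Path,
                       label_map: dict[str, int] | None = None) -> None:
    """Write cord/dura masks back to a NIfTI label volume."""
    label_map = label_map or {"cord": 1, "dura": 2}
    labels = np.zeros(seg.cord.shape, dtype=np.int16)
    labels[seg.dura] = label_map["dura"]
    labels[seg.cord] = label_map["cord"]
    affine = np.diag(list(seg.spacing) + [1.0])
    nib.save(nib.Nifti1Image(labels, affine), str(path))


_VCOL = re.compile(r"^v(\d{2,})$")


def read_velocity_csv(path: str | Path, sidecar: str | Path) -> VelocityROISeries:
    """Parse a per-slice pixel-velocity CSV plus its JSON metadata sidecar.

    The CSV must have header ``x,y,v00..vNN`` with velocities in cm/s;
    the sidecar provides ``pixel_area_mm2``, ``rr_interval_ms`` and
    ``slice_z_mm`` (optionally ``venc_cm_s``).
    """
    try:
        table = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"could not parse velocity CSV {path}: {exc}") from exc
    cols = list(table.columns)
    if cols[:2] != ["x", "y"]:
        raise FormatError(f"{path}: expected leading columns 'x,y', got {cols[:2]}")
    vcols = [c for c in cols[2:] if _VCOL.match(c)]
    if len(vcols) != len(cols) - 2 or not vcols:
        raise FormatError(f"{path}: velocity columns must be contiguous v00..vNN")
    idx = sorted(int(_VCOL.match(c).group(1)) for c in vcols)
    if idx != list(range(len(vcols))):
        raise FormatError(f"{path}: missing velocity phase column (found v{idx})")
    if table[vcols].isna().any().any():
        raise FormatError(f"{path}: ragged rows / missing velocity values")

    with open(sidecar) as fh:
        meta = json.load(fh)
    for key in ("pixel_area_mm2", "rr_interval_ms", "slice_z_mm"):
        if key not in meta:
            raise FormatError(f"{sidecar}: missing metadata key {key!r}")
    if "n_phases" in meta and int(meta["n_phases"]) != len(vcols):
        raise FormatError(
            f"{path}: {len(vcols)} velocity columns but sidecar declares "
            f"{meta['n_phases']} cardiac phases"
        )
    rr = float(meta["rr_interval_ms"])
    if rr <= 0:
        raise ValidationError(f"{sidecar}: nonpositive R-R interval {rr} ms")

    return VelocityROISeries(
        z_mm=float(meta["slice_z_mm"]),
        pixel_area_mm2=float(meta["pixel_area_mm2"]),
        pixel_xy=table[["x", "y"]].to_numpy(dtype=int),
        velocities=table[vcols].to_numpy(dtype=float),
        period_s=rr / 1000.0,
        venc_cm_s=float(meta["venc_cm_s"]) if meta.get("venc_cm_s") is not None else None,
    )


def write_velocity_csv(series: VelocityROISeries, path: str | Path,
                       sidecar: str | Path) -> None:
    """Write a VelocityROISeries in the CSV + JSON sidecar dialect."""
    n = series.n_phases
    cols = {"x": series.pixel_xy[:, 0], "y": series.pixel_xy[:, 1]}
    for k in range(n):
        cols[f"v{k:02d}"] = series.velocities[:, k]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")
    meta = {
        "pixel_area_mm2": series.pixel_area_mm2,
        "rr_interval_ms": series.period_s * 1000.0,
        "slice_z_mm": series.z_mm,
        "venc_cm_s": series.venc_cm_s,
        "n_phases": n,
    }
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=1)


# column -> unit for the profile table written by write_profiles
_PROFILE_UNITS = {
    "z": "mm",
    "a_cord": "mm^2", "a_dura": "mm^2", "a_sas": "mm^2",
    "p_cord": "mm", "p_dura": "mm", "p_sas": "mm",
    "d_h": "mm",
    "sv": "ml", "q_sys": "ml/s", "q_dia": "ml/s", "q_a": "ml/s",
    "u_sys": "cm/s", "u_dia": "cm/s", "re": "-", "alpha": "-",
}


def write_profiles(path: str | Path, geometric=None, hydrodynamic=None) -> None:
    """Write axial profiles to CSV, one row per z, units in the header.

    Accepts a GeometricProfile, a HydrodynamicProfile, or both; when
    both are given they must share one z-grid.
    """
    frames = []
    for prof in (geometric, hydrodynamic):
        if prof is not None:
            frames.append(prof.to_frame())
    if not frames:
        raise ValidationError("nothing to write")
    if len(frames) == 2:
        if len(frames[0]) != len(frames[1]) or not np.allclose(
            frames[0]["z"], frames[1]["z"], atol=1e-9
        ):
            raise ValidationError("geometric and hydrodynamic profiles must share one z-grid")
        frames[1] = frames[1].drop(columns="z")
        table = pd.concat(frames, axis=1)
    else:
        table = frames[0]
    table.columns = [f"{c} [{_PROFILE_UNITS.get(c, '?')}]" for c in table.columns]
    table.to_csv(path, index=False, float_format="%.10g")


def read_profiles(path: str | Path) -> pd.DataFrame:
    """Read back a profile CSV written by :func:`write_profiles`."""
    table = pd.read_csv(path)
    table.columns = [c.split(" [")[0] for c in table.columns]
    return table


# sheet-name patterns -> canonical parameter keys for the deposited
# supplementary workbook (axial parameter distributions and waveforms
# for each animal at baseline and follow-up); layouts in the wild vary,
# so matching is case-insensitive and tolerant of separators.
_S1_PATTERNS: list[tuple[str, str]] = [
    (r"p[_ ]?c\b|perimeter.*cord", "p_cord"),
    (r"p[_ ]?d\b|perimeter.*dura", "p_dura"),
    (r"p[_ ]?sas|perimeter.*sas", "p_sas"),
    (r"a[_ ]?c\b|area.*cord", "a_cord"),
    (r"a[_ ]?d\b|area.*dura", "a_dura"),
    (r"a[_ ]?sas|area.*sas", "a_sas"),
    (r"d[_ ]?h|hydraulic", "d_h"),
    (r"\bre\b|reynolds", "re"),
    (r"alpha|womersley", "alpha"),
    (r"u[_ ]?sys|systol.*velocity|velocity.*sys", "u_sys"),
    (r"u[_ ]?dia|diastol.*velocity|velocity.*dia", "u_dia"),
    (r"q[_ ]?sys", "q_sys"),
    (r"q[_ ]?dia", "q_dia"),
    (r"q[_ ]?a\b|amplitude", "q_a"),
    (r"sv|stroke", "sv"),
    (r"flow|waveform|q[_ ]?t", "waveform"),
]


def read_s1_table(path: str | Path) -> dict[str, pd.DataFrame]:
    """Import the deposited supplementary XLSX workbook, one sheet per parameter.

    Each sheet is expected to carry an axial coordinate in its first
    column and one column per animal/session.  Sheets are mapped to
    canonical parameter keys by name pattern; unrecognized sheets are
    kept under their own (lower-cased) names.  The mapping is logged so
    layout surprises are visible.
    """
    try:
        book = pd.read_excel(path, sheet_name=None, engine="openpyxl")
    except Exception as exc:
        raise FormatError(f"could not read workbook {path}: {exc}") from exc
    out: dict[str, pd.DataFrame] = {}
    for sheet, frame in book.items():
        key = sheet.strip().lower()
        for pat, canonical in _S1_PATTERNS:
            if re.search(pat, key):
                key = canonical
                break
        if key in out:  # keep both on collision
            key = f"{key}_{sheet.strip().lower()}"
        frame = frame.dropna(axis=1, how="all").dropna(axis=0, how="all")
        out[key] = frame
        logger.info("S1 import: sheet %r -> %r (%d rows)", sheet, key, len(frame))
    return out
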