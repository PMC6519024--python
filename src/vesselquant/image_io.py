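"""Volumetric image and tabular I/O with explicit world-coordinate geometry.

All lengths are millimetres and all volumes millilitres/litres in world
space; voxel indices never leak into downstream metrics.  The geometry
convention is fixed package-wide:

* 0-based voxel indices, array axes ordered ``(x, y, z)`` with axis 2 the
  cranio-caudal axis (increasing index = caudal -> cranial);
* voxel-centre convention: world = origin + (index + 0.5) * spacing, i.e.
  ``origin`` is the *corner* of the grid, not the centre of voxel 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

#: label codes used in all label masks
LABEL_BACKGROUND = 0
LABEL_LUNG = 1
LABEL_AIRWAY = 2
LABEL_VESSEL = 3
LABEL_ARTERY = 4
LABEL_VEIN = 5

SEGMENTS_SCHEMA_VERSION = 1

#: canonical per-segment table columns (order matters for writing)
SEGMENT_COLUMNS = [
    "segment_id",
    "tree_id",
    "compartment",
    "zone",
    "arc_mm",
    "chord_mm",
    "distance_metric",
    "mean_diameter_mm",
    "volume_ml",
    "n_points",
    "schema_version",
]


class GeometryError(ValueError):
    """Raised for unsupported or inconsistent image geometry."""


@dataclass
class CtVolume:
    """A 3-D Hounsfield-unit scalar grid with world geometry.

    ``values[i, j, k]`` with k the cranio-caudal (z) index.  ``spacing`` and
    ``origin`` are mm per axis; ``origin`` is the corner of voxel (0,0,0).
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise GeometryError(f"expected a 3-D volume, got {self.values.ndim}-D")
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise GeometryError("spacing must be three strictly positive floats")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise GeometryError("HU values must be finite")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (fractional) voxel indices to world mm (voxel-centre convention)."""
        return self.origin + (np.asarray(idx, dtype=float) + 0.5) * self.spacing

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`index_to_world`; returns fractional indices."""
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing - 0.5


@dataclass
class LabelMask:
    """Integer label grid aligned to a :class:`CtVolume`."""

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise GeometryError("label mask must be 3-D")
        if not np.issubdtype(self.values.dtype, np.integer):
            self.values = self.values.astype(np.uint8)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self):
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def volume_l(self, label=None) -> float:
        """Volume of a label (or of all non-zero voxels) in litres."""
        sel = self.values > 0 if label is None else self.values == label
        return float(sel.sum()) * self.voxel_volume_mm3 / 1.0e6

    def index_to_world(self, idx):
        return self.origin + (np.asarray(idx, dtype=float) + 0.5) * self.spacing

    def world_to_index(self, xyz):
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing - 0.5


_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_direction(direction: tuple) -> None:
    d = np.asarray(direction).reshape(3, 3)
    off = d - np.diag(np.diag(d))
    if np.any(np.abs(off) > 1e-6):
        raise GeometryError(
            "only axis-aligned orientations are supported; got a rotated "
            "direction matrix — resample the image upstream"
        )


def read_volume(path) -> CtVolume:
    """Read a NIfTI or MetaImage scalar volume.

    Raises on missing files, non-3-D images, vector voxels and rotated
    orientation matrices (axis-aligned flips are accepted).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not str(path.name).endswith(_SUPPORTED_SUFFIXES):
        raise GeometryError(f"unsupported image format: {path.name}")
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise GeometryError(f"expected a 3-D image, got {img.GetDimension()}-D")
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise GeometryError("expected scalar voxels")
    _check_direction(img.GetDirection())
    # sitk arrays are (z, y, x); transpose to package (x, y, z) order
    values = sitk.GetArrayFromImage(img).T
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    centre0 = np.asarray(img.GetOrigin(), dtype=float)
    origin = centre0 - 0.5 * spacing  # corner convention
    return CtVolume(values=values, spacing=spacing, origin=origin)


def write_volume(vol, path) -> None:
    """Write a :class:`CtVolume` or :class:`LabelMask` to NIfTI/MetaImage."""
    path = Path(path)
    if not str(path.name).endswith(_SUPPORTED_SUFFIXES):
        raise GeometryError(f"unsupported image format: {path.name}")
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.values.T))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin + 0.5 * vol.spacing))
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))


def read_mask(path) -> LabelMask:
    vol = read_volume(path)
    return LabelMask(values=np.rint(vol.values).astype(np.uint8),
                     spacing=vol.spacing, origin=vol.origin)


def segments_to_frame(segments) -> pd.DataFrame:
    """Convert a sequence of VesselSegment-like objects to the canonical table."""
    rows = []
    for i, s in enumerate(segments):
        rows.append({
            "segment_id": getattr(s, "segment_id", i),
            "tree_id": s.tree_id,
            "compartment": s.compartment or "unlabelled",
            "zone": getattr(s, "zone", None) or "unassigned",
            "arc_mm": s.arc_mm,
            "chord_mm": s.chord_mm,
            "distance_metric": s.distance_metric,
            "mean_diameter_mm": s.mean_diameter_mm,
            "volume_ml": s.volume_ml,
            "n_points": len(s.points),
            "schema_version": SEGMENTS_SCHEMA_VERSION,
        })
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def write_segments_csv(segments, path) -> None:
    """Write the per-segment morphometry table (RFC 4180 CSV, '.' decimal)."""
    frame = segments if isinstance(segments, pd.DataFrame) else segments_to_frame(segments)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.17g")


def read_segments_csv(path) -> pd.DataFrame:
    """Read a per-segment table; unknown extra columns warn, missing ones raise."""
    frame = pd.read_csv(path)
    missing = [c for c in SEGMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"segment table schema mismatch, missing columns: {missing}")
    extra = [c for c in frame.columns if c not in SEGMENT_COLUMNS]
    if extra:
        warnings.warn(f"ignoring unknown segment-table columns: {extra}")
    return frame
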