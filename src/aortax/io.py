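"""Volume I/O and the core grid types.

Volumes are held in a fixed internal anatomical orientation (LPS: axis 0
increases towards the patient's left, axis 1 towards posterior, axis 2 towards
superior) with voxel arrays indexed ``(x, y, z)``.  Inputs in NIfTI or NRRD
are reoriented on read.  All geometry downstream is expressed in physical
millimetres: ``world = origin + index * spacing``; voxel indices only appear
inside rasterisation and resampling kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Set

import numpy as np
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "LabelVolume",
    "VOCABULARY",
    "read_image",
    "read_labels",
    "write_image",
    "write_labels",
]

#: TotalSegmentator-style structure names -> integer ids used by the phantom
#: generator and expected in input label maps.
VOCABULARY: Dict[str, int] = {
    "aorta": 1,
    "lv_blood": 2,
    "rv_blood": 3,
    "liver": 4,
    "kidney_left": 5,
    "kidney_right": 6,
    "brachiocephalic_trunk": 7,
    "left_common_carotid": 8,
    "left_subclavian": 9,
    "iliac_left": 10,
    "iliac_right": 11,
}

_ORIENTATION = "LPS"


@dataclass
class ImageVolume:
    """A scalar HU grid with physical geometry.

    ``voxels`` is indexed ``(x, y, z)``; ``spacing`` and ``origin`` are in mm.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    axis_orientation: str = _ORIENTATION

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"non-3D input: volume has {self.voxels.ndim} dimensions")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing.shape != (3,) or self.origin.shape != (3,):
            raise ValueError("spacing and origin must be length-3")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Continuous voxel index -> physical mm point(s)."""
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Physical mm point(s) -> continuous voxel index."""
        return (np.asarray(pts, dtype=float) - self.origin) / self.spacing

    def same_geometry(self, other: "ImageVolume", tol_mm: float = 1e-3) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol_mm)
            and np.allclose(self.origin, other.origin, atol=tol_mm)
        )


@dataclass
class LabelVolume:
    """Integer anatomy labels aligned to an :class:`ImageVolume` grid."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    vocabulary: Dict[str, int] = field(default_factory=lambda: dict(VOCABULARY))
    missing: Set[str] = field(default_factory=set)
    axis_orientation: str = _ORIENTATION

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"non-3D input: label map has {self.voxels.ndim} dimensions")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("label voxels must be integer")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def has(self, name: str) -> bool:
        return name in self.vocabulary and name not in self.missing

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of a named structure (all-false if missing)."""
        if name not in self.vocabulary:
            raise KeyError(f"unknown structure {name!r}")
        return self.voxels == self.vocabulary[name]

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=float) - self.origin) / self.spacing


# ---------------------------------------------------------------------------
# SimpleITK bridge

def _from_sitk(img: sitk.Image) -> tuple:
    if img.GetDimension() != 3:
        raise ValueError(f"non-3D input: image has {img.GetDimension()} dimensions")
    img = sitk.DICOMOrient(img, _ORIENTATION)
    arr = sitk.GetArrayFromImage(img)          # (z, y, x)
    arr = np.ascontiguousarray(arr.transpose(2, 1, 0))
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    origin = np.asarray(img.GetOrigin(), dtype=float)
    return arr, spacing, origin


def _to_sitk(voxels: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(voxels.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def read_image(path: "str | Path") -> ImageVolume:
    """Read a NIfTI (.nii/.nii.gz) or NRRD volume as HU."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not any(str(path).endswith(s) for s in (".nii", ".nii.gz", ".nrrd", ".nhdr")):
        raise ValueError(f"unrecognized format: {path.name}")
    arr, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    return ImageVolume(arr.astype(np.float32), spacing, origin)


def read_labels(
    path: "str | Path",
    vocabulary: Optional[Dict[str, int]] = None,
    reference: Optional[ImageVolume] = None,
    tol_mm: float = 0.1,
    strict: bool = False,
) -> LabelVolume:
    """Read an integer label map and record absent structures.

    Structures of the vocabulary that have no voxels are listed in
    ``missing`` rather than silently treated as empty.  With ``strict`` an
    unknown label id raises.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded, atol=1e-3):
            raise ValueError("label map contains non-integer values")
        arr = rounded
    arr = arr.astype(np.int32)
    vocabulary = dict(vocabulary or VOCABULARY)
    if reference is not None:
        if arr.shape != reference.shape:
            raise ValueError(
                f"geometry mismatch: label shape {arr.shape} vs image {reference.shape}"
            )
        if not (
            np.allclose(spacing, reference.spacing, atol=tol_mm)
            and np.allclose(origin, reference.origin, atol=tol_mm)
        ):
            raise ValueError("geometry mismatch: spacing/origin differ beyond tolerance")
    present = set(np.unique(arr).tolist())
    if strict:
        unknown = present - set(vocabulary.values()) - {0}
        if unknown:
            raise ValueError(f"unknown label ids {sorted(unknown)}")
    missing = {name for name, lid in vocabulary.items() if lid not in present}
    return LabelVolume(arr, spacing, origin, vocabulary=vocabulary, missing=missing)


def write_image(volume: ImageVolume, path: "str | Path") -> None:
    sitk.WriteImage(_to_sitk(volume.voxels, volume.spacing, volume.origin), str(path))


def write_labels(labels: LabelVolume, path: "str | Path") -> None:
    vox = labels.voxels.astype(np.uint8 if labels.voxels.max(initial=0) < 256 else np.int32)
    sitk.WriteImage(_to_sitk(vox, labels.spacing, labels.origin), str(path))
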