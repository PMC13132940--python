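"""Failure-case detection: scan classification and quality safeguards."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from skimage import measure

from .config import PipelineConfig
from .io import LabelVolume
from .maskops import components_by_size, dilate_mm

__all__ = [
    "ScanClassification",
    "classify_scan",
    "surface_to_volume_check",
    "ellipse_aspect_check",
]


@dataclass
class ScanClassification:
    scan_class: str                       # full | abdominal | cardiac_two_part | partial | rejected
    reasons: List[str] = field(default_factory=list)
    component_count: int = 0
    surface_to_volume_per_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.scan_class == "rejected" and not self.reasons:
            raise ValueError("a rejected scan must carry at least one reason")


def _touches(aorta_mask: np.ndarray, labels: LabelVolume, names, radius_mm: float) -> bool:
    for name in names:
        if labels.has(name):
            m = labels.mask(name)
            if m.any() and (dilate_mm(m, radius_mm, labels.spacing) & aorta_mask).any():
                return True
    return False


def classify_scan(aorta_mask: np.ndarray, labels: LabelVolume,
                  config: Optional[PipelineConfig] = None) -> ScanClassification:
    """Determine the field of view from the aorta's shape and neighbours.

    Two sizeable components mean a cardiac scan (ascending+root and a
    descending portion); one component spanning from the arch branches to
    the iliacs is a complete aorta; one abdominal component has kidneys
    nearby but no arch branches; anything else is partial coverage.  An
    empty aorta label rejects the scan outright.
    """
    config = config or PipelineConfig()
    if aorta_mask is None or not aorta_mask.any():
        return ScanClassification("rejected", reasons=["no aorta"], component_count=0)
    comps = components_by_size(aorta_mask, labels.spacing,
                               config.min_component_volume_mm3)
    n = len(comps)
    if n == 0:
        return ScanClassification("rejected",
                                  reasons=["aorta below minimum component volume"],
                                  component_count=0)
    if n == 2:
        return ScanClassification("cardiac_two_part", component_count=2)
    if n > 2:
        return ScanClassification("partial",
                                  reasons=[f"{n} aorta fragments"], component_count=n)

    r = config.artery_dilation_mm
    arch = _touches(aorta_mask, labels,
                    ("brachiocephalic_trunk", "left_common_carotid", "left_subclavian"), r)
    iliac = _touches(aorta_mask, labels, ("iliac_left", "iliac_right"), r)
    kidneys = labels.has("kidney_left") or labels.has("kidney_right")
    if arch and iliac:
        return ScanClassification("full", component_count=1)
    if kidneys and not arch:
        return ScanClassification("abdominal", component_count=1)
    return ScanClassification("partial", reasons=["coverage incomplete"],
                              component_count=1)


def surface_to_volume_check(lumen_mask: np.ndarray, spacing: np.ndarray,
                            threshold_per_mm: Optional[float] = None,
                            config: Optional[PipelineConfig] = None
                            ) -> Tuple[float, bool]:
    """Surface-to-volume ratio of the lumen (1/mm) and a roughness flag.

    The surface is a triangulated iso-surface (marching cubes at level 0.5)
    of the mask; the volume is the voxel count times the voxel volume.
    High ratios indicate a rough or porous lumen surface, typically from
    non-contrast imaging or acquisition artifacts.
    """
    if not lumen_mask.any():
        raise ValueError("empty lumen mask")
    config = config or PipelineConfig()
    if threshold_per_mm is None:
        threshold_per_mm = config.surface_volume_threshold_per_mm
    padded = np.pad(lumen_mask, 1).astype(np.uint8)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                                spacing=tuple(spacing))
    area = measure.mesh_surface_area(verts, faces)
    volume = float(lumen_mask.sum()) * float(np.prod(spacing))
    ratio = float(area / volume)
    return ratio, ratio > threshold_per_mm


def ellipse_aspect_check(slice_mask: np.ndarray, threshold: float = 2.5
                         ) -> Tuple[float, bool]:
    """Aspect ratio of the best-fit ellipse of a cross-section.

    The ratio is the square root of the ratio of the two in-plane
    second-moment eigenvalues; a ratio above the threshold marks a
    degenerate (obliquely cut or corrupted) slice whose diameter estimate
    must be discarded.  A ratio exactly at the threshold passes.
    """
    if not slice_mask.any():
        raise ValueError("empty slice mask")
    ij = np.argwhere(slice_mask).astype(float)
    centred = ij - ij.mean(axis=0)
    cov = centred.T @ centred / len(centred)
    evals = np.linalg.eigvalsh(cov)
    lo = max(float(evals[0]), 1e-12)
    ratio = float(np.sqrt(evals[1] / lo))
    return ratio, ratio <= threshold
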