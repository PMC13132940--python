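"""Small shared mask-geometry helpers (physical mm throughout)."""

from __future__ import annotations

from typing import List, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "ball_mm",
    "dilate_mm",
    "com_mm",
    "snap_to_mask",
    "surface_points_mm",
    "boundary_clusters",
    "components_by_size",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def ball_mm(radius_mm: float, spacing: np.ndarray) -> np.ndarray:
    r_vox = np.maximum(np.ceil(radius_mm / spacing).astype(int), 1)
    grids = np.meshgrid(*[np.arange(-r, r + 1) for r in r_vox], indexing="ij")
    d2 = sum((g * s / radius_mm) ** 2 for g, s in zip(grids, spacing))
    return d2 <= 1.0 + 1e-9


def dilate_mm(mask: np.ndarray, radius_mm: float, spacing: np.ndarray) -> np.ndarray:
    if radius_mm <= 0:
        return mask
    return ndimage.binary_dilation(mask, structure=ball_mm(radius_mm, spacing))


def com_mm(mask: np.ndarray, spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    if not mask.any():
        raise ValueError("empty mask has no centre of mass")
    idx = np.asarray(ndimage.center_of_mass(mask), dtype=float)
    return origin + idx * spacing


def snap_to_mask(point_mm: np.ndarray, mask: np.ndarray, spacing: np.ndarray,
                 origin: np.ndarray) -> np.ndarray:
    """Nearest voxel centre of ``mask`` to a physical point."""
    idx = np.argwhere(mask)
    if len(idx) == 0:
        raise ValueError("cannot snap to an empty mask")
    pts = origin + idx * spacing
    k = int(np.argmin(np.einsum("ij,ij->i", pts - point_mm, pts - point_mm)))
    return pts[k]


def surface_points_mm(mask: np.ndarray, spacing: np.ndarray,
                      origin: np.ndarray) -> np.ndarray:
    """Voxel centres on the boundary of a mask (mask minus its erosion)."""
    if not mask.any():
        raise ValueError("empty mask has no surface")
    inner = ndimage.binary_erosion(mask)
    shell = mask & ~inner
    if not shell.any():
        shell = mask
    return origin + np.argwhere(shell) * spacing


def boundary_clusters(mask: np.ndarray, spacing: np.ndarray, origin: np.ndarray
                      ) -> List[Tuple[np.ndarray, int]]:
    """Clusters of mask voxels lying on the grid boundary.

    Returns (centroid_mm, size) per 26-connected cluster, largest first.
    Each cluster marks a place where the structure leaves the field of view.
    """
    edge = np.zeros_like(mask)
    edge[0, :, :] = edge[-1, :, :] = True
    edge[:, 0, :] = edge[:, -1, :] = True
    edge[:, :, 0] = edge[:, :, -1] = True
    touching = mask & edge
    if not touching.any():
        return []
    lab, n = ndimage.label(touching, structure=_STRUCT26)
    out = []
    for i in range(1, n + 1):
        m = lab == i
        out.append((com_mm(m, spacing, origin), int(m.sum())))
    out.sort(key=lambda t: -t[1])
    return out


def components_by_size(mask: np.ndarray, spacing: np.ndarray,
                       min_volume_mm3: float = 0.0) -> List[np.ndarray]:
    """26-connected components above a volume cutoff, largest first."""
    lab, n = ndimage.label(mask, structure=_STRUCT26)
    voxvol = float(np.prod(spacing))
    comps = []
    for i in range(1, n + 1):
        m = lab == i
        if m.sum() * voxvol >= min_volume_mm3:
            comps.append(m)
    comps.sort(key=lambda m: -int(m.sum()))
    return comps
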