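"""Refinement of the aorta label into pure lumen and calcifications.

The input aorta label (from TotalSegmentator or the phantom generator)
covers lumen, wall and plaque.  A morphological skeleton of the label,
dilated by 1 mm, samples voxels that are almost surely contrast-enhanced
blood; their HU statistics (mu, sigma) define the adaptive lumen band
[mu - 5 sigma, mu + 3 sigma], which removes the darker wall and the bright
calcifications.  Calcified plaque is then everything removed from the label
with HU above the adaptive threshold max(min_hu, mu + alpha * sigma).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize

from .config import PipelineConfig
from .io import ImageVolume

__all__ = [
    "LumenStats",
    "LumenResult",
    "skeleton_lumen_stats",
    "refine_lumen",
    "extract_calcifications",
    "refine",
    "sweep_calcification_params",
]


@dataclass
class LumenStats:
    mu_hu: float
    sigma_hu: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("no skeleton samples")
        if self.sigma_hu < 0:
            raise ValueError("negative sigma")


@dataclass
class LumenResult:
    lumen_mask: np.ndarray
    calcification_mask: np.ndarray
    stats: LumenStats
    band: Tuple[float, float]
    calc_threshold: float
    calcification_ratio: float       # percent of (lumen + calc) voxels
    #: lumen voxels outside the HU band that were added by morphological closing
    band_violations: int = 0
    failed: bool = False


def _ball(radius_mm: float, spacing: np.ndarray) -> np.ndarray:
    """Ellipsoidal structuring element of a given physical radius."""
    r_vox = np.maximum(np.ceil(radius_mm / spacing).astype(int), 1)
    grids = np.meshgrid(*[np.arange(-r, r + 1) for r in r_vox], indexing="ij")
    d2 = sum((g * s / radius_mm) ** 2 for g, s in zip(grids, spacing))
    return d2 <= 1.0 + 1e-9


def _ball_vox(radius_vox: int) -> np.ndarray:
    g = np.meshgrid(*[np.arange(-radius_vox, radius_vox + 1)] * 3, indexing="ij")
    return sum(x**2 for x in g) <= radius_vox**2 + 1e-9


def dilated_skeleton(aorta_mask: np.ndarray, image: ImageVolume,
                     config: PipelineConfig) -> np.ndarray:
    """Morphological 3D skeleton of the aorta label, dilated by
    ``skeleton_dilation_mm`` and clipped to the label."""
    if not aorta_mask.any():
        raise ValueError("empty aorta mask")
    skel = skeletonize(aorta_mask)
    n = int(skel.sum())
    if n < 10:
        raise ValueError(f"degenerate skeleton of {n} voxels")
    ball = _ball(config.skeleton_dilation_mm, image.spacing)
    return ndimage.binary_dilation(skel, structure=ball) & aorta_mask


def skeleton_lumen_stats(aorta_mask: np.ndarray, image: ImageVolume,
                         config: Optional[PipelineConfig] = None) -> LumenStats:
    """HU mean and spread of skeleton-sampled pure-lumen voxels."""
    config = config or PipelineConfig()
    sample = dilated_skeleton(aorta_mask, image, config)
    vals = image.voxels[sample]
    return LumenStats(float(vals.mean()), float(vals.std()), int(vals.size))


def refine_lumen(aorta_mask: np.ndarray, image: ImageVolume, stats: LumenStats,
                 config: Optional[PipelineConfig] = None,
                 skeleton: Optional[np.ndarray] = None) -> LumenResult:
    """Keep connected in-band voxels of the aorta label as pure lumen.

    Connected components are retained when they touch the dilated skeleton
    (cardiac scans legitimately contain two aorta parts).  Morphological
    opening then closing removes outliers and holes; voxels at or above the
    calcification threshold are re-excluded afterwards so plaque can never
    be closed back into the lumen.
    """
    config = config or PipelineConfig()
    if skeleton is None:
        skeleton = dilated_skeleton(aorta_mask, image, config)
    sigma = max(stats.sigma_hu, config.sigma_floor_hu)
    lo = stats.mu_hu - config.lumen_band[0] * sigma
    hi = stats.mu_hu + config.lumen_band[1] * sigma
    in_band = aorta_mask & (image.voxels >= lo) & (image.voxels <= hi)

    struct26 = np.ones((3, 3, 3), dtype=bool)
    lab, n = ndimage.label(in_band, structure=struct26)
    if n == 0:
        return LumenResult(np.zeros_like(aorta_mask), np.zeros_like(aorta_mask),
                           stats, (lo, hi), _calc_threshold(stats, config),
                           0.0, failed=True)
    keep_ids = np.unique(lab[skeleton & in_band])
    keep_ids = keep_ids[keep_ids > 0]
    kept = np.isin(lab, keep_ids)

    ball = _ball_vox(config.morphology_radius_vox)
    opened = ndimage.binary_opening(kept, structure=ball)
    # erode with filled borders so a lumen that leaves the field of view
    # keeps touching the grid face
    closed = ndimage.binary_erosion(
        ndimage.binary_dilation(opened, structure=ball), structure=ball, border_value=1
    )
    lumen = closed & aorta_mask
    thr = _calc_threshold(stats, config)
    lumen &= image.voxels < thr
    violations = int((lumen & ~in_band).sum())
    failed = not lumen.any()
    return LumenResult(lumen, np.zeros_like(lumen), stats, (lo, hi), thr,
                       0.0, band_violations=violations, failed=failed)


def _calc_threshold(stats: LumenStats, config: PipelineConfig) -> float:
    return max(config.min_hu, stats.mu_hu + config.alpha * stats.sigma_hu)


def extract_calcifications(aorta_mask: np.ndarray, lumen_mask: np.ndarray,
                           image: ImageVolume, stats: LumenStats,
                           config: Optional[PipelineConfig] = None
                           ) -> Tuple[np.ndarray, float]:
    """Calcified voxels of the aorta label and the calcification ratio.

    Calcification = voxels removed from the label (aorta minus lumen) with
    HU at or above max(min_hu, mu + alpha * sigma).  The ratio is reported
    as percent of (lumen + calcification) voxels.
    """
    config = config or PipelineConfig()
    thr = _calc_threshold(stats, config)
    calc = aorta_mask & ~lumen_mask & (image.voxels >= thr)
    n_l, n_c = int(lumen_mask.sum()), int(calc.sum())
    ratio = 100.0 * n_c / max(n_l + n_c, 1)
    return calc, ratio


def refine(aorta_mask: np.ndarray, image: ImageVolume,
           config: Optional[PipelineConfig] = None) -> LumenResult:
    """Full refinement: skeleton stats, lumen band, calcifications."""
    config = config or PipelineConfig()
    skeleton = dilated_skeleton(aorta_mask, image, config)
    vals = image.voxels[skeleton]
    stats = LumenStats(float(vals.mean()), float(vals.std()), int(vals.size))
    result = refine_lumen(aorta_mask, image, stats, config, skeleton=skeleton)
    calc, ratio = extract_calcifications(aorta_mask, result.lumen_mask, image,
                                         stats, config)
    result.calcification_mask = calc
    result.calcification_ratio = ratio
    return result


def sweep_calcification_params(cases: Sequence[Tuple[np.ndarray, ImageVolume]],
                               alphas: Sequence[float],
                               min_hus: Sequence[float],
                               config: Optional[PipelineConfig] = None
                               ) -> pd.DataFrame:
    """Parameter ablation over (alpha, min_hu).

    ``cases`` is a sequence of (aorta_mask, image) pairs.  Returns one row
    per combination with the mean/std calcification ratio over the cases
    and the number of failed refinements (empty lumen).
    """
    base = (config or PipelineConfig()).to_dict()
    rows: List[dict] = []
    for alpha in alphas:
        for min_hu in min_hus:
            cfg = PipelineConfig.from_dict({**base, "alpha": alpha, "min_hu": min_hu})
            ratios, n_failed = [], 0
            for aorta_mask, image in cases:
                res = refine(aorta_mask, image, cfg)
                if res.failed:
                    n_failed += 1
                else:
                    ratios.append(res.calcification_ratio)
            rows.append({
                "alpha": alpha,
                "min_hu": min_hu,
                "ratio_mean": float(np.mean(ratios)) if ratios else float("nan"),
                "ratio_std": float(np.std(ratios)) if ratios else float("nan"),
                "n_failed": n_failed,
            })
    return pd.DataFrame(rows)
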