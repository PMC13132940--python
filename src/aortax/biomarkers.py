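"""Quantitative aortic biomarkers.

Diameters are measured on straightened cross-sections at the slice with the
largest cross-sectional area per segment (smallest for the sinotubular
junction and annulus).  The maximal diameter is the longest chord through
the centre of mass of the cross-section that hits the section boundary,
searched over 180 ray angles with sub-pixel boundary crossings.  Tortuosity
is centerline arc length between two anchor landmarks divided by their
Euclidean distance (>= 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .centerline import Centerline
from .config import PipelineConfig
from .cpr import CSAProfile, StraightenedVolume
from .landmarks import Landmark, SegmentTable
from .qc import ellipse_aspect_check

__all__ = [
    "DiameterMeasurement",
    "TortuosityResult",
    "AgreementStats",
    "max_diameter",
    "measure_segments",
    "measure_root",
    "tortuosity",
    "agreement_metrics",
]


@dataclass
class DiameterMeasurement:
    name: str
    segment: str
    arc_length_mm: float
    max_diameter_mm: float
    csa_mm2: float
    aspect_ratio: float
    qc_pass: bool
    centerline_name: str = "main"
    warnings: List[str] = field(default_factory=list)


@dataclass
class TortuosityResult:
    name: str                       # descending | full_aortic
    centerline_length_mm: float
    geometric_length_mm: float
    index: float

    def __post_init__(self) -> None:
        if self.index < 1.0 - 1e-6:
            raise ValueError(f"tortuosity index {self.index} below 1")


# ---------------------------------------------------------------------------
# Maximal diameter


def max_diameter(slice_mask: np.ndarray, inplane_res_mm: float,
                 angle_step_deg: float = 1.0
                 ) -> Tuple[float, np.ndarray, float]:
    """Longest chord through the centre of mass of a cross-section.

    For each angle, rays are cast from the COM in both directions; the
    boundary crossing is located with linear interpolation of the bilinear
    mask profile (sub-pixel).  Returns (diameter mm, COM in pixel
    coordinates, angle deg).  A COM outside the mask (crescent section)
    yields a zero diameter, which downstream QC rejects.
    """
    if not slice_mask.any():
        raise ValueError("empty slice mask")
    m = slice_mask.astype(np.float32)
    com = np.asarray(ndimage.center_of_mass(slice_mask), dtype=float)
    com_val = ndimage.map_coordinates(m, com[:, None], order=1)[0]
    if com_val < 0.5:
        return 0.0, com, 0.0

    angles = np.radians(np.arange(0.0, 180.0, angle_step_deg))
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)     # (A, 2)
    max_r = float(np.hypot(*slice_mask.shape)) + 2.0
    dt = 0.25                                                     # pixels
    ts = np.arange(dt, max_r, dt)                                 # (T,)

    def reach(sign: float) -> np.ndarray:
        pts = com[None, None, :] + sign * ts[None, :, None] * dirs[:, None, :]
        vals = ndimage.map_coordinates(m, pts.reshape(-1, 2).T, order=1,
                                       mode="constant", cval=0.0)
        vals = vals.reshape(len(angles), len(ts))
        outside = vals < 0.5
        first = np.argmax(outside, axis=1)                        # first exit
        first = np.where(outside.any(axis=1), first, len(ts) - 1)
        v_in = np.where(first > 0, vals[np.arange(len(angles)), first - 1], com_val)
        v_out = vals[np.arange(len(angles)), first]
        t_in = np.where(first > 0, ts[first - 1], 0.0)
        frac = np.where(v_in > v_out, (v_in - 0.5) / np.maximum(v_in - v_out, 1e-9), 0.0)
        return t_in + frac * dt

    r_pos, r_neg = reach(+1.0), reach(-1.0)
    chords = (r_pos + r_neg) * inplane_res_mm
    k = int(np.argmax(chords))
    return float(chords[k]), com, float(np.degrees(angles[k]))


# ---------------------------------------------------------------------------
# Per-segment measurements


def _measure_slice(sv: StraightenedVolume, idx: int, name: str, segment: str,
                   config: PipelineConfig) -> DiameterMeasurement:
    mask = sv.lumen_slices[idx]
    warnings: List[str] = []
    if not mask.any():
        return DiameterMeasurement(name, segment, float(sv.slice_arc_lengths[idx]),
                                   0.0, 0.0, np.inf, False, sv_name(sv),
                                   ["empty slice"])
    diam, _, _ = max_diameter(mask, sv.inplane_res_mm)
    csa = float(mask.sum()) * sv.inplane_res_mm**2
    aspect, aspect_ok = ellipse_aspect_check(mask, config.aspect_ratio_threshold)
    qc = aspect_ok and diam > 0
    if not aspect_ok:
        warnings.append(f"aspect ratio {aspect:.2f} exceeds "
                        f"{config.aspect_ratio_threshold}; measurement discarded")
    if diam == 0.0:
        warnings.append("centre of mass outside the section")
    n_pix = int(mask.sum())
    if n_pix <= 2:
        warnings.append("degenerate section of <= 2 pixels")
        qc = False
    return DiameterMeasurement(name, segment, float(sv.slice_arc_lengths[idx]),
                               diam, csa, aspect, qc, sv_name(sv), warnings)


def sv_name(sv: StraightenedVolume) -> str:
    return getattr(sv, "name", "main")


def measure_segments(sv: StraightenedVolume, profile: CSAProfile,
                     segment_table: SegmentTable,
                     config: Optional[PipelineConfig] = None
                     ) -> List[DiameterMeasurement]:
    """One diameter per available segment, at its maximal-CSA slice.

    Ties between equal-area slices resolve to the lower arc length.
    Segments without a valid slice are skipped (reported by the pipeline as
    warnings).
    """
    config = config or PipelineConfig()
    out: List[DiameterMeasurement] = []
    for seg in segment_table.available_segments():
        sel = np.where((sv.slice_arc_lengths >= seg.start_mm - 1e-9)
                       & (sv.slice_arc_lengths <= seg.end_mm + 1e-9)
                       & profile.valid)[0]
        if len(sel) == 0:
            continue
        best = sel[int(np.argmax(profile.area_mm2[sel]))]   # first max = lower arc
        out.append(_measure_slice(sv, int(best), seg.name, seg.name, config))
    return out


def measure_root(sv_root: StraightenedVolume,
                 root_lms: Dict[str, Tuple[float, float]],
                 config: Optional[PipelineConfig] = None
                 ) -> List[DiameterMeasurement]:
    """Diameters at the three root landmarks on the root straightened volume."""
    config = config or PipelineConfig()
    out = []
    for name, (arc, _area) in root_lms.items():
        idx = int(np.argmin(np.abs(sv_root.slice_arc_lengths - arc)))
        out.append(_measure_slice(sv_root, idx, name, "root", config))
    return out


# ---------------------------------------------------------------------------
# Tortuosity


def tortuosity(centerline: Centerline, landmark_a: Landmark,
               landmark_b: Landmark, name: str) -> TortuosityResult:
    """Centerline length over Euclidean distance between two landmarks.

    Descending tortuosity anchors at the distal arch and the diaphragm;
    full aortic tortuosity at the iliac bifurcation and the
    ventricular-aortic junction.
    """
    arc = abs(landmark_a.arc_length_mm - landmark_b.arc_length_mm)
    geo = float(np.linalg.norm(landmark_a.world_mm - landmark_b.world_mm))
    if geo < 1e-6:
        raise ValueError("coincident landmarks")
    return TortuosityResult(name, arc, geo, arc / geo)


# ---------------------------------------------------------------------------
# Agreement with manual readings


@dataclass
class AgreementStats:
    n: int
    mae: float
    mape_percent: float
    bias: float
    pearson_r: float
    cv_percent: float
    loa_low: float
    loa_high: float
    out_of_loa_fraction: float


def agreement_metrics(automatic: Sequence[float], manual: Sequence[float],
                      absolute_cv: bool = False) -> AgreementStats:
    """Agreement between automatic and manual measurements.

    MAE, MAPE and bias quantify deviation; the Pearson correlation and the
    coefficient of variation (mean signed per-pair difference over the pair
    average, in percent; ``absolute_cv`` switches to absolute differences)
    treat the comparison as an inter-observer study.  The limits of
    agreement are bias +/- 1.96 times the SD (ddof=1) of the differences.
    """
    a = np.asarray(automatic, dtype=float)
    m = np.asarray(manual, dtype=float)
    if a.shape != m.shape or a.ndim != 1:
        raise ValueError("need two equal-length 1-D sequences")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two pairs")
    if np.any(m <= 0):
        raise ValueError("manual values must be positive for ratio metrics")
    d = a - m
    mae = float(np.mean(np.abs(d)))
    mape = float(100.0 * np.mean(np.abs(d) / m))
    bias = float(np.mean(d))
    sd_a, sd_m = a.std(), m.std()
    pearson = float(np.corrcoef(a, m)[0, 1]) if sd_a > 0 and sd_m > 0 else float("nan")
    rel = d / ((a + m) / 2.0)
    cv = float(100.0 * np.mean(np.abs(rel) if absolute_cv else rel))
    sd_d = float(np.std(d, ddof=1))
    loa_low, loa_high = bias - 1.96 * sd_d, bias + 1.96 * sd_d
    out = float(np.mean((d < loa_low) | (d > loa_high)))
    return AgreementStats(n, mae, mape, bias, pearson, cv, loa_low, loa_high, out)
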