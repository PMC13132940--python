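"""Anatomical landmarks on the centerline and the segment partition.

Landmarks are found from the organ/artery label maps and projected onto the
centerline: five segmental landmarks (ventricular-aortic junction, proximal
and distal arch, diaphragm, renal) partition a full aorta into the ESC
segments (ascending, arch, descending, suprarenal, infrarenal); three root
landmarks (sinus of Valsalva, sinotubular junction, annulus) are extrema of
the cross-sectional-area profile inside fixed windows around the
ventricular-aortic junction.

Arc-length convention: 0 at the iliac bifurcation, increasing toward the
aortic valve.  "Distal" (downstream, with the blood flow) therefore means
*decreasing* arc length; landmark-ordering statements in anatomical order
(valve first) translate to decreasing arc positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .centerline import Centerline, EndpointPair, extract_centerline, \
    compute_frames, fit_smoothing_spline, lv_junction_point
from .config import PipelineConfig
from .cpr import CSAProfile, csa_profile, straighten
from .io import ImageVolume, LabelVolume
from .maskops import com_mm, dilate_mm, snap_to_mask, surface_points_mm

__all__ = [
    "Landmark",
    "LandmarkError",
    "Segment",
    "SegmentTable",
    "overlap_landmark",
    "arch_landmarks",
    "diaphragm_landmark",
    "renal_landmark",
    "root_landmarks",
    "build_root_centerline",
    "partition_segments",
    "anatomical_order_ok",
]


class LandmarkError(ValueError):
    """A landmark could not be computed (missing/too-distant structures)."""


@dataclass
class Landmark:
    name: str
    arc_length_mm: float
    world_mm: np.ndarray
    provenance: str

    def __post_init__(self) -> None:
        self.world_mm = np.asarray(self.world_mm, dtype=float)


def _project(centerline: Centerline, point_mm: np.ndarray, name: str,
             provenance: str) -> Landmark:
    arc = centerline.nearest_arc(point_mm)
    return Landmark(name, arc, centerline.point(arc), provenance)


# ---------------------------------------------------------------------------
# Overlap-based landmarks


def overlap_landmark(lumen_mask: np.ndarray, organ_mask: np.ndarray,
                     centerline: Centerline, dilation_mm: float,
                     spacing: np.ndarray, origin: np.ndarray,
                     name: str = "overlap") -> Landmark:
    """Dilate both masks, take the centre of mass of their overlap, and
    assign the nearest centerline point."""
    if not lumen_mask.any() or not organ_mask.any():
        raise LandmarkError(f"{name}: empty input mask")
    overlap = dilate_mm(lumen_mask, dilation_mm, spacing) & \
        dilate_mm(organ_mask, dilation_mm, spacing)
    if not overlap.any():
        raise LandmarkError(f"{name}: structures do not meet after {dilation_mm} mm dilation")
    com = com_mm(overlap, spacing, origin)
    return _project(centerline, com, name, f"overlap-COM(dilation={dilation_mm}mm)")


def arch_landmarks(lumen_mask: np.ndarray, labels: LabelVolume,
                   centerline: Centerline,
                   config: Optional[PipelineConfig] = None
                   ) -> Tuple[Landmark, Landmark, List[str]]:
    """Proximal and distal aortic-arch landmarks from the arch branches.

    The proximal landmark sits at the brachiocephalic-trunk origin; the
    distal landmark is the left-subclavian projection shifted 20 mm along
    the centerline toward the descending aorta (clamped to the span with a
    warning when necessary).
    """
    config = config or PipelineConfig()
    warnings: List[str] = []
    for req in ("brachiocephalic_trunk", "left_subclavian"):
        if not labels.has(req):
            raise LandmarkError(f"arch: {req} label missing")
    r = config.artery_dilation_mm
    prox = overlap_landmark(lumen_mask, labels.mask("brachiocephalic_trunk"),
                            centerline, r, labels.spacing, labels.origin,
                            name="proximal_arch")
    sub = overlap_landmark(lumen_mask, labels.mask("left_subclavian"),
                           centerline, r, labels.spacing, labels.origin,
                           name="left_subclavian")
    target = sub.arc_length_mm - config.distal_arch_offset_mm   # toward descending
    if target < 0.0:
        warnings.append("distal_arch: 20 mm offset clamped to the centerline start")
        target = 0.0
    distal = Landmark("distal_arch", target, centerline.point(target),
                      f"left_subclavian - {config.distal_arch_offset_mm}mm arc")
    return prox, distal, warnings


def diaphragm_landmark(rv_mask: np.ndarray, liver_mask: np.ndarray,
                       centerline: Centerline, spacing: np.ndarray,
                       origin: np.ndarray, tol_mm: float = 0.5,
                       max_iter: int = 50) -> Landmark:
    """Diaphragm from the RV blood pool (above) and the liver (below).

    Starting at the lowest RV surface point, the closest RV-liver point
    pair is refined by alternating nearest-neighbour projections; the pair
    distance is non-increasing and the midpoint of the final pair defines
    the diaphragm position.
    """
    if not rv_mask.any() or not liver_mask.any():
        raise LandmarkError("diaphragm: RV or liver mask missing/empty")
    rv_pts = surface_points_mm(rv_mask, spacing, origin)
    liv_pts = surface_points_mm(liver_mask, spacing, origin)
    rv_tree, liv_tree = cKDTree(rv_pts), cKDTree(liv_pts)

    p = rv_pts[np.argmin(rv_pts[:, 2])]          # lowest (most inferior) RV point
    prev = np.inf
    for _ in range(max_iter):
        d, j = liv_tree.query(p)
        q = liv_pts[j]
        d2, i = rv_tree.query(q)
        p_new = rv_pts[i]
        if prev - d2 < tol_mm:
            p = p_new
            break
        p, prev = p_new, d2
    d_final, j = liv_tree.query(p)
    mid = 0.5 * (p + liv_pts[j])
    return _project(centerline, mid, "diaphragm",
                    f"RV-liver closest pair midpoint (gap {d_final:.1f}mm)")


def renal_landmark(kidney_left: np.ndarray, kidney_right: np.ndarray,
                   centerline: Centerline, spacing: np.ndarray,
                   origin: np.ndarray) -> Landmark:
    """Centerline point closest to the infinite line through the two kidney
    centres of mass."""
    if not kidney_left.any() or not kidney_right.any():
        raise LandmarkError("renal: kidney mask missing/empty")
    a = com_mm(kidney_left, spacing, origin)
    b = com_mm(kidney_right, spacing, origin)
    axis = b - a
    norm = np.linalg.norm(axis)
    if norm < 1.0:
        raise LandmarkError("degenerate kidney line (coincident centres of mass)")
    axis /= norm
    rel = centerline.samples - a
    perp = rel - np.outer(rel @ axis, axis)
    d2 = np.einsum("ij,ij->i", perp, perp)
    k = int(np.argmin(d2))
    arc = float(centerline.arc_length[k])
    return Landmark("renal", arc, centerline.point(arc), "kidney-COM line projection")


# ---------------------------------------------------------------------------
# Aortic root


def _window_extremum(profile: CSAProfile, lo: float, hi: float, mode: str,
                     start_at: float, name: str) -> Tuple[float, float]:
    sel = (profile.arc_length_mm >= lo - 1e-9) & (profile.arc_length_mm <= hi + 1e-9) \
        & profile.valid
    if not sel.any():
        raise LandmarkError(f"{name}: CSA window [{lo:.1f}, {hi:.1f}] mm not covered")
    arcs = profile.arc_length_mm[sel]
    areas = profile.area_mm2[sel]
    order = np.argsort(np.abs(arcs - start_at), kind="stable")
    arcs, areas = arcs[order], areas[order]
    k = int(np.argmax(areas) if mode == "max" else np.argmin(areas))
    return float(arcs[k]), float(areas[k])


def root_landmarks(profile: CSAProfile, va_arc: float,
                   config: Optional[PipelineConfig] = None,
                   annulus_profile: Optional[CSAProfile] = None,
                   ) -> Dict[str, Tuple[float, float]]:
    """Root landmark arc positions (and their areas) on a root CSA profile.

    ``profile`` must be parameterised consistently with ``va_arc`` and
    increase toward the valve/LV.  The sinus of Valsalva is the CSA maximum
    within 20 mm distal to the ventricular-aortic junction (excluding the
    junction itself), the sinotubular junction the CSA minimum 5-25 mm
    beyond the sinus, and the annulus the CSA minimum within 10 mm proximal
    to the junction on the combined LV-aorta profile.  Ties break toward
    the window start.
    """
    config = config or PipelineConfig()
    out: Dict[str, Tuple[float, float]] = {}
    eps = 1e-6
    sinus_arc, sinus_area = _window_extremum(
        profile, va_arc - config.sinus_window_mm, va_arc - eps, "max",
        start_at=va_arc, name="sinus_valsalva")
    out["sinus_valsalva"] = (sinus_arc, sinus_area)
    lo_off, hi_off = config.stj_window_mm
    out["sinotubular_junction"] = _window_extremum(
        profile, sinus_arc - hi_off, sinus_arc - lo_off, "min",
        start_at=sinus_arc - lo_off, name="sinotubular_junction")
    ap = annulus_profile if annulus_profile is not None else profile
    out["annulus"] = _window_extremum(
        ap, va_arc, va_arc + config.annulus_window_mm, "min",
        start_at=va_arc, name="annulus")
    return out


def build_root_centerline(lumen_mask: np.ndarray, labels: LabelVolume,
                          centerline: Centerline, image: ImageVolume,
                          config: Optional[PipelineConfig] = None,
                          span_mm: float = 60.0):
    """Combined LV-aorta centerline around the aortic root.

    Takes the last ``span_mm`` of the aortic centerline and extends it into
    the LV blood pool (medial path toward the LV centre of mass, truncated
    to ``lv_extension_mm``).  Returns ``(root_centerline, root_profile,
    va_arc_on_root)`` where the profile is the CSA of lumen-union-LV along
    the root line; arc length increases toward the LV.
    """
    config = config or PipelineConfig()
    if not labels.has("lv_blood"):
        raise LandmarkError("root: LV blood-pool label missing")
    lv = labels.mask("lv_blood")
    combined = lumen_mask | lv
    sp, og = labels.spacing, labels.origin

    end_pt = centerline.samples[-1]
    lv_com = com_mm(lv, sp, og)
    lv_target = snap_to_mask(lv_com, lv, sp, og)
    ext = extract_centerline(combined, sp, og,
                             EndpointPair(end_pt, lv_target, "root-extension"),
                             eps_mm=config.medial_eps_mm)
    seg = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(ext, axis=0), axis=1))])
    ext = ext[seg <= config.lv_extension_mm]

    from .centerline import default_residual_mm
    keep = centerline.arc_length >= centerline.total_length_mm - span_mm
    raw = np.concatenate([centerline.samples[keep], ext[1:]], axis=0)
    residual = config.spline_residual_mm or default_residual_mm(sp)
    root_cl = fit_smoothing_spline(raw, config.centerline_step_mm,
                                   residual_rms_mm=residual, name="root")
    root_cl = compute_frames(root_cl)
    sv = straighten(image, combined, root_cl, config)
    prof = csa_profile(sv)
    va_world = lv_junction_point(lumen_mask, labels, config)
    va_arc = root_cl.nearest_arc(va_world)
    return root_cl, prof, va_arc


# ---------------------------------------------------------------------------
# Segment partition


@dataclass
class Segment:
    name: str
    start_mm: float                 # lower arc-length bound
    end_mm: float
    centerline_name: str = "main"
    available: bool = True
    reason: str = ""


@dataclass
class SegmentTable:
    segments: List[Segment] = field(default_factory=list)
    scan_class: str = "full"

    def available_segments(self) -> List[Segment]:
        return [s for s in self.segments if s.available]

    def __iter__(self):
        return iter(self.segments)


#: segment -> (lower landmark, upper landmark); None means a centerline end
_FULL_PLAN = [
    ("infrarenal", None, "renal"),
    ("suprarenal", "renal", "diaphragm"),
    ("descending", "diaphragm", "distal_arch"),
    ("arch", "distal_arch", "proximal_arch"),
    ("ascending", "proximal_arch", "ventricular_aortic"),
]


def partition_segments(landmarks: Dict[str, Landmark], centerline: Centerline,
                       scan_class: str) -> SegmentTable:
    """Partition the centerline into ESC segments from the landmarks.

    Segment boundaries equal landmark arc-lengths exactly; a missing
    landmark makes the adjacent segments unavailable (never silently
    merged).
    """
    L = centerline.total_length_mm
    table = SegmentTable(scan_class=scan_class)

    def arc_of(name, default=None):
        lm = landmarks.get(name)
        return None if lm is None else float(lm.arc_length_mm)

    if scan_class in ("full", "abdominal"):
        plan = _FULL_PLAN if scan_class == "full" else _FULL_PLAN[:3]
        for name, lo_lm, hi_lm in plan:
            lo = 0.0 if lo_lm is None else arc_of(lo_lm)
            hi = L if hi_lm is None or (scan_class == "abdominal" and hi_lm in
                                        ("distal_arch",)) else arc_of(hi_lm)
            if scan_class == "abdominal" and name == "descending":
                hi = L   # descending stub: diaphragm up to the scan boundary
            if lo is None or hi is None:
                missing = lo_lm if lo is None else hi_lm
                table.segments.append(Segment(name, np.nan, np.nan,
                                              available=False,
                                              reason=f"missing landmark {missing}"))
            elif hi <= lo:
                table.segments.append(Segment(name, lo, hi, available=False,
                                              reason="degenerate interval"))
            else:
                table.segments.append(Segment(name, lo, hi))
    elif scan_class == "cardiac_two_part":
        va = arc_of("ventricular_aortic")
        if centerline.name == "ascending":
            if va is None:
                table.segments.append(Segment("ascending", np.nan, np.nan,
                                              centerline_name=centerline.name,
                                              available=False,
                                              reason="missing landmark ventricular_aortic"))
            else:
                lo, hi = sorted((0.0, va))
                table.segments.append(Segment("ascending", lo, hi,
                                              centerline_name=centerline.name))
        else:
            table.segments.append(Segment("descending", 0.0, L,
                                          centerline_name=centerline.name))
    else:   # partial: a single unnamed span
        table.segments.append(Segment("visible_aorta", 0.0, L))
    return table


def anatomical_order_ok(landmarks: Dict[str, Landmark]) -> bool:
    """Check that present segmental landmarks appear in anatomical order
    (valve -> bifurcation means decreasing arc length)."""
    order = ["ventricular_aortic", "proximal_arch", "distal_arch",
             "diaphragm", "renal"]
    arcs = [landmarks[n].arc_length_mm for n in order if n in landmarks]
    return all(a > b for a, b in zip(arcs, arcs[1:]))
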