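"""Centerline extraction and regularised local frames.

The medial path is a minimal-cost route over the 26-connected in-lumen
voxel graph with edge cost ``step_length / (eps + distance_to_boundary)``,
which penalises wall-hugging routes and makes the path track the centres of
the maximally inscribed spheres.  The raw voxel path is approximated by a
cubic smoothing spline to remove voxel-scale fluctuations, resampled at a
uniform arc-length step, and equipped with rotation-minimising
(tangent, normal, binormal) frames.  A final pass enforces
``dot(normal_i, normal_{i+1}) >= 0`` by flipping, so frames stay stable
across inflection points where a naive Frenet normal would reverse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.interpolate import UnivariateSpline
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .config import PipelineConfig
from .io import LabelVolume
from .maskops import (boundary_clusters, com_mm, components_by_size,
                      dilate_mm, snap_to_mask)

__all__ = [
    "Centerline",
    "EndpointPair",
    "determine_endpoints",
    "extract_centerline",
    "fit_smoothing_spline",
    "compute_frames",
    "lv_junction_point",
]


# ---------------------------------------------------------------------------
# Data types


@dataclass
class EndpointPair:
    start: np.ndarray            # mm
    end: np.ndarray              # mm
    rule: str                    # which endpoint rule fired
    component: int = 0           # index of the lumen component this pair lives in

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)
        if np.allclose(self.start, self.end):
            raise ValueError("endpoint pair is degenerate (start == end)")


@dataclass
class Centerline:
    """Arc-length parameterised smooth curve with orthonormal local frames."""

    samples: np.ndarray                      # (N, 3) mm
    arc_length: np.ndarray                   # (N,) cumulative mm
    tangents: np.ndarray                     # (N, 3) unit
    normals: Optional[np.ndarray] = None
    binormals: Optional[np.ndarray] = None
    name: str = "main"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.arc_length) <= 0):
            raise ValueError("arc_length must be strictly increasing")

    @property
    def total_length_mm(self) -> float:
        return float(self.arc_length[-1])

    def point(self, s) -> np.ndarray:
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.total_length_mm)
        return np.stack(
            [np.interp(s, self.arc_length, self.samples[:, k]) for k in range(3)], axis=-1
        )

    def frame(self, s) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Interpolated orthonormal frame at arc-length ``s``."""
        if self.normals is None:
            raise ValueError("frames not computed")
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.total_length_mm)
        out = []
        for arr in (self.tangents, self.normals, self.binormals):
            v = np.stack(
                [np.interp(s, self.arc_length, arr[:, k]) for k in range(3)], axis=-1
            )
            out.append(v / np.linalg.norm(v, axis=-1, keepdims=True))
        t, n, b = out
        n = n - (np.sum(n * t, axis=-1, keepdims=True)) * t
        n /= np.linalg.norm(n, axis=-1, keepdims=True)
        b = np.cross(t, n)
        return t, n, b

    def nearest_arc(self, point_mm: np.ndarray) -> float:
        """Arc-length of the sample closest to a physical point."""
        d2 = np.einsum("ij,ij->i", self.samples - point_mm, self.samples - point_mm)
        return float(self.arc_length[int(np.argmin(d2))])


# ---------------------------------------------------------------------------
# Endpoint rules


def lv_junction_point(lumen_mask: np.ndarray, labels: LabelVolume,
                      config: PipelineConfig) -> np.ndarray:
    """Centre of mass of (dilated LV blood pool) & (dilated lumen), snapped
    to the lumen.  Shared with the ventricular-aortic landmark."""
    if not labels.has("lv_blood"):
        raise ValueError("LV blood-pool label missing")
    lv = labels.mask("lv_blood")
    r = config.artery_dilation_mm
    overlap = dilate_mm(lv, r, labels.spacing) & dilate_mm(lumen_mask, r, labels.spacing)
    if not overlap.any():
        raise ValueError("LV and lumen do not meet after dilation")
    com = com_mm(overlap, labels.spacing, labels.origin)
    return snap_to_mask(com, lumen_mask, labels.spacing, labels.origin)


def iliac_bifurcation_point(lumen_mask: np.ndarray, labels: LabelVolume,
                            config: PipelineConfig) -> np.ndarray:
    """Most superior region where both dilated iliac labels meet the aortic
    lumen; returns its centroid snapped to the lumen."""
    if not (labels.has("iliac_left") and labels.has("iliac_right")):
        raise ValueError("iliac labels missing")
    r = config.artery_dilation_mm
    left = dilate_mm(labels.mask("iliac_left"), r, labels.spacing) & lumen_mask
    right = dilate_mm(labels.mask("iliac_right"), r, labels.spacing) & lumen_mask
    both = left & right
    meet = both if both.any() else (left | right)
    if not meet.any():
        raise ValueError("iliac arteries do not meet the lumen")
    zs = np.argwhere(meet)[:, 2]
    top = zs.max()
    slab = meet.copy()
    slab[:, :, : max(top - 2, 0)] = False
    com = com_mm(slab, labels.spacing, labels.origin)
    return snap_to_mask(com, lumen_mask, labels.spacing, labels.origin)


def _farthest_pair(mask: np.ndarray, spacing: np.ndarray, origin: np.ndarray
                   ) -> Tuple[np.ndarray, np.ndarray]:
    pts = origin + np.argwhere(mask) * spacing
    c = pts.mean(axis=0)
    a = pts[np.argmax(np.einsum("ij,ij->i", pts - c, pts - c))]
    b = pts[np.argmax(np.einsum("ij,ij->i", pts - a, pts - a))]
    a = pts[np.argmax(np.einsum("ij,ij->i", pts - b, pts - b))]
    return a, b


def _order_inferior_first(a: np.ndarray, b: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    return (a, b) if a[2] <= b[2] else (b, a)


def determine_endpoints(lumen_mask: np.ndarray, labels: LabelVolume,
                        scan_class: str,
                        config: Optional[PipelineConfig] = None
                        ) -> List[EndpointPair]:
    """Scan-type-dependent centerline endpoints.

    full      : iliac bifurcation -> LV junction
    abdominal : iliac bifurcation -> superior scan boundary
    cardiac   : two pairs - the descending portion between its two scan
                boundary crossings, and the ascending portion from its scan
                boundary down to the LV junction
    partial   : between the two largest scan-boundary crossings, falling
                back to the farthest-apart pair of lumen voxels
    """
    config = config or PipelineConfig()
    sp, og = labels.spacing, labels.origin
    if not lumen_mask.any():
        raise ValueError("empty lumen mask")

    if scan_class == "full":
        start = iliac_bifurcation_point(lumen_mask, labels, config)
        end = lv_junction_point(lumen_mask, labels, config)
        return [EndpointPair(start, end, "iliac_bifurcation->lv_junction")]

    if scan_class == "abdominal":
        start = iliac_bifurcation_point(lumen_mask, labels, config)
        clusters = boundary_clusters(lumen_mask, sp, og)
        if not clusters:
            raise ValueError("lumen does not reach the scan boundary")
        top = max(clusters, key=lambda t: t[0][2])[0]
        end = snap_to_mask(top, lumen_mask, sp, og)
        return [EndpointPair(start, end, "iliac_bifurcation->scan_boundary")]

    if scan_class == "cardiac_two_part":
        comps = components_by_size(lumen_mask, sp, config.min_component_volume_mm3)
        if len(comps) < 2:
            raise ValueError(f"expected two aorta components, found {len(comps)}")
        lv_dil = (dilate_mm(labels.mask("lv_blood"), config.artery_dilation_mm, sp)
                  if labels.has("lv_blood") else np.zeros_like(lumen_mask))
        pairs: List[EndpointPair] = []
        for ci, comp in enumerate(comps[:2]):
            clusters = boundary_clusters(comp, sp, og)
            if (lv_dil & dilate_mm(comp, config.artery_dilation_mm, sp)).any():
                if not clusters:
                    raise ValueError("ascending component does not reach the boundary")
                start = snap_to_mask(clusters[0][0], comp, sp, og)
                end = lv_junction_point(comp, labels, config)
                pairs.append(EndpointPair(start, end, "scan_boundary->lv_junction", ci))
            else:
                if len(clusters) >= 2:
                    a = snap_to_mask(clusters[0][0], comp, sp, og)
                    b = snap_to_mask(clusters[1][0], comp, sp, og)
                else:
                    a, b = _farthest_pair(comp, sp, og)
                a, b = _order_inferior_first(a, b)
                pairs.append(EndpointPair(a, b, "scan_boundary->scan_boundary", ci))
        return pairs

    # partial / unknown coverage
    clusters = boundary_clusters(lumen_mask, sp, og)
    if len(clusters) >= 2:
        a = snap_to_mask(clusters[0][0], lumen_mask, sp, og)
        b = snap_to_mask(clusters[1][0], lumen_mask, sp, og)
        rule = "scan_boundary->scan_boundary"
    else:
        a, b = _farthest_pair(lumen_mask, sp, og)
        rule = "farthest_pair"
    a, b = _order_inferior_first(a, b)
    return [EndpointPair(a, b, rule)]


# ---------------------------------------------------------------------------
# Medial path

_OFFSETS = np.array([(i, j, k)
                     for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
                     if (i, j, k) != (0, 0, 0)], dtype=int)


def extract_centerline(lumen_mask: np.ndarray, spacing: np.ndarray,
                       origin: np.ndarray, endpoints: EndpointPair,
                       eps_mm: float = 0.1) -> np.ndarray:
    """Minimal-cost medial route between the endpoints, as ordered voxel
    centres in mm.  Edge cost is step length over (eps + distance to the
    lumen boundary at the target voxel)."""
    if not lumen_mask.any():
        raise ValueError("empty lumen mask")
    dtb = ndimage.distance_transform_edt(lumen_mask, sampling=spacing)

    idx = np.argwhere(lumen_mask)
    n = len(idx)
    comp_id = np.full(lumen_mask.shape, -1, dtype=np.int64)
    comp_id[tuple(idx.T)] = np.arange(n)

    rows, cols, data = [], [], []
    shape = lumen_mask.shape
    for off in _OFFSETS:
        src = idx
        dst = idx + off
        ok = np.all((dst >= 0) & (dst < shape), axis=1)
        src, dst = src[ok], dst[ok]
        ok2 = lumen_mask[tuple(dst.T)]
        src, dst = src[ok2], dst[ok2]
        if len(src) == 0:
            continue
        step = float(np.linalg.norm(off * spacing))
        w = step / (eps_mm + dtb[tuple(dst.T)])
        rows.append(comp_id[tuple(src.T)])
        cols.append(comp_id[tuple(dst.T)])
        data.append(w)
    graph = coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()

    def _voxel_id(p_mm):
        snapped = snap_to_mask(np.asarray(p_mm, float), lumen_mask, spacing, origin)
        iv = np.round((snapped - origin) / spacing).astype(int)
        return int(comp_id[tuple(iv)])

    s_id, e_id = _voxel_id(endpoints.start), _voxel_id(endpoints.end)
    dist, pred = dijkstra(graph, directed=True, indices=s_id,
                          return_predecessors=True)
    if not np.isfinite(dist[e_id]):
        raise ValueError("endpoints lie in different lumen components (no route)")
    path_ids = [e_id]
    while path_ids[-1] != s_id:
        path_ids.append(int(pred[path_ids[-1]]))
    path_ids.reverse()
    path = origin + idx[path_ids] * spacing
    # short moving average removes the 26-connectivity zigzag, which would
    # otherwise inflate the path length by several percent; endpoints stay
    if len(path) >= 7:
        kernel = np.ones(5) / 5.0
        smooth = np.stack(
            [np.convolve(np.pad(path[:, c], (2, 2), mode="edge"), kernel,
                         mode="valid") for c in range(3)], axis=1)
        smooth[0], smooth[-1] = path[0], path[-1]
        path = smooth
    return path


# ---------------------------------------------------------------------------
# Smoothing spline


def default_residual_mm(spacing: np.ndarray) -> float:
    """Default spline residual target: 0.35x the voxel diagonal (the raw
    path is already pre-smoothed, so only sub-voxel jitter remains)."""
    return 0.35 * float(np.linalg.norm(spacing))


def fit_smoothing_spline(raw_path: np.ndarray, step_mm: float = 1.0,
                         residual_rms_mm: float = 1.0,
                         name: str = "main") -> Centerline:
    """Cubic smoothing spline per coordinate against cumulative chord
    length, resampled at a uniform arc-length step.

    The smoothing factor targets a fit residual of ``residual_rms_mm`` RMS,
    enough to remove voxel-scale zigzag without cutting curvature.  The last
    sample is placed exactly at the total length.
    """
    raw_path = np.asarray(raw_path, dtype=float)
    if len(raw_path) < 4:
        raise ValueError("need at least 4 path points")
    seg = np.linalg.norm(np.diff(raw_path, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-9])
    raw_path = raw_path[keep]
    u = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(raw_path, axis=0), axis=1))])
    if u[-1] <= 0:
        raise ValueError("zero-length path")

    s_factor = len(raw_path) * residual_rms_mm**2 / 3.0   # per coordinate
    # pin the endpoints: smoothing must not pull the curve ends inward,
    # which would bias chord lengths (and with them tortuosity indices)
    w = np.ones(len(raw_path))
    w[0] = w[-1] = 100.0
    splines = [UnivariateSpline(u, raw_path[:, k], w=w, k=3, s=s_factor)
               for k in range(3)]

    # arc-length reparameterisation on a dense grid
    ud = np.linspace(0.0, u[-1], max(8 * len(raw_path), 512))
    pd = np.stack([sp(ud) for sp in splines], axis=1)
    dp = np.stack([sp.derivative()(ud) for sp in splines], axis=1)
    speed = np.linalg.norm(dp, axis=1)
    s_dense = np.concatenate([[0.0], np.cumsum(0.5 * (speed[1:] + speed[:-1]) * np.diff(ud))])
    total = float(s_dense[-1])

    s_out = np.arange(0.0, total, step_mm)
    if total - s_out[-1] > 1e-6:
        s_out = np.concatenate([s_out, [total]])
    u_out = np.interp(s_out, s_dense, ud)
    samples = np.stack([sp(u_out) for sp in splines], axis=1)
    tang = np.stack([sp.derivative()(u_out) for sp in splines], axis=1)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    return Centerline(samples=samples, arc_length=s_out, tangents=tang, name=name)


# ---------------------------------------------------------------------------
# Rotation-minimising frames


def compute_frames(centerline: Centerline,
                   up_vector: Sequence[float] = (0.0, -1.0, 0.0)) -> Centerline:
    """Propagate rotation-minimising frames (double-reflection scheme) from
    an initial normal built from the up vector, then enforce the
    consecutive-normal flip rule.

    The default up vector points anterior; when it is near-parallel to the
    first tangent the lateral axis is used instead.
    """
    t = centerline.tangents
    if np.linalg.norm(t[0]) < 1e-9:
        raise ValueError("degenerate first tangent")
    up = np.asarray(up_vector, dtype=float)
    n0 = up - np.dot(up, t[0]) * t[0]
    if np.linalg.norm(n0) < 1e-6:
        lateral = np.array([1.0, 0.0, 0.0])
        n0 = lateral - np.dot(lateral, t[0]) * t[0]
        if np.linalg.norm(n0) < 1e-6:
            raise ValueError("up vector parallel to the first tangent")
    n0 /= np.linalg.norm(n0)

    x = centerline.samples
    N = len(x)
    normals = np.empty_like(t)
    normals[0] = n0
    for i in range(N - 1):
        v1 = x[i + 1] - x[i]
        c1 = np.dot(v1, v1)
        if c1 < 1e-14:
            normals[i + 1] = normals[i]
            continue
        rL = normals[i] - (2.0 / c1) * np.dot(v1, normals[i]) * v1
        tL = t[i] - (2.0 / c1) * np.dot(v1, t[i]) * v1
        v2 = t[i + 1] - tL
        c2 = np.dot(v2, v2)
        r_next = rL if c2 < 1e-14 else rL - (2.0 / c2) * np.dot(v2, rL) * v2
        # flip rule: never let consecutive normals reverse
        if np.dot(r_next, normals[i]) < 0:
            r_next = -r_next
        normals[i + 1] = r_next

    # re-orthonormalise against the tangents
    normals -= np.sum(normals * t, axis=1, keepdims=True) * t
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    centerline.normals = normals
    centerline.binormals = np.cross(t, normals)
    return centerline


def centerline_to_csv(centerline: Centerline) -> "pd.DataFrame":
    import pandas as pd

    d = {
        "x_mm": centerline.samples[:, 0],
        "y_mm": centerline.samples[:, 1],
        "z_mm": centerline.samples[:, 2],
        "arc_length_mm": centerline.arc_length,
    }
    for name, arr in (("tangent", centerline.tangents),
                      ("normal", centerline.normals),
                      ("binormal", centerline.binormals)):
        if arr is not None:
            for k, ax in enumerate("xyz"):
                d[f"{name}_{ax}"] = arr[:, k]
    return pd.DataFrame(d)
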