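"""Synthetic CTA phantoms with analytic ground truth.

Generates contrast-enhanced-CTA-like volumes plus TotalSegmentator-style
label maps so every pipeline stage can be exercised without patient data.
The phantom emulates: a tubular aortic lumen with approximately normal
contrast HU (default N(300, 20)), a darker wall ring, bright calcified
plaques at the lumen/wall interface, surrounding organ blobs (LV/RV blood
pools, liver, kidneys, arch branch arteries, iliac arteries) and a known
analytic centerline, radius profile and landmark positions.

Curve kinds
-----------
``straight``
    a vertical tube of the given length.
``semicircle``
    a half-circle of the given radius in the x-z plane (arc length pi*R,
    endpoint distance 2R, tortuosity pi/2).
``s_curve``
    a vertical run with a lateral sinusoid - contains inflection points,
    which exercises the frame-flip regularisation.
``full_aorta``
    abdominal+descending vertical run, semicircular arch, ascending run
    down to the aortic valve; landmark ground truth is defined by
    construction at the junctions.

Voxels are assigned by centre-point inclusion (no partial volume) so mask
ground truth is exact; optional Gaussian smoothing applies to HU only,
never to labels.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io import VOCABULARY, ImageVolume, LabelVolume

__all__ = [
    "PhantomSpec",
    "PhantomGroundTruth",
    "AnalyticCurve",
    "make_curve",
    "rasterize_phantom",
    "crop_axial",
]


# ---------------------------------------------------------------------------
# Analytic curves


class AnalyticCurve:
    """Arc-length parameterised curve backed by a dense polyline.

    The polyline is sampled finely enough (default ~0.05 mm steps) that the
    chord-length parameterisation agrees with the true arc length to well
    below 0.1 %.
    """

    def __init__(self, points: np.ndarray):
        points = np.asarray(points, dtype=float)
        if points.ndim != 2 or points.shape[1] != 3 or len(points) < 2:
            raise ValueError("need an (N, 3) polyline with N >= 2")
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
        keep = np.concatenate([[True], seg > 1e-12])
        points = points[keep]
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
        self.points = points
        self.s = np.concatenate([[0.0], np.cumsum(seg)])
        self.total_length = float(self.s[-1])
        if self.total_length <= 0:
            raise ValueError("degenerate curve of zero length")
        # central-difference tangents on the dense polyline
        t = np.gradient(points, self.s, axis=0)
        self._tangents = t / np.linalg.norm(t, axis=1, keepdims=True)

    def point(self, s) -> np.ndarray:
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.total_length)
        out = np.stack([np.interp(s, self.s, self.points[:, k]) for k in range(3)], axis=-1)
        return out

    def tangent(self, s) -> np.ndarray:
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.total_length)
        t = np.stack([np.interp(s, self.s, self._tangents[:, k]) for k in range(3)], axis=-1)
        return t / np.linalg.norm(t, axis=-1, keepdims=True)

    def arc_of_point(self, p: np.ndarray) -> float:
        """Arc-length of the curve point closest to ``p`` (projection)."""
        d2 = np.einsum("ij,ij->i", self.points - p, self.points - p)
        return float(self.s[int(np.argmin(d2))])

    def chord_length(self, s0: float, s1: float) -> float:
        return float(np.linalg.norm(self.point(s1) - self.point(s0)))

    def tortuosity(self, s0: float, s1: float) -> float:
        """Arc length between s0 and s1 divided by the straight-line distance."""
        chord = self.chord_length(s0, s1)
        if chord <= 0:
            raise ValueError("coincident anchor points")
        return abs(s1 - s0) / chord


# ---------------------------------------------------------------------------
# Specification


@dataclass
class PhantomSpec:
    curve_kind: str = "full_aorta"

    # straight / s_curve
    length_mm: float = 100.0
    s_amplitude_mm: float = 8.0
    s_period_mm: float = 50.0

    # semicircle
    semicircle_radius_mm: float = 50.0

    # full aorta geometry
    descending_length_mm: float = 150.0
    arch_radius_mm: float = 30.0
    ascending_length_mm: float = 40.0
    #: lateral sinusoid on the abdominal/descending run (amplitude, period)
    tortuosity_amplitude_mm: float = 0.0
    tortuosity_period_mm: float = 80.0

    # radius profile
    lumen_radius_mm: float = 10.0
    wall_thickness_mm: float = 2.0
    #: optional Gaussian aneurysm bump: (centre arc-length mm, amplitude mm, sigma mm)
    aneurysm: Optional[Tuple[float, float, float]] = None
    #: aortic-root features: sinus bulge, STJ narrowing, annulus narrowing
    root_features: bool = True
    sinus_bulge_mm: float = 3.0
    stj_narrowing_mm: float = 1.5
    annulus_narrowing_mm: float = 2.5

    # HU model
    lumen_mean_hu: float = 300.0
    lumen_sd_hu: float = 20.0
    wall_hu: float = 50.0
    background_hu: float = 40.0
    calc_hu: float = 800.0
    noise_sd_hu: float = 10.0
    smooth_sigma_mm: float = 0.0

    # calcifications
    calc_fraction: float = 0.0          # of (lumen + calcification) voxels
    calc_blob_radius_mm: float = 2.0

    # hyperdense speckle clusters in the peripheral lumen (emulates the
    # wall-adjacent calcification and artifacts of mislabelled non-contrast
    # acquisitions, which fragment the refined lumen)
    speckle_fraction: float = 0.0
    speckle_hu: float = 900.0
    speckle_radius_mm: float = 1.4
    #: clusters are seeded at fractional radius >= this (0 = anywhere)
    speckle_min_radius_frac: float = 0.35

    include_organs: bool = True
    #: clip the grid at the curve end planes so the vessel leaves the
    #: field of view there (None -> True for standalone tubes, False for
    #: the full aorta, whose ends meet the iliacs and the LV instead)
    crop_ends: Optional[bool] = None
    spacing_mm: float = 1.25
    margin_mm: float = 8.0
    rng_seed: int = 0

    # landmark construction (full aorta): arc-lengths of the renal plane and
    # of the diaphragm organ pair, measured from the iliac bifurcation (s=0)
    renal_arc_mm: float = 40.0
    diaphragm_arc_mm: float = 95.0

    def __post_init__(self) -> None:
        if self.wall_thickness_mm < 0:
            raise ValueError("wall thickness must be >= 0")
        if self.lumen_radius_mm <= self.wall_thickness_mm:
            raise ValueError("need lumen radius > wall thickness")
        if not 0.0 <= self.calc_fraction <= 0.5:
            raise ValueError("calc_fraction must be in [0, 0.5]")
        if self.curve_kind not in ("straight", "semicircle", "s_curve", "full_aorta"):
            raise ValueError(f"unknown curve kind {self.curve_kind!r}")

    @classmethod
    def non_contrast(cls, **overrides) -> "PhantomSpec":
        """A scan without contrast agent: lumen HU ~ wall HU plus heavy
        clustered hyperdense noise, which fragments the refined lumen."""
        base = dict(
            curve_kind="straight",
            length_mm=100.0,
            lumen_mean_hu=50.0,
            lumen_sd_hu=25.0,
            wall_hu=50.0,
            speckle_fraction=0.15,
            speckle_hu=900.0,
            include_organs=False,
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: "str | Path") -> "PhantomSpec":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        if "aneurysm" in data and data["aneurysm"] is not None:
            data["aneurysm"] = tuple(data["aneurysm"])
        return cls(**data)


# ---------------------------------------------------------------------------
# Ground truth


@dataclass
class PhantomGroundTruth:
    curve: AnalyticCurve
    total_length_mm: float
    #: arc-lengths (mm, 0 at the iliac bifurcation / proximal curve end)
    landmarks_s: Dict[str, float]
    radius_fn: Callable[[np.ndarray], np.ndarray]
    tortuosity: Dict[str, float]
    calc_fraction: float
    lumen_mask: np.ndarray
    calc_mask: np.ndarray
    wall_mask: np.ndarray

    def to_json_dict(self) -> dict:
        s = np.linspace(0.0, self.total_length_mm, 257)
        return {
            "total_length_mm": self.total_length_mm,
            "landmarks_s_mm": {k: float(v) for k, v in sorted(self.landmarks_s.items())},
            "tortuosity": {k: float(v) for k, v in sorted(self.tortuosity.items())},
            "calc_fraction": float(self.calc_fraction),
            "radius_profile": {
                "s_mm": [round(float(x), 4) for x in s],
                "r_mm": [round(float(x), 4) for x in self.radius_fn(s)],
            },
        }


# ---------------------------------------------------------------------------
# Curve construction


def _dense(n: int, f) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)
    return np.asarray(f(t)).T


def make_curve(spec: PhantomSpec) -> AnalyticCurve:
    """Analytic centerline of the phantom, parameterised by arc length.

    Arc length runs from the proximal curve end (the iliac bifurcation for
    the full aorta) towards the distal end (the aortic valve).
    """
    n = 4001
    if spec.curve_kind == "straight":
        if spec.length_mm <= 0:
            raise ValueError("degenerate parameters: zero length")
        pts = _dense(n, lambda t: (0 * t, 0 * t, t * spec.length_mm))
    elif spec.curve_kind == "semicircle":
        R = spec.semicircle_radius_mm
        if R <= 0:
            raise ValueError("degenerate parameters: zero radius")
        th = np.linspace(0.0, np.pi, n)
        pts = np.stack([R * np.cos(th), 0 * th, R * np.sin(th)], axis=1)
    elif spec.curve_kind == "s_curve":
        L, A, P = spec.length_mm, spec.s_amplitude_mm, spec.s_period_mm
        if L <= 0:
            raise ValueError("degenerate parameters: zero length")
        z = np.linspace(0.0, L, n)
        pts = np.stack([0 * z, A * np.sin(2 * np.pi * z / P), z], axis=1)
    else:  # full_aorta
        D, R, A = spec.descending_length_mm, spec.arch_radius_mm, spec.ascending_length_mm
        if min(D, R, A) <= 0:
            raise ValueError("degenerate parameters")
        amp, per = spec.tortuosity_amplitude_mm, spec.tortuosity_period_mm
        z = np.linspace(0.0, D, 2 * n // 3)
        # sin^2 envelope keeps the run C1-continuous with the straight axis
        # at both junctions even when the sinusoid is on
        y = amp * np.sin(np.pi * z / D) ** 2 * np.sin(2 * np.pi * z / per)
        run = np.stack([np.full_like(z, R), y, z], axis=1)
        phi = np.linspace(0.0, np.pi, n // 2)
        arch = np.stack([R * np.cos(phi), 0 * phi, D + R * np.sin(phi)], axis=1)
        t = np.linspace(0.0, A, n // 3)
        asc = np.stack([np.full_like(t, -R), 0 * t, D - t], axis=1)
        pts = np.concatenate([run, arch[1:], asc[1:]], axis=0)
    return AnalyticCurve(pts)


def _radius_fn(spec: PhantomSpec, total_length: float) -> Callable[[np.ndarray], np.ndarray]:
    def gauss(s, c, a, w):
        return a * np.exp(-((s - c) ** 2) / (2.0 * w**2))

    L = total_length

    def r(s):
        s = np.asarray(s, dtype=float)
        out = np.full_like(s, spec.lumen_radius_mm, dtype=float)
        if spec.aneurysm is not None:
            c, a, w = spec.aneurysm
            out = out + gauss(s, c, a, w)
        if spec.curve_kind == "full_aorta" and spec.root_features:
            out = out + gauss(s, L - 10.0, spec.sinus_bulge_mm, 3.0)
            out = out - gauss(s, L - 22.0, spec.stj_narrowing_mm, 2.5)
            out = out - gauss(s, L, spec.annulus_narrowing_mm, 2.0)
        return out

    return r


# ---------------------------------------------------------------------------
# Rasterisation helpers


def _ellipsoid_mask(X, Y, Z, center, semiaxes) -> np.ndarray:
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0


def _tube_mask(pts_flat, shape, start, direction, length, radius) -> np.ndarray:
    """Boolean mask of a straight tube; pts_flat is the (N,3) voxel centres."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    rel = pts_flat - np.asarray(start, dtype=float)
    proj = rel @ direction
    perp = rel - proj[:, None] * direction[None, :]
    d2 = np.einsum("ij,ij->i", perp, perp)
    inside = (proj >= 0.0) & (proj <= length) & (d2 <= radius**2)
    return inside.reshape(shape)


def _perp_basis(t: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(t, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    n = np.cross(t, ref)
    n /= np.linalg.norm(n)
    return n, np.cross(t, n)


# ---------------------------------------------------------------------------
# Main rasteriser


def rasterize_phantom(spec: PhantomSpec):
    """Rasterise a phantom onto a regular grid.

    Returns ``(ImageVolume, LabelVolume, PhantomGroundTruth)``.  Voxels are
    assigned by centre-point inclusion; the same seed always yields
    byte-identical output.
    """
    rng = np.random.default_rng(spec.rng_seed)
    curve = make_curve(spec)
    L = curve.total_length
    r_fn = _radius_fn(spec, L)
    h = float(spec.spacing_mm)

    # dense samples for distance queries
    s_dense = np.arange(0.0, L + 0.25, 0.5)
    p_dense = curve.point(s_dense)
    r_dense = r_fn(s_dense)
    wall = spec.wall_thickness_mm
    rmax = float(r_dense.max()) + wall

    # ---- layout of organs (full aorta only) -------------------------------
    organs: Dict[str, dict] = {}
    full = spec.curve_kind == "full_aorta" and spec.include_organs
    if full:
        pv = curve.point(L)                  # aortic valve
        tv = curve.tangent(L)                # points away from the arch (down)
        p_ren = curve.point(spec.renal_arc_mm)
        p_dia = curve.point(spec.diaphragm_arc_mm)
        organs["lv_blood"] = dict(kind="ellipsoid", center=pv + tv * 36.0,
                                  semiaxes=(20.0, 20.0, 38.0), hu=280.0)
        organs["rv_blood"] = dict(kind="ellipsoid", center=p_dia + [45.0, 0.0, 23.0],
                                  semiaxes=(20.0, 20.0, 18.0), hu=250.0)
        organs["liver"] = dict(kind="ellipsoid", center=p_dia + [45.0, 0.0, -25.0],
                               semiaxes=(28.0, 28.0, 20.0), hu=90.0)
        organs["kidney_left"] = dict(kind="ellipsoid", center=p_ren + [38.0, 0.0, 0.0],
                                     semiaxes=(12.0, 10.0, 22.0), hu=100.0)
        organs["kidney_right"] = dict(kind="ellipsoid", center=p_ren - [38.0, 0.0, 0.0],
                                      semiaxes=(12.0, 10.0, 22.0), hu=100.0)
        D, R = spec.descending_length_mm, spec.arch_radius_mm
        for name, phi_deg in (("brachiocephalic_trunk", 145.0),
                              ("left_common_carotid", 90.0),
                              ("left_subclavian", 35.0)):
            phi = np.radians(phi_deg)
            base = np.array([R * np.cos(phi), 0.0, D + R * np.sin(phi)])
            direction = np.array([np.cos(phi), 0.0, np.sin(phi)])
            organs[name] = dict(kind="tube", start=base, direction=direction,
                                length=rmax + 26.0, radius=4.0, hu=300.0)
        p0 = curve.point(0.0)
        for name, sx in (("iliac_left", +1.0), ("iliac_right", -1.0)):
            direction = np.array([sx * np.sin(np.radians(30.0)), 0.0, -np.cos(np.radians(30.0))])
            organs[name] = dict(kind="tube", start=p0, direction=direction,
                                length=rmax + 22.0, radius=6.0, hu=300.0)

    # ---- grid bounds ------------------------------------------------------
    lo = p_dense.min(axis=0) - (rmax + spec.margin_mm)
    hi = p_dense.max(axis=0) + (rmax + spec.margin_mm)
    for o in organs.values():
        if o["kind"] == "ellipsoid":
            c, a = np.asarray(o["center"]), np.asarray(o["semiaxes"])
            lo = np.minimum(lo, c - a - spec.margin_mm)
            hi = np.maximum(hi, c + a + spec.margin_mm)
        else:
            s0 = np.asarray(o["start"])
            s1 = s0 + np.asarray(o["direction"]) * o["length"]
            lo = np.minimum(lo, np.minimum(s0, s1) - o["radius"] - spec.margin_mm)
            hi = np.maximum(hi, np.maximum(s0, s1) + o["radius"] + spec.margin_mm)
    crop_ends = spec.crop_ends
    if crop_ends is None:
        crop_ends = spec.curve_kind != "full_aorta"
    if crop_ends:
        # place each flat end face on the grid boundary (the vessel "leaves
        # the field of view" there) when its outward direction is axial
        for s_end, sign in ((0.0, -1.0), (curve.total_length, +1.0)):
            outward = sign * curve.tangent(s_end)
            z_end = float(curve.point(s_end)[2])
            if outward[2] <= -0.6:
                lo[2] = max(lo[2], z_end)
            elif outward[2] >= 0.6:
                hi[2] = min(hi[2], z_end)
    origin = np.floor(lo / h) * h
    shape = tuple(int(np.ceil((hi[k] - origin[k]) / h)) + 1 for k in range(3))

    xs = origin[0] + h * np.arange(shape[0])
    ys = origin[1] + h * np.arange(shape[1])
    zs = origin[2] + h * np.arange(shape[2])
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts_flat = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    # ---- tube masks --------------------------------------------------------
    tree = cKDTree(p_dense)
    dist, idx = tree.query(pts_flat, workers=-1)
    s_vox = s_dense[idx]
    r_vox = r_fn(s_vox)
    # flat end planes: the tube is cut perpendicular to the curve at both
    # ends instead of carrying rounded caps
    def _snap_axis(t):
        t = np.where(np.abs(t) < 1e-3, 0.0, t)
        return t / np.linalg.norm(t)

    t0, tL = _snap_axis(curve.tangent(0.0)), _snap_axis(curve.tangent(L))
    tol = 1e-6
    near0 = s_vox <= rmax + 5.0
    nearL = s_vox >= L - (rmax + 5.0)
    inside_ends = ~(near0 & ((pts_flat - curve.point(0.0)) @ t0 < -tol)) & ~(
        nearL & ((pts_flat - curve.point(L)) @ tL > tol)
    )
    lumen = ((dist <= r_vox) & inside_ends).reshape(shape)
    aorta = ((dist <= r_vox + wall) & inside_ends).reshape(shape)
    wall_mask = aorta & ~lumen
    if not lumen.any():
        raise ValueError("tube exits the grid / empty lumen")

    # ---- calcification blobs ----------------------------------------------
    calc = np.zeros(shape, dtype=bool)
    if spec.calc_fraction > 0:
        n_lumen = int(lumen.sum())
        for _ in range(2000):
            n_calc = int(calc.sum())
            if n_calc / (n_lumen + n_calc - np.count_nonzero(calc & lumen)) >= spec.calc_fraction:
                break
            sc = rng.uniform(5.0, max(L - 5.0, 6.0))
            psi = rng.uniform(0.0, 2 * np.pi)
            t = curve.tangent(sc)
            nvec, bvec = _perp_basis(t)
            center = curve.point(sc) + float(r_fn(sc)) * (np.cos(psi) * nvec + np.sin(psi) * bvec)
            ci = np.round((center - origin) / h).astype(int)
            w = int(np.ceil(spec.calc_blob_radius_mm / h)) + 1
            sl = tuple(slice(max(ci[k] - w, 0), min(ci[k] + w + 1, shape[k])) for k in range(3))
            d2 = ((X[sl] - center[0]) ** 2 + (Y[sl] - center[1]) ** 2 + (Z[sl] - center[2]) ** 2)
            blob = (d2 <= spec.calc_blob_radius_mm**2) & aorta[sl]
            calc[sl] |= blob
    lumen_true = lumen & ~calc
    wall_mask = wall_mask & ~calc
    n_l, n_c = int(lumen_true.sum()), int(calc.sum())
    calc_fraction = n_c / max(n_l + n_c, 1)

    # ---- organ masks & labels ----------------------------------------------
    labels = np.zeros(shape, dtype=np.int32)
    hu = rng.normal(spec.background_hu, spec.noise_sd_hu, size=shape).astype(np.float32)
    organ_masks: Dict[str, np.ndarray] = {}
    for name, o in organs.items():
        if o["kind"] == "ellipsoid":
            m = _ellipsoid_mask(X, Y, Z, o["center"], o["semiaxes"])
        else:
            m = _tube_mask(pts_flat, shape, o["start"], o["direction"], o["length"], o["radius"])
        m &= ~aorta
        organ_masks[name] = m
        hu[m] = o["hu"] + rng.normal(0.0, spec.noise_sd_hu, size=int(m.sum()))
        labels[m] = VOCABULARY[name]

    hu[wall_mask] = spec.wall_hu + rng.normal(0.0, spec.noise_sd_hu, size=int(wall_mask.sum()))
    hu[lumen_true] = spec.lumen_mean_hu + rng.normal(
        0.0, spec.lumen_sd_hu, size=int(lumen_true.sum())
    )
    hu[calc] = spec.calc_hu + rng.normal(0.0, 30.0, size=int(calc.sum()))

    # hyperdense speckle clusters inside the lumen
    if spec.speckle_fraction > 0:
        target = spec.speckle_fraction * int(lumen_true.sum())
        covered = np.zeros(shape, dtype=bool)
        dist_grid = dist.reshape(shape)
        rvox_grid = r_vox.reshape(shape)
        peripheral = lumen_true & (dist_grid >= spec.speckle_min_radius_frac * rvox_grid)
        lumen_idx = np.argwhere(peripheral if peripheral.any() else lumen_true)
        for _ in range(5000):
            if covered.sum() >= target:
                break
            ci = lumen_idx[rng.integers(len(lumen_idx))]
            w = int(np.ceil(spec.speckle_radius_mm / h)) + 1
            sl = tuple(slice(max(ci[k] - w, 0), min(ci[k] + w + 1, shape[k])) for k in range(3))
            cx = origin + ci * h
            d2 = (X[sl] - cx[0]) ** 2 + (Y[sl] - cx[1]) ** 2 + (Z[sl] - cx[2]) ** 2
            blob = (d2 <= spec.speckle_radius_mm**2) & lumen_true[sl]
            covered[sl] |= blob
        hu[covered] = spec.speckle_hu + rng.normal(0.0, 30.0, size=int(covered.sum()))

    labels[aorta | calc] = VOCABULARY["aorta"]

    if spec.smooth_sigma_mm > 0:
        hu = ndimage.gaussian_filter(hu, sigma=spec.smooth_sigma_mm / h)

    image = ImageVolume(hu.astype(np.float32), np.full(3, h), origin)
    missing = {n for n in VOCABULARY if n != "aorta" and n not in organs}
    label_vol = LabelVolume(labels, np.full(3, h), origin, missing=missing)

    # ---- ground truth -------------------------------------------------------
    landmarks_s: Dict[str, float] = {"bifurcation": 0.0}
    tort: Dict[str, float] = {"full": curve.tortuosity(0.0, L)}
    if spec.curve_kind == "full_aorta":
        D, R = spec.descending_length_mm, spec.arch_radius_mm
        s_arch = lambda phi_deg: D + R * np.radians(phi_deg)
        landmarks_s.update(
            renal=spec.renal_arc_mm,
            diaphragm=spec.diaphragm_arc_mm,
            distal_arch=s_arch(35.0) - 20.0,
            proximal_arch=s_arch(145.0),
            left_common_carotid=s_arch(90.0),
            ventricular_aortic=L,
        )
        if spec.root_features:
            landmarks_s.update(sinus_valsalva=L - 10.0,
                               sinotubular_junction=L - 22.0,
                               annulus=L)
        tort["descending"] = curve.tortuosity(landmarks_s["diaphragm"],
                                              landmarks_s["distal_arch"])
    truth = PhantomGroundTruth(
        curve=curve,
        total_length_mm=L,
        landmarks_s=landmarks_s,
        radius_fn=r_fn,
        tortuosity=tort,
        calc_fraction=calc_fraction,
        lumen_mask=lumen_true,
        calc_mask=calc,
        wall_mask=wall_mask,
    )
    return image, label_vol, truth


# ---------------------------------------------------------------------------
# Field-of-view crops


def crop_axial(image: ImageVolume, labels: LabelVolume, z_min_mm: float, z_max_mm: float):
    """Crop a phantom to an axial (superior-inferior) range.

    World coordinates of the retained voxels are preserved, so ground-truth
    landmark positions remain valid where they are inside the crop.  A
    cardiac-style crop that removes the arch apex leaves two disconnected
    aorta components, as real cardiac field-of-views do.
    """
    zs = image.origin[2] + image.spacing[2] * np.arange(image.shape[2])
    keep = np.where((zs >= z_min_mm) & (zs <= z_max_mm))[0]
    if len(keep) == 0:
        raise ValueError("empty crop range")
    sl = slice(keep[0], keep[-1] + 1)
    new_origin = image.origin.copy()
    new_origin[2] = zs[keep[0]]
    img = ImageVolume(image.voxels[:, :, sl].copy(), image.spacing.copy(), new_origin)
    vox = labels.voxels[:, :, sl].copy()
    present = set(np.unique(vox).tolist())
    missing = {n for n, i in labels.vocabulary.items() if i not in present}
    lab = LabelVolume(vox, labels.spacing.copy(), new_origin,
                      vocabulary=dict(labels.vocabulary), missing=missing)
    return img, lab


def write_truth_json(truth: PhantomGroundTruth, path: "str | Path") -> None:
    Path(path).write_text(json.dumps(truth.to_json_dict(), indent=2, sort_keys=True))
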