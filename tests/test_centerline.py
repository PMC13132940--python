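"""Centerline extraction: endpoints, medial path, spline, local frames."""

import numpy as np
import pytest
from scipy import ndimage

from aortax.centerline import (Centerline, EndpointPair, compute_frames,
                               determine_endpoints, extract_centerline,
                               fit_smoothing_spline)
from aortax.maskops import components_by_size
from aortax.phantom import crop_axial


def _axis_distance(truth, samples):
    s = np.linspace(0.0, truth.total_length_mm, 4000)
    axis = truth.curve.point(s)
    return np.array([np.min(np.linalg.norm(axis - p, axis=1)) for p in samples])


# ---------------------------------------------------------------------------
# endpoints


def test_full_scan_endpoints_at_bifurcation_and_lv(full_case, cfg):
    lumen = full_case["report"].lumen.lumen_mask
    pairs = determine_endpoints(lumen, full_case["labels"], "full", cfg)
    assert len(pairs) == 1 and pairs[0].rule == "iliac_bifurcation->lv_junction"
    truth = full_case["truth"]
    bif_true = truth.curve.point(0.0)
    assert np.linalg.norm(pairs[0].start - bif_true) <= 10.0
    lv_true = truth.curve.point(truth.total_length_mm)
    assert np.linalg.norm(pairs[0].end - lv_true) <= 10.0


def test_abdominal_endpoint_on_topmost_slice(abdominal_case, cfg):
    lumen = abdominal_case["report"].lumen.lumen_mask
    labels = abdominal_case["labels"]
    pairs = determine_endpoints(lumen, labels, "abdominal", cfg)
    zs = labels.origin[2] + labels.spacing[2] * np.arange(labels.shape[2])
    top_occupied = zs[np.where(lumen.any(axis=(0, 1)))[0].max()]
    assert pairs[0].end[2] == pytest.approx(top_occupied, abs=labels.spacing[2])


def test_cardiac_scan_gives_two_endpoint_pairs(cardiac_case, cfg):
    lumen = cardiac_case["report"].lumen.lumen_mask
    pairs = determine_endpoints(lumen, cardiac_case["labels"],
                                "cardiac_two_part", cfg)
    assert len(pairs) == 2
    rules = {p.rule for p in pairs}
    assert "scan_boundary->lv_junction" in rules
    assert "scan_boundary->scan_boundary" in rules
    assert pairs[0].component != pairs[1].component


def test_degenerate_endpoint_pair_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        EndpointPair(np.zeros(3), np.zeros(3), "x")


# ---------------------------------------------------------------------------
# medial path


def test_straight_tube_path_tracks_axis(straight_run):
    d = _axis_distance(straight_run["truth"], straight_run["raw"])
    # every interior path point within one voxel of the true axis
    assert np.quantile(d[3:-3], 1.0) <= np.linalg.norm(
        straight_run["image"].spacing)


def test_semicircle_path_length_within_3_percent(semicircle_run):
    raw = semicircle_run["raw"]
    length = np.sum(np.linalg.norm(np.diff(raw, axis=0), axis=1))
    true = semicircle_run["truth"].total_length_mm
    assert abs(length - true) / true < 0.03


def test_path_endpoints_snap_to_requested_points(straight_run):
    raw, pair = straight_run["raw"], straight_run["pair"]
    sp = straight_run["image"].spacing
    assert np.linalg.norm(raw[0] - pair.start) <= np.linalg.norm(sp)
    assert np.linalg.norm(raw[-1] - pair.end) <= np.linalg.norm(sp)


def test_disconnected_endpoints_raise(straight_run):
    lumen = straight_run["lumen"].lumen_mask.copy()
    lumen[:, :, 40:45] = False          # cut the tube in two
    img = straight_run["image"]
    with pytest.raises(ValueError, match="different lumen components|no route"):
        extract_centerline(lumen, img.spacing, img.origin,
                           straight_run["pair"])


def test_medialness_of_constant_radius_tube(straight_run):
    """Mean distance-to-boundary along the path >= 0.8 x tube radius."""
    img = straight_run["image"]
    lumen = straight_run["lumen"].lumen_mask
    dtb = ndimage.distance_transform_edt(lumen, sampling=img.spacing)
    idx = np.round((straight_run["raw"] - img.origin) / img.spacing).astype(int)
    vals = dtb[tuple(idx[5:-5].T)]
    assert vals.mean() >= 0.8 * 10.0


# ---------------------------------------------------------------------------
# smoothing spline


def test_spline_arc_length_parameterisation(straight_run):
    cl = straight_run["centerline"]
    assert np.all(np.diff(cl.arc_length) > 0)
    assert cl.arc_length[-1] == pytest.approx(cl.total_length_mm)
    assert cl.arc_length[0] == 0.0


def test_noisy_straight_path_tangents_within_2_degrees():
    rng = np.random.default_rng(0)
    z = np.arange(0.0, 100.0, 1.0)
    path = np.stack([rng.uniform(-0.5, 0.5, z.size),
                     rng.uniform(-0.5, 0.5, z.size), z], axis=1)
    cl = fit_smoothing_spline(path, 1.0, residual_rms_mm=0.6)
    angles = np.degrees(np.arccos(np.clip(cl.tangents @ [0, 0, 1], -1, 1)))
    assert angles.max() <= 2.0


def test_semicircle_discrete_curvature(semicircle_run):
    cl = semicircle_run["centerline"]
    p = cl.samples
    # finite-difference curvature away from the ends
    k = []
    for i in range(10, len(p) - 10):
        a, b, c = p[i - 5], p[i], p[i + 5]
        v1, v2 = b - a, c - b
        angle = np.arccos(np.clip(np.dot(v1, v2) /
                                  (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1))
        k.append(angle / (0.5 * (np.linalg.norm(v1) + np.linalg.norm(v2))))
    assert np.median(k) == pytest.approx(1.0 / 50.0, rel=0.10)


def test_spline_requires_enough_points():
    with pytest.raises(ValueError, match="at least 4"):
        fit_smoothing_spline(np.zeros((3, 3)), 1.0)


def test_spline_idempotent_on_straight_path(straight_run):
    cl = straight_run["centerline"]
    refit = fit_smoothing_spline(cl.samples, 1.0, residual_rms_mm=0.6)
    n = min(len(refit.samples), len(cl.samples))
    rms = np.sqrt(np.mean(np.sum((refit.samples[:n] - cl.samples[:n]) ** 2, axis=1)))
    assert rms < 0.1


# ---------------------------------------------------------------------------
# frames


def test_straight_line_frames_are_constant(straight_run):
    cl = straight_run["centerline"]
    assert np.allclose(cl.normals, cl.normals[0], atol=5e-3)
    assert np.allclose(cl.binormals, cl.binormals[0], atol=5e-3)


def test_frames_orthonormal_to_1e6(s_curve_run):
    cl = s_curve_run["centerline"]
    for arr in (cl.tangents, cl.normals, cl.binormals):
        assert np.abs(np.linalg.norm(arr, axis=1) - 1.0).max() <= 1e-6
    assert np.abs(np.einsum("ij,ij->i", cl.tangents, cl.normals)).max() <= 1e-6
    assert np.abs(np.einsum("ij,ij->i", cl.tangents, cl.binormals)).max() <= 1e-6
    assert np.abs(np.einsum("ij,ij->i", cl.normals, cl.binormals)).max() <= 1e-6


def test_no_normal_flips_across_inflections(s_curve_run):
    """The s-curve phantom contains inflection points where a naive Frenet
    normal reverses; the regularised frames never do (brute-force check)."""
    cl = s_curve_run["centerline"]
    dots = np.einsum("ij,ij->i", cl.normals[:-1], cl.normals[1:])
    assert dots.min() >= 0.0
    # frame continuity: <= 15 degrees between consecutive normals at 1 mm
    assert np.degrees(np.arccos(np.clip(dots, -1, 1))).max() <= 15.0


def test_naive_frenet_normal_does_flip_on_s_curve(s_curve_run):
    """Independent check that the flip regularisation is actually needed:
    second-derivative (Frenet) normals reverse sign at the inflection."""
    cl = s_curve_run["centerline"]
    d2 = np.gradient(np.gradient(cl.samples, cl.arc_length, axis=0),
                     cl.arc_length, axis=0)
    norms = np.linalg.norm(d2, axis=1)
    ok = norms > 1e-4
    frenet = d2[ok] / norms[ok, None]
    dots = np.einsum("ij,ij->i", frenet[:-1], frenet[1:])
    assert dots.min() < 0.0


def test_up_vector_parallel_to_tangent_uses_fallback(straight_run):
    cl = Centerline(samples=straight_run["centerline"].samples.copy(),
                    arc_length=straight_run["centerline"].arc_length.copy(),
                    tangents=straight_run["centerline"].tangents.copy())
    out = compute_frames(cl, up_vector=(0.0, 0.0, 1.0))   # ~parallel to the axis
    assert np.abs(np.linalg.norm(out.normals, axis=1) - 1.0).max() <= 1e-6
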