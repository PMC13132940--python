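"""Landmark detection and the ESC segment partition."""

import numpy as np
import pytest

from aortax.centerline import Centerline
from aortax.config import PipelineConfig
from aortax.cpr import CSAProfile
from aortax.landmarks import (Landmark, LandmarkError, anatomical_order_ok,
                              arch_landmarks, diaphragm_landmark,
                              overlap_landmark, partition_segments,
                              renal_landmark, root_landmarks)


def _line_centerline(length=100.0, step=1.0):
    s = np.arange(0.0, length + step / 2, step)
    pts = np.stack([np.zeros_like(s), np.zeros_like(s), s], axis=1)
    t = np.tile([0.0, 0.0, 1.0], (len(s), 1))
    return Centerline(samples=pts, arc_length=s, tangents=t)


# ---------------------------------------------------------------------------
# overlap landmark


def test_overlap_landmark_matches_brute_force(full_case, cfg):
    labels = full_case["labels"]
    report = full_case["report"]
    lumen = report.lumen.lumen_mask
    cl = None
    # rebuild the main centerline from the report's straightened geometry
    sv = report.straightened["main"]
    cl = Centerline(samples=sv.slice_centers,
                    arc_length=sv.slice_arc_lengths,
                    tangents=np.tile([0, 0, 1.0], (sv.n_slices, 1)))
    lm = overlap_landmark(lumen, labels.mask("lv_blood"), cl,
                          cfg.artery_dilation_mm, labels.spacing, labels.origin,
                          name="ventricular_aortic")
    # exhaustive check: the sample at the landmark arc is the true argmin
    from aortax.maskops import com_mm, dilate_mm
    overlap = dilate_mm(lumen, 5.0, labels.spacing) & \
        dilate_mm(labels.mask("lv_blood"), 5.0, labels.spacing)
    com = com_mm(overlap, labels.spacing, labels.origin)
    d = np.linalg.norm(cl.samples - com, axis=1)
    assert lm.arc_length_mm == cl.arc_length[int(np.argmin(d))]


def test_overlap_landmark_too_far_reports_missing(cfg):
    cl = _line_centerline()
    a = np.zeros((40, 40, 80), bool)
    b = np.zeros_like(a)
    a[18:22, 18:22, 10:20] = True
    b[18:22, 18:22, 70:78] = True       # 50 mm away at 1 mm spacing
    with pytest.raises(LandmarkError, match="do not meet"):
        overlap_landmark(a, b, cl, 5.0, np.ones(3), np.zeros(3))


# ---------------------------------------------------------------------------
# arch


def test_arch_landmarks_ordering_and_offset(full_case, landmark_runs, cfg):
    report = full_case["report"]
    lms = {l.name: l for l in report.landmarks["main"]}
    # distal arch lies distal (lower arc) of the proximal arch
    assert lms["distal_arch"].arc_length_mm < lms["proximal_arch"].arc_length_mm
    # the 20 mm offset from the subclavian projection is exact by construction
    truth = full_case["truth"]
    d = truth.curve.arc_of_point(lms["distal_arch"].world_mm)
    assert d == pytest.approx(truth.landmarks_s["distal_arch"], abs=3.0)


def test_arch_landmarks_missing_branch_raises(full_case, cfg):
    labels = full_case["labels"]
    lumen = full_case["report"].lumen.lumen_mask
    sv = full_case["report"].straightened["main"]
    cl = Centerline(samples=sv.slice_centers, arc_length=sv.slice_arc_lengths,
                    tangents=np.tile([0, 0, 1.0], (sv.n_slices, 1)))
    labels.missing.add("left_subclavian")
    try:
        with pytest.raises(LandmarkError, match="left_subclavian"):
            arch_landmarks(lumen, labels, cl, cfg)
    finally:
        labels.missing.discard("left_subclavian")


def test_distal_arch_clamped_at_centerline_start(cfg):
    """A subclavian projection within 20 mm of the centerline start clamps
    the distal-arch landmark to arc 0 with a warning."""
    cl = _line_centerline(60.0)
    from aortax.io import LabelVolume, VOCABULARY
    shape = (40, 40, 61)
    lumen = np.zeros(shape, bool)
    lumen[17:23, 17:23, :] = True
    lab = np.zeros(shape, np.int32)
    lab[24:28, 18:22, 12:18] = VOCABULARY["brachiocephalic_trunk"]
    lab[24:28, 18:22, 2:8] = VOCABULARY["left_subclavian"]
    labels = LabelVolume(lab, np.ones(3), np.array([-20.0, -20.0, 0.0]))
    prox, distal, warns = arch_landmarks(lumen, labels, cl, cfg)
    assert distal.arc_length_mm == 0.0
    assert any("clamped" in w for w in warns)


# ---------------------------------------------------------------------------
# diaphragm


def test_diaphragm_between_rv_and_liver(full_case):
    report = full_case["report"]
    truth = full_case["truth"]
    lm = {l.name: l for l in report.landmarks["main"]}["diaphragm"]
    err = truth.curve.arc_of_point(lm.world_mm) - truth.landmarks_s["diaphragm"]
    assert abs(err) <= 10.0


def test_diaphragm_iteration_properties():
    """Alternating closest-point iteration: the pair distance never
    increases, and the midpoint is equidistant from both final points."""
    rv = np.zeros((40, 40, 60), bool)
    liv = np.zeros_like(rv)
    rv[10:25, 10:25, 38:52] = True
    liv[14:30, 12:28, 10:30] = True
    cl = _line_centerline(60.0)
    lm = diaphragm_landmark(rv, liv, cl, np.ones(3), np.zeros(3))
    # midpoint is at z=(30+38)/2 - 0.5..: between the facing surfaces
    assert 31.0 <= lm.world_mm[2] <= 36.0
    assert lm.name == "diaphragm"


def test_diaphragm_missing_mask_raises():
    cl = _line_centerline(60.0)
    with pytest.raises(LandmarkError):
        diaphragm_landmark(np.zeros((4, 4, 4), bool),
                           np.ones((4, 4, 4), bool), cl, np.ones(3), np.zeros(3))


# ---------------------------------------------------------------------------
# renal


def test_renal_landmark_matches_brute_force_line_distance(full_case):
    labels = full_case["labels"]
    report = full_case["report"]
    sv = report.straightened["main"]
    cl = Centerline(samples=sv.slice_centers, arc_length=sv.slice_arc_lengths,
                    tangents=np.tile([0, 0, 1.0], (sv.n_slices, 1)))
    lm = renal_landmark(labels.mask("kidney_left"), labels.mask("kidney_right"),
                        cl, labels.spacing, labels.origin)
    from aortax.maskops import com_mm
    a = com_mm(labels.mask("kidney_left"), labels.spacing, labels.origin)
    b = com_mm(labels.mask("kidney_right"), labels.spacing, labels.origin)
    axis = (b - a) / np.linalg.norm(b - a)
    rel = cl.samples - a
    d = np.linalg.norm(rel - np.outer(rel @ axis, axis), axis=1)
    assert lm.arc_length_mm == cl.arc_length[int(np.argmin(d))]
    truth = full_case["truth"]
    err = truth.curve.arc_of_point(lm.world_mm) - truth.landmarks_s["renal"]
    assert abs(err) <= 10.0


def test_degenerate_kidney_line_raises():
    cl = _line_centerline(40.0)
    k = np.zeros((20, 20, 40), bool)
    k[8:12, 8:12, 18:22] = True
    with pytest.raises(LandmarkError, match="degenerate kidney line"):
        renal_landmark(k, k.copy(), cl, np.ones(3), np.zeros(3))


# ---------------------------------------------------------------------------
# aortic root


def _profile(arcs, areas):
    return CSAProfile(np.asarray(arcs, float), np.asarray(areas, float),
                      np.ones(len(arcs), bool))


def test_root_windows_and_tie_rules(cfg):
    # synthetic profile: bulge at 90, narrowing at 78, va at 100
    arcs = np.arange(0.0, 111.0)
    areas = 300 + 200 * np.exp(-((arcs - 90) ** 2) / 18.0) \
        - 120 * np.exp(-((arcs - 78) ** 2) / 12.0)
    lms = root_landmarks(_profile(arcs, areas), va_arc=100.0, config=cfg)
    assert lms["sinus_valsalva"][0] == pytest.approx(90.0, abs=1.0)
    stj_arc = lms["sinotubular_junction"][0]
    # STJ window starts exactly at sinus - 5 and spans to sinus - 25
    assert lms["sinus_valsalva"][0] - 25 <= stj_arc <= lms["sinus_valsalva"][0] - 5
    assert stj_arc == pytest.approx(78.0, abs=1.5)


def test_monotone_profile_puts_sinus_at_window_far_end(cfg):
    arcs = np.arange(0.0, 111.0)
    areas = 1000.0 - 5.0 * arcs          # monotone: max furthest from va
    lms = root_landmarks(_profile(arcs, areas), va_arc=100.0, config=cfg)
    assert lms["sinus_valsalva"][0] == pytest.approx(80.0, abs=1e-9)


def test_uncovered_root_window_reports_missing(cfg):
    arcs = np.arange(95.0, 111.0)        # window (80, 100) barely covered
    with pytest.raises(LandmarkError, match="annulus|window"):
        root_landmarks(_profile(arcs, np.ones_like(arcs)), va_arc=120.0,
                       config=cfg)


def test_root_landmark_recovery_on_phantom(full_case):
    report = full_case["report"]
    truth = full_case["truth"]
    lms = {l.name: l for l in report.landmarks["main"]}
    for name in ("sinus_valsalva", "sinotubular_junction", "annulus"):
        err = truth.curve.arc_of_point(lms[name].world_mm) - truth.landmarks_s[name]
        assert abs(err) <= 3.0, (name, err)


# ---------------------------------------------------------------------------
# segments


def test_full_partition_contiguous_and_complete(full_case):
    report = full_case["report"]
    segs = {s.name: s for t in report.segments for s in t}
    assert set(segs) == {"infrarenal", "suprarenal", "descending", "arch",
                         "ascending"}
    assert all(s.available for s in segs.values())
    order = ["infrarenal", "suprarenal", "descending", "arch", "ascending"]
    for lo, hi in zip(order, order[1:]):
        assert segs[lo].end_mm == pytest.approx(segs[hi].start_mm, abs=1e-9)
    assert segs["infrarenal"].start_mm == 0.0


def test_segment_bounds_equal_landmark_arcs(full_case):
    report = full_case["report"]
    lms = {l.name: l for l in report.landmarks["main"]}
    segs = {s.name: s for t in report.segments for s in t}
    assert segs["suprarenal"].start_mm == lms["renal"].arc_length_mm
    assert segs["descending"].start_mm == lms["diaphragm"].arc_length_mm
    assert segs["arch"].start_mm == lms["distal_arch"].arc_length_mm
    assert segs["ascending"].start_mm == lms["proximal_arch"].arc_length_mm


def test_missing_renal_degrades_not_merges(full_case):
    report = full_case["report"]
    lms = {l.name: l for l in report.landmarks["main"]}
    partial = {k: v for k, v in lms.items() if k != "renal"}
    sv = report.straightened["main"]
    cl = Centerline(samples=sv.slice_centers, arc_length=sv.slice_arc_lengths,
                    tangents=np.tile([0, 0, 1.0], (sv.n_slices, 1)))
    table = partition_segments(partial, cl, "full")
    by_name = {s.name: s for s in table}
    assert not by_name["infrarenal"].available
    assert not by_name["suprarenal"].available
    assert by_name["descending"].available


def test_abdominal_partition(abdominal_case):
    segs = {s.name: s for t in abdominal_case["report"].segments for s in t}
    assert {"infrarenal", "suprarenal"} <= set(segs)
    assert "arch" not in segs and "ascending" not in segs


def test_anatomical_order_invariant(full_case):
    lms = {l.name: l for l in full_case["report"].landmarks["main"]}
    assert anatomical_order_ok(lms)
    # perturbing one landmark must break it
    bad = dict(lms)
    bad["diaphragm"] = Landmark("diaphragm", lms["proximal_arch"].arc_length_mm
                                + 1.0, lms["diaphragm"].world_mm, "test")
    assert not anatomical_order_ok(bad)


def test_landmark_world_point_lies_on_centerline(full_case):
    report = full_case["report"]
    sv = report.straightened["main"]
    for lm in report.landmarks["main"]:
        if lm.name in ("annulus",):      # annulus lives on the root extension
            continue
        k = int(np.argmin(np.abs(sv.slice_arc_lengths - lm.arc_length_mm)))
        assert np.linalg.norm(sv.slice_centers[k] - lm.world_mm) <= 2.0, lm.name
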