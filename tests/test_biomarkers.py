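"""Biomarkers: maximal diameters, tortuosity, QC checks, agreement stats."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aortax.biomarkers import (agreement_metrics, max_diameter, tortuosity,
                               TortuosityResult)
from aortax.landmarks import Landmark
from aortax.qc import (classify_scan, ellipse_aspect_check,
                       surface_to_volume_check)


def _disk(radius_px, shape=128):
    ij = np.indices((shape, shape)) - (shape - 1) / 2.0
    return (ij[0] ** 2 + ij[1] ** 2) <= radius_px ** 2


def _ellipse(a_px, b_px, shape=128, angle_deg=0.0):
    ij = np.indices((shape, shape)) - (shape - 1) / 2.0
    th = np.radians(angle_deg)
    u = ij[0] * np.cos(th) + ij[1] * np.sin(th)
    v = -ij[0] * np.sin(th) + ij[1] * np.cos(th)
    return (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0


# ---------------------------------------------------------------------------
# maximal diameter


def test_disk_diameter_recovered():
    res = 0.5
    mask = _disk(20.0)                    # radius 10 mm at 0.5 mm pixels
    d, com, _ = max_diameter(mask, res)
    assert d == pytest.approx(20.0, abs=0.5)


def test_ellipse_major_axis_found():
    res = 0.5
    mask = _ellipse(30.0, 20.0, angle_deg=30.0)   # semi-axes 15/10 mm
    d, com, angle = max_diameter(mask, res)
    assert d == pytest.approx(30.0, abs=0.5)
    # brute-force oracle: longest pixel-pair chord through the COM
    ij = np.argwhere(mask).astype(float)
    c = ij.mean(axis=0)
    rel = ij - c
    r = np.linalg.norm(rel, axis=1)
    th = np.arctan2(rel[:, 1], rel[:, 0])
    best = 0.0
    for k in range(180):
        a = np.radians(k)
        along = np.abs(((th - a) + np.pi / 2) % np.pi - np.pi / 2) < np.radians(1.5)
        if along.any():
            proj = rel[along] @ [np.cos(a), np.sin(a)]
            best = max(best, (proj.max() - proj.min()) * res)
    assert d == pytest.approx(best, abs=0.75)


def test_single_pixel_mask_degenerate():
    mask = np.zeros((32, 32), bool)
    mask[16, 16] = True
    d, _, _ = max_diameter(mask, 0.5)
    assert d <= 2 * 0.5                   # about one pixel


def test_crescent_com_outside_returns_zero():
    mask = _disk(24.0) & ~_disk(18.0)
    mask[:, :64] = False                  # half-annulus: COM in the void
    d, _, _ = max_diameter(mask, 0.5)
    assert d == 0.0


def test_empty_slice_raises():
    with pytest.raises(ValueError, match="empty"):
        max_diameter(np.zeros((8, 8), bool), 0.5)


def test_max_chord_at_least_equivalent_circle_diameter(full_case):
    for m in full_case["report"].measurements:
        if m.qc_pass:
            eq = 2.0 * np.sqrt(m.csa_mm2 / np.pi)
            assert m.max_diameter_mm >= eq - 1.0, m.name


# ---------------------------------------------------------------------------
# tortuosity


def _lm(name, arc, xyz):
    return Landmark(name, arc, np.asarray(xyz, float), "test")


def test_tortuosity_of_straight_segment_is_one():
    a = _lm("a", 0.0, (0, 0, 0))
    b = _lm("b", 80.0, (0, 0, 80.0))
    t = tortuosity(None, a, b, "descending")
    assert t.index == pytest.approx(1.0, abs=1e-9)


def test_tortuosity_semicircle_analytic():
    R = 50.0
    a = _lm("a", 0.0, (R, 0, 0))
    b = _lm("b", np.pi * R, (-R, 0, 0))
    t = tortuosity(None, a, b, "descending")
    assert t.index == pytest.approx(np.pi / 2, abs=1e-9)


def test_coincident_landmarks_raise():
    a = _lm("a", 10.0, (1, 2, 3))
    with pytest.raises(ValueError, match="coincident"):
        tortuosity(None, a, _lm("b", 20.0, (1, 2, 3)), "x")


def test_index_never_below_one_across_phantoms(landmark_runs):
    for run in landmark_runs:
        for t in run["report"].tortuosity:
            assert t.index >= 1.0 - 1e-6


def test_tortuosity_result_validates_index():
    with pytest.raises(ValueError):
        TortuosityResult("x", 50.0, 100.0, 0.5)


# ---------------------------------------------------------------------------
# QC: aspect ratio, surface/volume, classification


def test_disk_aspect_ratio_isotropic():
    ratio, ok = ellipse_aspect_check(_disk(20.0), 2.5)
    assert ratio == pytest.approx(1.0, abs=0.05)
    assert ok


def test_bar_aspect_ratio_fails_threshold():
    bar = np.zeros((64, 64), bool)
    bar[12:52, 27:37] = True              # 40 x 10 bar
    ratio, ok = ellipse_aspect_check(bar, 2.5)
    # brute-force second moments of the same pixel set
    ij = np.argwhere(bar).astype(float)
    c = ij - ij.mean(axis=0)
    evals = np.linalg.eigvalsh(c.T @ c / len(c))
    assert ratio == pytest.approx(float(np.sqrt(evals[1] / evals[0])), abs=1e-9)
    assert ratio == pytest.approx(4.0, abs=0.3)
    assert not ok


def test_aspect_ratio_boundary_passes():
    bar = np.zeros((64, 64), bool)
    bar[12:52, 27:37] = True
    ratio, ok = ellipse_aspect_check(bar, threshold=ratio_of(bar))
    assert ok                             # <= semantics: exactly at threshold


def ratio_of(mask):
    return ellipse_aspect_check(mask, 1e9)[0]


def test_sphere_surface_to_volume():
    R = 20.0
    shape = (50, 50, 50)
    ij = np.indices(shape) - 24.5
    sphere = (ij ** 2).sum(axis=0) <= R ** 2
    ratio, flag = surface_to_volume_check(sphere, np.ones(3),
                                          threshold_per_mm=0.4)
    assert ratio == pytest.approx(3.0 / R, rel=0.15)
    assert not flag


def test_porous_mask_flags_roughness():
    """Salt-and-pepper holes raise the surface-to-volume ratio of an
    otherwise identical tube and trip the flag."""
    rng = np.random.default_rng(0)
    ij = np.indices((40, 40)) - 19.5
    disk = (ij[0] ** 2 + ij[1] ** 2) <= 144
    tube = np.repeat(disk[:, :, None], 60, axis=2)
    smooth_ratio, _ = surface_to_volume_check(tube, np.ones(3), 1e9)
    porous = tube & (rng.random(tube.shape) > 0.12)
    porous_ratio, flag = surface_to_volume_check(porous, np.ones(3),
                                                 smooth_ratio * 1.5)
    assert porous_ratio > smooth_ratio
    assert flag


def test_threshold_above_ratio_does_not_flag():
    cube = np.zeros((12, 12, 12), bool)
    cube[2:10, 2:10, 2:10] = True
    ratio, _ = surface_to_volume_check(cube, np.ones(3), 1e9)
    _, flag = surface_to_volume_check(cube, np.ones(3), ratio + 0.1)
    assert not flag


def test_classification_outcomes(full_case, cardiac_case, abdominal_case, cfg):
    assert full_case["report"].classification.scan_class == "full"
    cc = cardiac_case["report"].classification
    assert cc.scan_class == "cardiac_two_part" and cc.component_count == 2
    assert abdominal_case["report"].classification.scan_class == "abdominal"


def test_empty_aorta_rejected(full_case, cfg):
    labels = full_case["labels"]
    empty = np.zeros_like(labels.mask("aorta"))
    cls = classify_scan(empty, labels, cfg)
    assert cls.scan_class == "rejected"
    assert "no aorta" in cls.reasons


# ---------------------------------------------------------------------------
# agreement metrics

MANUAL = np.array([20., 22., 25., 28., 30., 32., 34., 36., 38., 40.])
DELTA = np.array([0.5, -0.3, 1.2, 0.1, -0.7, 0.4, 3.5, -0.2, 0.3, 0.8])
# frozen oracle: exact rational/symbolic arithmetic on the table above
EXPECTED = {
    "mae": 0.800000000000000000,
    "mape_percent": 2.62432594409374595,
    "bias": 0.560000000000000000,
    "pearson_r": 0.986562088712439542,
    "cv_percent": 1.70211777970232962,
    "loa_low": -1.73356293424299420,
    "loa_high": 2.85356293424299420,
    "out_of_loa_fraction": 0.1,
}


def test_agreement_reproduces_hand_computed_table():
    stats = agreement_metrics(MANUAL + DELTA, MANUAL)
    for key, want in EXPECTED.items():
        assert getattr(stats, key) == pytest.approx(want, abs=1e-9), key
    assert stats.n == 10


def test_identical_pairs_all_zero():
    stats = agreement_metrics(MANUAL, MANUAL)
    assert stats.mae == 0.0 and stats.bias == 0.0 and stats.cv_percent == 0.0
    assert stats.out_of_loa_fraction == 0.0


def test_perfect_linear_relation_pearson_one():
    stats = agreement_metrics(2.0 * MANUAL, MANUAL)
    assert stats.pearson_r == pytest.approx(1.0, abs=1e-12)


def test_agreement_contract_violations():
    with pytest.raises(ValueError):
        agreement_metrics([1.0], [1.0])
    with pytest.raises(ValueError):
        agreement_metrics([1.0, 2.0], [0.0, 2.0])


@given(st.lists(st.tuples(st.floats(10.0, 60.0), st.floats(-3.0, 3.0)),
                min_size=3, max_size=40))
def test_agreement_invariants(pairs):
    m = np.array([p[0] for p in pairs])
    a = m + np.array([p[1] for p in pairs])
    stats = agreement_metrics(a, m)
    assert stats.mae >= abs(stats.bias) - 1e-12
    assert stats.loa_low <= stats.bias <= stats.loa_high
    assert 0.0 <= stats.out_of_loa_fraction <= 1.0
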