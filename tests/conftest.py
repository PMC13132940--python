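"""Shared phantom fixtures.

Expensive phantom pipelines are session-scoped and shared across test
modules.  Phantom grids use 1.5 mm voxels for the anatomical full-aorta
cases (fast, and well within the landmark tolerances) and 0.8 mm for the
geometric tube cases where analytic accuracy is asserted.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from aortax.centerline import (compute_frames, determine_endpoints,
                               extract_centerline, fit_smoothing_spline)
from aortax.config import PipelineConfig
from aortax.lumen import refine
from aortax.phantom import PhantomSpec, crop_axial, rasterize_phantom
from aortax.pipeline import analyze

settings.register_profile("ci", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("ci")

SPACING_FULL = 1.5
SPACING_TUBE = 0.8


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


def _tube_run(spec: PhantomSpec):
    """Rasterise a standalone tube and take it through refinement,
    centerline extraction and frame computation."""
    image, labels, truth = rasterize_phantom(spec)
    result = refine(labels.mask("aorta"), image)
    pair = determine_endpoints(result.lumen_mask, labels, "partial")[0]
    raw = extract_centerline(result.lumen_mask, image.spacing, image.origin, pair)
    from aortax.centerline import default_residual_mm
    cl = fit_smoothing_spline(raw, 1.0,
                              residual_rms_mm=default_residual_mm(image.spacing))
    cl = compute_frames(cl)
    return dict(spec=spec, image=image, labels=labels, truth=truth,
                lumen=result, pair=pair, raw=raw, centerline=cl)


@pytest.fixture(scope="session")
def straight_run():
    return _tube_run(PhantomSpec(curve_kind="straight", length_mm=100.0,
                                 spacing_mm=SPACING_TUBE, rng_seed=1,
                                 include_organs=False))


@pytest.fixture(scope="session")
def semicircle_run():
    return _tube_run(PhantomSpec(curve_kind="semicircle",
                                 semicircle_radius_mm=50.0,
                                 spacing_mm=SPACING_TUBE, rng_seed=1,
                                 include_organs=False))


@pytest.fixture(scope="session")
def s_curve_run():
    return _tube_run(PhantomSpec(curve_kind="s_curve", length_mm=100.0,
                                 s_amplitude_mm=8.0, s_period_mm=50.0,
                                 spacing_mm=SPACING_TUBE, rng_seed=1,
                                 include_organs=False))


@pytest.fixture(scope="session")
def full_case():
    """Anatomical full-aorta phantom with 3% calcification, analysed."""
    spec = PhantomSpec(rng_seed=1, spacing_mm=SPACING_FULL, calc_fraction=0.03)
    image, labels, truth = rasterize_phantom(spec)
    report = analyze(image, labels)
    return dict(spec=spec, image=image, labels=labels, truth=truth,
                report=report)


@pytest.fixture(scope="session")
def const_case():
    """Constant-radius (10 mm) full aorta without root features."""
    spec = PhantomSpec(rng_seed=2, spacing_mm=SPACING_FULL, root_features=False)
    image, labels, truth = rasterize_phantom(spec)
    report = analyze(image, labels)
    return dict(spec=spec, image=image, labels=labels, truth=truth,
                report=report)


@pytest.fixture(scope="session")
def aneurysm_case():
    """Infrarenal aneurysm bump: +8 mm radius at arc 20 mm."""
    spec = PhantomSpec(rng_seed=3, spacing_mm=SPACING_FULL,
                       aneurysm=(20.0, 8.0, 8.0), root_features=False)
    image, labels, truth = rasterize_phantom(spec)
    report = analyze(image, labels)
    return dict(spec=spec, image=image, labels=labels, truth=truth,
                report=report)


@pytest.fixture(scope="session")
def landmark_runs():
    """Ten seeded full-aorta phantoms (varying noise, calcification layout
    and descending tortuosity), analysed end to end."""
    runs = []
    for seed in range(10):
        spec = PhantomSpec(rng_seed=seed, spacing_mm=SPACING_FULL,
                           tortuosity_amplitude_mm=3.0 * (seed % 3))
        image, labels, truth = rasterize_phantom(spec)
        runs.append(dict(spec=spec, truth=truth,
                         report=analyze(image, labels)))
    return runs


@pytest.fixture(scope="session")
def noncontrast_case():
    spec = PhantomSpec.non_contrast(spacing_mm=1.0, rng_seed=4)
    image, labels, truth = rasterize_phantom(spec)
    report = analyze(image, labels)
    return dict(spec=spec, image=image, labels=labels, report=report)


@pytest.fixture(scope="session")
def cardiac_case(full_case):
    """Cardiac field of view: the arch apex is cut, leaving two aorta
    components (ascending+root and a descending portion)."""
    image, labels = crop_axial(full_case["image"], full_case["labels"],
                               93.0, 162.0)
    report = analyze(image, labels)
    return dict(image=image, labels=labels, truth=full_case["truth"],
                report=report)


@pytest.fixture(scope="session")
def abdominal_case(full_case):
    image, labels = crop_axial(full_case["image"], full_case["labels"],
                               -30.0, 105.0)
    report = analyze(image, labels)
    return dict(image=image, labels=labels, truth=full_case["truth"],
                report=report)
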