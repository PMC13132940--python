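"""End-to-end orchestration: classify, refine, centerline, CPR, landmarks,
segments, biomarkers, report; batch processing over directories.

Degraded inputs (missing organs, partial field of view) produce partial
reports with warnings; scans failing quality control are rejected with
machine-readable reasons.  One failing case never aborts a batch.
"""

from __future__ import annotations

import json
import time
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .biomarkers import measure_root, measure_segments, tortuosity
from .centerline import (Centerline, compute_frames, determine_endpoints,
                         extract_centerline, fit_smoothing_spline)
from .config import PipelineConfig
from .cpr import csa_profile, straighten
from .io import ImageVolume, LabelVolume, read_image, read_labels
from .landmarks import (Landmark, LandmarkError, anatomical_order_ok,
                        arch_landmarks, build_root_centerline,
                        diaphragm_landmark, overlap_landmark, partition_segments,
                        renal_landmark, root_landmarks)
from .lumen import refine
from .maskops import dilate_mm
from .qc import ScanClassification, classify_scan, surface_to_volume_check
from .report import ReportDocument, write_report

__all__ = ["analyze", "batch", "RunManifest", "CaseResult"]


@dataclass
class CaseResult:
    case: str
    status: str                    # ok | degraded | rejected | failed
    reasons: List[str] = field(default_factory=list)
    seconds: float = 0.0
    report_path: Optional[str] = None


@dataclass
class RunManifest:
    cases: List[CaseResult] = field(default_factory=list)

    def counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for c in self.cases:
            out[c.status] = out.get(c.status, 0) + 1
        return out

    def write(self, path: "str | Path") -> None:
        doc = {"counts": self.counts(),
               "cases": [{"case": c.case, "status": c.status,
                          "reasons": c.reasons, "seconds": round(c.seconds, 2),
                          "report": c.report_path} for c in self.cases]}
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def _fit_centerline(lumen_mask, labels, pair, config, name) -> Centerline:
    from .centerline import default_residual_mm
    raw = extract_centerline(lumen_mask, labels.spacing, labels.origin, pair,
                             eps_mm=config.medial_eps_mm)
    residual = config.spline_residual_mm or default_residual_mm(labels.spacing)
    cl = fit_smoothing_spline(raw, config.centerline_step_mm,
                              residual_rms_mm=residual, name=name)
    return compute_frames(cl)


def analyze(image: Union[ImageVolume, str, Path],
            labels: Union[LabelVolume, str, Path],
            config: Optional[PipelineConfig] = None,
            out_dir: Optional["str | Path"] = None,
            scan_type: str = "auto",
            stem: str = "aorta",
            figure: bool = True) -> ReportDocument:
    """Run the full analysis on one scan.

    ``scan_type`` overrides the automatic field-of-view classification
    (auto | full | abdominal | cardiac_two_part | partial).
    """
    config = config or PipelineConfig()
    if not isinstance(image, ImageVolume):
        image = read_image(image)
    if not isinstance(labels, LabelVolume):
        labels = read_labels(labels, reference=image)

    warnings: List[str] = []
    errors: List[str] = []
    aorta = labels.mask("aorta")

    cls = classify_scan(aorta, labels, config)
    if scan_type != "auto" and cls.scan_class != "rejected":
        cls = ScanClassification(scan_type, reasons=[f"forced (auto: {cls.scan_class})"],
                                 component_count=cls.component_count)
    report = ReportDocument(status="rejected", classification=cls, config=config)
    if cls.scan_class == "rejected":
        report.errors = list(cls.reasons)
        if out_dir:
            write_report(report, out_dir, stem, figure)
        return report

    # ---- lumen refinement + quality gates ---------------------------------
    lumen_res = refine(aorta, image, config)
    report.lumen = lumen_res
    if lumen_res.failed or not lumen_res.lumen_mask.any():
        cls.reasons.append("empty lumen after refinement (probable non-contrast scan)")
        cls.scan_class = "rejected"
        report.errors = list(cls.reasons)
        report.lumen = None
        if out_dir:
            write_report(report, out_dir, stem, figure)
        return report
    ratio, rough = surface_to_volume_check(lumen_res.lumen_mask, labels.spacing,
                                           config=config)
    cls.surface_to_volume_per_mm = ratio
    if rough:
        cls.reasons.append(f"surface-to-volume ratio {ratio:.3f}/mm exceeds "
                           f"{config.surface_volume_threshold_per_mm}/mm "
                           "(rough or porous lumen; probable non-contrast scan)")
        cls.scan_class = "rejected"
        report.errors = list(cls.reasons)
        if out_dir:
            write_report(report, out_dir, stem, figure)
        return report
    lumen = lumen_res.lumen_mask

    # ---- centerlines -------------------------------------------------------
    try:
        pairs = determine_endpoints(lumen, labels, cls.scan_class, config)
    except ValueError as exc:
        warnings.append(f"endpoint rule failed ({exc}); falling back to partial")
        cls.scan_class = "partial"
        pairs = determine_endpoints(lumen, labels, "partial", config)

    from .maskops import components_by_size
    comps = (components_by_size(lumen, labels.spacing, config.min_component_volume_mm3)
             if cls.scan_class == "cardiac_two_part" else [lumen])

    centerlines: Dict[str, Centerline] = {}
    masks: Dict[str, np.ndarray] = {}
    for pair in pairs:
        mask = comps[pair.component] if cls.scan_class == "cardiac_two_part" else lumen
        if cls.scan_class == "cardiac_two_part":
            name = "ascending" if pair.rule.endswith("lv_junction") else "descending"
        else:
            name = "main"
        try:
            centerlines[name] = _fit_centerline(mask, labels, pair, config, name)
            masks[name] = mask
        except ValueError as exc:
            errors.append(f"centerline {name} failed: {exc}")
    if not centerlines:
        cls.scan_class = "rejected"
        cls.reasons.extend(errors or ["no centerline"])
        report.errors = list(cls.reasons)
        if out_dir:
            write_report(report, out_dir, stem, figure)
        return report

    # ---- CPR ----------------------------------------------------------------
    for name, cl in centerlines.items():
        sv = straighten(image, masks[name], cl, config)
        report.straightened[name] = sv
        report.profiles[name] = csa_profile(sv)

    # ---- landmarks ----------------------------------------------------------
    sp, og = labels.spacing, labels.origin
    landmarks: Dict[str, Dict[str, Landmark]] = {n: {} for n in centerlines}

    def try_landmark(cname, fn, *args, **kw):
        try:
            lm = fn(*args, **kw)
            landmarks[cname][lm.name] = lm
            return lm
        except LandmarkError as exc:
            warnings.append(str(exc))
            return None

    root_ready: List[Tuple[str, Dict[str, Tuple[float, float]]]] = []
    for cname, cl in centerlines.items():
        mask = masks[cname]
        wants_body = cname == "main" and cls.scan_class in ("full", "abdominal")
        wants_root = (cname == "ascending") or (
            cname == "main" and cls.scan_class == "full")
        if wants_body:
            landmarks[cname]["bifurcation"] = Landmark(
                "bifurcation", 0.0, cl.point(0.0), "centerline start")
            if labels.has("kidney_left") and labels.has("kidney_right"):
                try_landmark(cname, renal_landmark, labels.mask("kidney_left"),
                             labels.mask("kidney_right"), cl, sp, og)
            else:
                warnings.append("renal: kidney labels missing; "
                                "suprarenal/infrarenal split unavailable")
            if labels.has("rv_blood") and labels.has("liver"):
                try_landmark(cname, diaphragm_landmark, labels.mask("rv_blood"),
                             labels.mask("liver"), cl, sp, og)
            else:
                warnings.append("diaphragm: RV or liver label missing; "
                                "falling back to scan boundary")
        if cls.scan_class == "full" and cname == "main":
            try:
                prox, distal, w = arch_landmarks(mask, labels, cl, config)
                landmarks[cname][prox.name] = prox
                landmarks[cname][distal.name] = distal
                warnings.extend(w)
                if labels.has("left_common_carotid"):
                    try_landmark(cname, overlap_landmark, mask,
                                 labels.mask("left_common_carotid"), cl,
                                 config.artery_dilation_mm, sp, og,
                                 name="left_common_carotid")
            except LandmarkError as exc:
                warnings.append(f"{exc}; arch segment unavailable")
        if wants_root:
            if labels.has("lv_blood"):
                va = try_landmark(cname, overlap_landmark, mask,
                                  labels.mask("lv_blood"), cl,
                                  config.artery_dilation_mm, sp, og,
                                  name="ventricular_aortic")
                if va is not None:
                    try:
                        root_cl, root_prof, va_arc = build_root_centerline(
                            mask, labels, cl, image, config)
                        lms = root_landmarks(root_prof, va_arc, config)
                        for nm, (arc, _a) in lms.items():
                            world = root_cl.point(arc)
                            main_arc = cl.nearest_arc(world)
                            landmarks[cname][nm] = Landmark(
                                nm, main_arc, world, "root CSA window")
                        sv_root = straighten(image, masks[cname] |
                                             labels.mask("lv_blood"), root_cl, config)
                        sv_root.name = "root"
                        report.straightened[f"{cname}_root"] = sv_root
                        report.profiles[f"{cname}_root"] = root_prof
                        root_ready.append((cname, lms))
                    except (LandmarkError, ValueError) as exc:
                        warnings.append(f"root landmarks failed: {exc}")
            else:
                warnings.append("ventricular_aortic: LV label missing")

    # ---- segments & measurements -------------------------------------------
    for cname, cl in centerlines.items():
        table = partition_segments(landmarks[cname], cl, cls.scan_class)
        table_avail = [s for s in table if s.available]
        for s in table:
            if not s.available:
                warnings.append(f"segment {s.name} unavailable: {s.reason}")
        report.segments.append(table)
        meas = measure_segments(report.straightened[cname],
                                report.profiles[cname], table, config)
        for m in meas:
            m.centerline_name = cname
            warnings.extend(f"{m.name}: {w}" for w in m.warnings)
        report.measurements.extend(meas)
    for cname, lms in root_ready:
        meas = measure_root(report.straightened[f"{cname}_root"], lms, config)
        for m in meas:
            m.centerline_name = f"{cname}_root"
            warnings.extend(f"{m.name}: {w}" for w in m.warnings)
        report.measurements.extend(meas)

    # ---- tortuosity ---------------------------------------------------------
    if cls.scan_class == "full":
        main_lms = landmarks.get("main", {})
        if not anatomical_order_ok(main_lms):
            warnings.append("landmark ordering violated; check segmentation")
        if "distal_arch" in main_lms and "diaphragm" in main_lms:
            report.tortuosity.append(tortuosity(centerlines["main"],
                                                main_lms["distal_arch"],
                                                main_lms["diaphragm"],
                                                "descending"))
        if "ventricular_aortic" in main_lms and "bifurcation" in main_lms:
            report.tortuosity.append(tortuosity(centerlines["main"],
                                                main_lms["bifurcation"],
                                                main_lms["ventricular_aortic"],
                                                "full_aortic"))
    else:
        warnings.append("tortuosity indices require a full-aorta scan")

    report.landmarks = {n: sorted(d.values(), key=lambda l: l.name)
                        for n, d in landmarks.items()}
    report.warnings = warnings
    report.errors = errors
    report.status = "ok" if not warnings and not errors else "degraded"
    if out_dir:
        write_report(report, out_dir, stem, figure)
    return report


# ---------------------------------------------------------------------------
# Batch


def _find_cases(directory: Path) -> List[Tuple[str, Path, Path]]:
    cases = []
    for img in sorted(directory.glob("*_image.nii.gz")):
        stem = img.name[: -len("_image.nii.gz")]
        lab = directory / f"{stem}_labels.nii.gz"
        if lab.exists():
            cases.append((stem, img, lab))
    return cases


def _run_case(args) -> CaseResult:
    stem, img_path, lab_path, config_dict, out_dir, scan_type = args
    t0 = time.perf_counter()
    config = PipelineConfig.from_dict(config_dict)
    try:
        rep = analyze(img_path, lab_path, config, out_dir=out_dir,
                      scan_type=scan_type, stem=stem, figure=False)
        return CaseResult(stem, rep.status, rep.errors or rep.warnings[:3],
                          time.perf_counter() - t0,
                          str(Path(out_dir) / f"{stem}.json"))
    except Exception as exc:                      # one case never kills the batch
        return CaseResult(stem, "failed", [str(exc)], time.perf_counter() - t0)


def batch(directory: "str | Path", config: Optional[PipelineConfig] = None,
          out_dir: "str | Path" = "reports", n_workers: int = 1,
          scan_type: str = "auto") -> RunManifest:
    """Analyze every ``<case>_image.nii.gz`` / ``<case>_labels.nii.gz`` pair
    in a directory.  Cases are independent; with ``n_workers > 1`` they run
    in separate processes and reports are identical to a serial run."""
    directory = Path(directory)
    cases = _find_cases(directory)
    if not cases:
        raise ValueError(f"no cases found in {directory}")
    config = config or PipelineConfig()
    Path(out_dir).mkdir(parents=True, exist_ok=True)
    jobs = [(stem, str(i), str(l), config.to_dict(), str(out_dir), scan_type)
            for stem, i, l in cases]
    manifest = RunManifest()
    if n_workers <= 1:
        for job in jobs:
            manifest.cases.append(_run_case(job))
    else:
        with ProcessPoolExecutor(max_workers=n_workers) as pool:
            manifest.cases.extend(pool.map(_run_case, jobs))
    manifest.write(Path(out_dir) / "manifest.json")
    return manifest
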