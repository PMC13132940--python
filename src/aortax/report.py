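"""Report assembly: JSON document, CSV biomarker table, summary figure.

The JSON schema is stable and documented here; re-running the pipeline on
identical inputs with the same configuration produces byte-identical files
(no timestamps; floats rounded to 6 decimals).

Top-level keys:

``status``          ok | degraded | rejected
``classification``  scan class, component count, reasons, surface/volume ratio
``config``          full configuration snapshot used for the run
``software_version``
``landmarks``       name, arc_length_mm, x/y/z mm, centerline, provenance
``segments``        name, start_mm, end_mm, centerline, available, reason
``measurements``    name, segment, arc_length_mm, max_diameter_mm, csa_mm2,
                    aspect_ratio, qc_pass, centerline
``tortuosity``      name, centerline_length_mm, geometric_length_mm, index
``calcification``   ratio_percent, threshold_hu, mu_hu, sigma_hu, band_hu
``warnings`` / ``errors``
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .biomarkers import DiameterMeasurement, TortuosityResult
from .config import PipelineConfig
from .cpr import CSAProfile, StraightenedVolume
from .landmarks import Landmark, SegmentTable
from .lumen import LumenResult
from .qc import ScanClassification

__all__ = ["ReportDocument", "assemble_report", "write_report"]


def _round(obj, ndigits: int = 6):
    if isinstance(obj, dict):
        return {k: _round(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return round(v, ndigits) if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round(obj.tolist(), ndigits)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


@dataclass
class ReportDocument:
    status: str
    classification: ScanClassification
    config: PipelineConfig
    landmarks: Dict[str, List[Landmark]] = field(default_factory=dict)
    segments: List[SegmentTable] = field(default_factory=list)
    measurements: List[DiameterMeasurement] = field(default_factory=list)
    tortuosity: List[TortuosityResult] = field(default_factory=list)
    lumen: Optional[LumenResult] = None
    warnings: List[str] = field(default_factory=list)
    errors: List[str] = field(default_factory=list)
    #: per-centerline CSA profiles, for the summary figure
    profiles: Dict[str, CSAProfile] = field(default_factory=dict)
    straightened: Dict[str, StraightenedVolume] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        lm_rows = []
        for cname, lms in sorted(self.landmarks.items()):
            for lm in lms:
                lm_rows.append({
                    "name": lm.name, "centerline": cname,
                    "arc_length_mm": lm.arc_length_mm,
                    "x_mm": lm.world_mm[0], "y_mm": lm.world_mm[1],
                    "z_mm": lm.world_mm[2], "provenance": lm.provenance,
                })
        lm_rows.sort(key=lambda r: (r["centerline"], r["name"]))
        seg_rows = [{
            "name": s.name, "centerline": s.centerline_name,
            "start_mm": None if not np.isfinite(s.start_mm) else s.start_mm,
            "end_mm": None if not np.isfinite(s.end_mm) else s.end_mm,
            "available": s.available, "reason": s.reason,
        } for table in self.segments for s in table]
        meas_rows = [{
            "name": me.name, "segment": me.segment, "centerline": me.centerline_name,
            "arc_length_mm": me.arc_length_mm,
            "max_diameter_mm": me.max_diameter_mm, "csa_mm2": me.csa_mm2,
            "aspect_ratio": None if not np.isfinite(me.aspect_ratio) else me.aspect_ratio,
            "qc_pass": me.qc_pass,
        } for me in self.measurements]
        tort_rows = [{
            "name": t.name, "centerline_length_mm": t.centerline_length_mm,
            "geometric_length_mm": t.geometric_length_mm, "index": t.index,
        } for t in self.tortuosity]
        calc = None
        if self.lumen is not None:
            calc = {
                "ratio_percent": self.lumen.calcification_ratio,
                "threshold_hu": self.lumen.calc_threshold,
                "mu_hu": self.lumen.stats.mu_hu,
                "sigma_hu": self.lumen.stats.sigma_hu,
                "band_hu": list(self.lumen.band),
            }
        doc = {
            "status": self.status,
            "classification": {
                "scan_class": self.classification.scan_class,
                "component_count": self.classification.component_count,
                "reasons": list(self.classification.reasons),
                "surface_to_volume_per_mm": self.classification.surface_to_volume_per_mm,
            },
            "config": self.config.to_dict(),
            "software_version": __version__,
            "landmarks": lm_rows,
            "segments": seg_rows,
            "measurements": meas_rows,
            "tortuosity": tort_rows,
            "calcification": calc,
            "warnings": list(self.warnings),
            "errors": list(self.errors),
        }
        return _round(doc)

    def measurement_table(self) -> pd.DataFrame:
        """CSV twin: one row per measurement."""
        rows = [{
            "name": me.name, "segment": me.segment,
            "centerline": me.centerline_name,
            "arc_length_mm": round(me.arc_length_mm, 3),
            "value": round(me.max_diameter_mm, 3), "units": "mm",
            "csa_mm2": round(me.csa_mm2, 3),
            "flags": "" if me.qc_pass else "qc_fail",
        } for me in self.measurements]
        for t in self.tortuosity:
            rows.append({"name": f"tortuosity_{t.name}", "segment": t.name,
                         "centerline": "main",
                         "arc_length_mm": np.nan, "value": round(t.index, 4),
                         "units": "", "csa_mm2": np.nan, "flags": ""})
        if self.lumen is not None:
            rows.append({"name": "calcification_ratio", "segment": "",
                         "centerline": "main", "arc_length_mm": np.nan,
                         "value": round(self.lumen.calcification_ratio, 3),
                         "units": "%", "csa_mm2": np.nan, "flags": ""})
        return pd.DataFrame(rows)


def assemble_report(status, classification, config, **parts) -> ReportDocument:
    return ReportDocument(status=status, classification=classification,
                          config=config, **parts)


def write_report(report: ReportDocument, out_dir: "str | Path",
                 stem: str = "aorta", figure: bool = True) -> Path:
    """Write <stem>.json, <stem>.csv and (optionally) <stem>.png."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / f"{stem}.json"
    json_path.write_text(json.dumps(report.to_json_dict(), indent=2,
                                    sort_keys=True) + "\n")
    report.measurement_table().to_csv(out_dir / f"{stem}.csv", index=False)
    if figure and report.profiles:
        _summary_figure(report, out_dir / f"{stem}.png")
    return json_path


def _summary_figure(report: ReportDocument, path: Path) -> None:
    """CSA-vs-arc-length plot with measurement markers plus a montage of the
    straightened cross-sections at the measurement slices."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    meas = [m for m in report.measurements if m.qc_pass]
    n_tiles = max(len(meas), 1)
    fig = plt.figure(figsize=(10, 6))
    gs = fig.add_gridspec(2, n_tiles, height_ratios=[2, 1])
    ax = fig.add_subplot(gs[0, :])
    for cname, prof in sorted(report.profiles.items()):
        ax.plot(prof.arc_length_mm, prof.area_mm2, lw=1.2, label=cname)
    for m in meas:
        prof = report.profiles.get(m.centerline_name)
        if prof is None:
            continue
        ax.axvline(m.arc_length_mm, color="crimson", ls=":", lw=0.8)
        ax.annotate(m.name, (m.arc_length_mm, float(np.nanmax(prof.area_mm2))),
                    rotation=90, fontsize=7, va="top")
    ax.set_xlabel("arc length (mm)")
    ax.set_ylabel("cross-sectional area (mm$^2$)")
    ax.legend(fontsize=7)
    for i, m in enumerate(meas):
        sv = report.straightened.get(m.centerline_name)
        if sv is None:
            continue
        axm = fig.add_subplot(gs[1, i])
        idx = int(np.argmin(np.abs(sv.slice_arc_lengths - m.arc_length_mm)))
        axm.imshow(sv.hu_slices[idx].T, cmap="gray", vmin=-150, vmax=550,
                   origin="lower")
        axm.contour(sv.lumen_slices[idx].T, levels=[0.5], colors="r",
                    linewidths=0.6)
        axm.set_title(f"{m.name}\n{m.max_diameter_mm:.1f} mm", fontsize=7)
        axm.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
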