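"""Pipeline configuration.

All distances are in millimetres, all intensities in Hounsfield units (HU).
Defaults follow the published method where it states a value (calcification
weighting ``alpha`` = 3, minimum calcification threshold 400 HU, 1 mm skeleton
dilation, 5 mm artery dilation, 20 mm distal-arch offset, aortic-root search
windows of 20 / 5-25 / 10 mm); the remaining values are this package's own
documented choices (see ``docs/methods.md``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # --- lumen refinement -------------------------------------------------
    #: weighting factor of the adaptive calcification threshold
    #: max(min_hu, mu + alpha * sigma)
    alpha: float = 3.0
    #: minimum calcification threshold in HU
    min_hu: float = 400.0
    #: lumen HU band as multiples of sigma (below mu, above mu):
    #: voxels within [mu - band[0]*sigma, mu + band[1]*sigma] are lumen candidates
    lumen_band: Tuple[float, float] = (5.0, 3.0)
    #: dilation of the skeleton before HU sampling, mm
    skeleton_dilation_mm: float = 1.0
    #: radius (voxels) of the ball used for morphological opening/closing
    morphology_radius_vox: int = 1
    #: minimum sigma substituted when the sampled HU spread is ~0 (constant phantoms)
    sigma_floor_hu: float = 1.0

    # --- landmarks --------------------------------------------------------
    #: dilation applied to artery/organ masks and the lumen before overlap, mm
    artery_dilation_mm: float = 5.0
    #: arc-length offset from the left-subclavian projection to the distal arch, mm
    distal_arch_offset_mm: float = 20.0
    #: sinus of Valsalva searched within this many mm distal to the
    #: ventricular-aortic landmark
    sinus_window_mm: float = 20.0
    #: sinotubular junction searched within [lo, hi] mm beyond the sinus
    stj_window_mm: Tuple[float, float] = (5.0, 25.0)
    #: annulus searched within this many mm proximal to the ventricular-aortic
    #: landmark on the combined LV-aorta centerline
    annulus_window_mm: float = 10.0
    #: length of the centerline extension into the LV blood pool, mm
    lv_extension_mm: float = 30.0

    # --- centerline -------------------------------------------------------
    #: epsilon of the medial edge cost  step / (eps + distance-to-boundary)
    medial_eps_mm: float = 0.1
    #: smoothing-spline residual target (RMS, mm); None -> 0.35x voxel diagonal
    spline_residual_mm: Optional[float] = None
    #: arc-length resampling step of the centerline, mm
    centerline_step_mm: float = 1.0

    # --- curved planar reformatting ---------------------------------------
    cpr_slice_step_mm: float = 1.0
    cpr_inplane_res_mm: float = 0.5
    cpr_halfwidth_mm: float = 40.0

    # --- quality control --------------------------------------------------
    #: best-fit-ellipse aspect ratio above which a slice measurement is discarded
    aspect_ratio_threshold: float = 2.5
    #: lumen surface-to-volume ratio (1/mm) above which the scan is rejected
    surface_volume_threshold_per_mm: float = 0.4
    #: connected components smaller than this are ignored when classifying, mm^3
    min_component_volume_mm3: float = 1000.0

    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_hu", "skeleton_dilation_mm", "artery_dilation_mm",
            "distal_arch_offset_mm", "sinus_window_mm", "annulus_window_mm",
            "lv_extension_mm", "centerline_step_mm", "cpr_slice_step_mm",
            "cpr_inplane_res_mm", "cpr_halfwidth_mm",
        ):
            value = getattr(self, name)
            if not isinstance(value, (int, float)):
                raise TypeError(f"{name} must be numeric, got {value!r}")
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        lo, hi = self.stj_window_mm
        if not 0 <= lo < hi:
            raise ValueError(f"stj_window_mm must satisfy 0 <= lo < hi, got {lo, hi}")
        if min(self.lumen_band) < 0:
            raise ValueError("lumen_band multiples must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lumen_band"] = list(self.lumen_band)
        d["stj_window_mm"] = list(self.stj_window_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("lumen_band", "stj_window_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def load_config(path: "str | Path | None" = None, **overrides) -> PipelineConfig:
    """Load a configuration from a JSON/YAML file, falling back to defaults.

    Unspecified keys keep their default values; keyword overrides take
    precedence over the file.
    """
    data: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        text = path.read_text()
        if path.suffix == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text) or {}
    data.update(overrides)
    return PipelineConfig.from_dict(data)
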