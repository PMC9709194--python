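"""Pipeline configuration with YAML overrides.

Collects the tunables of the measurement path in one place: edge
detector parameters, plate-search radii, and the switch for the
machine-to-actual area correction (off by default — the shipped trait
models already regress on machine-recognised areas).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import yaml

from .errors import InvalidSpecError

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    # segmentation
    canny_sigma: float = 1.6
    closing_radius: int = 3
    min_region_px: int = 64
    # plate detection (radii as fractions of the short image side)
    plate_radius_min: float = 0.1
    plate_radius_max: float = 0.45
    plate_n_radii: int = 24
    plate_score_threshold: float = 0.25
    # area handling
    apply_area_correction: bool = False
    # capture defaults, overridable per call
    default_f35_mm: Optional[float] = None
    default_distance_cm: Optional[float] = None

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


def load_config(path: Optional[Path] = None) -> PipelineConfig:
    """Load a YAML config file; unknown keys are rejected to catch
    typos early.  No file means all defaults."""
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise InvalidSpecError(f"config {path} must be a YAML mapping")
    valid = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - valid
    if unknown:
        raise InvalidSpecError(f"unknown config keys in {path}: {sorted(unknown)}")
    return PipelineConfig(**data)
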