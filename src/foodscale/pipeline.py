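"""End-to-end estimation pipeline: classify, segment, measure, weigh.

The recognition step is a pluggable interface with a deterministic
stub (sidecar label files / explicit labels) standing in for any
external classifier service, so the whole pipeline runs offline and
reproducibly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Optional, Protocol

import pandas as pd

from .area_weight import LinearModel, TraitClass, correct_area, default_models, predict_weight
from .camera_geometry import CameraSpec, CaptureGeometry, camera_spec_from_image, read_exif_f35
from .config import PipelineConfig
from .errors import GeometryError, InvalidSpecError, ModelError, SegmentationError, StatsError
from .food_registry import trait_for_label
from .imaging_ops import FoodImage, RegionBox, load_image, segment_food
from .stats import ValidationReport, validate_pairs

__all__ = [
    "Classifier",
    "ClassifierResult",
    "EstimateReport",
    "sidecar_label_classifier",
    "classify",
    "estimate",
    "validate_estimates",
]


@dataclass(frozen=True)
class ClassifierResult:
    """A recognised food label with its confidence and looked-up trait.
    ``label`` is "unknown" when recognition fails; the trait must then
    come from the caller."""

    label: str
    confidence: float
    trait: Optional[TraitClass]


class Classifier(Protocol):
    def __call__(self, image_path: Path) -> tuple[str, float]:
        """Return (label, confidence in [0, 1]) for an image file."""


def sidecar_label_classifier(image_path: Path) -> tuple[str, float]:
    """Deterministic stub classifier: reads the label from a sidecar
    ``<image>.label.txt`` file, with confidence 1.0; "unknown" with
    confidence 0.0 when no sidecar exists."""
    sidecar = Path(str(image_path) + ".label.txt")
    if not sidecar.exists():
        sidecar = Path(image_path).with_suffix(".label.txt")
    if sidecar.exists():
        return sidecar.read_text().strip(), 1.0
    return "unknown", 0.0


def classify(
    image_path: Path,
    classifier: Optional[Classifier] = None,
    label: Optional[str] = None,
    trait: Optional[TraitClass] = None,
) -> ClassifierResult:
    """Resolve the food label and trait for an image.

    An explicit ``label`` bypasses the classifier; an explicit ``trait``
    overrides (or substitutes for) the vocabulary lookup.  An unknown
    label without an explicit trait is an error: the trait selects the
    weight model and cannot be guessed.
    """
    if label is not None:
        resolved, conf = label, 1.0
    else:
        clf = classifier or sidecar_label_classifier
        resolved, conf = clf(Path(image_path))
    looked_up = trait_for_label(resolved, strict=False) if resolved != "unknown" else None
    final_trait = trait if trait is not None else looked_up
    if final_trait is None:
        raise ModelError(
            f"cannot resolve a trait class for label {resolved!r}; pass one explicitly"
        )
    return ClassifierResult(label=resolved, confidence=conf, trait=TraitClass.parse(final_trait))


@dataclass
class EstimateReport:
    """Everything one estimation run produced, serialisable to JSON.
    ``area_cm2``/``weight_g`` are None when segmentation found nothing."""

    image: str
    label: str
    trait: str
    pixel_count: Optional[int]
    area_cm2: Optional[float]
    corrected_area_cm2: Optional[float]
    weight_g: Optional[float]
    clipped: bool
    f35_mm: float
    distance_cm: float
    width_px: int
    height_px: int
    model_id: Optional[str]

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def estimate(
    image_path: Path,
    distance_cm: Optional[float] = None,
    f35_mm: Optional[float] = None,
    label: Optional[str] = None,
    trait: Optional[TraitClass] = None,
    roi: Optional[RegionBox] = None,
    config: Optional[PipelineConfig] = None,
    classifier: Optional[Classifier] = None,
    models: Optional[dict[TraitClass, LinearModel]] = None,
) -> EstimateReport:
    """Run the full pipeline on one photograph.

    Geometry resolution order: explicit arguments, then EXIF
    (FocalLengthIn35mmFilm), then config defaults.  The object distance
    never lives in EXIF, so it must come from an argument or config.
    """
    cfg = config or PipelineConfig()
    image_path = Path(image_path)

    f35 = f35_mm if f35_mm is not None else (read_exif_f35(image_path) or cfg.default_f35_mm)
    if f35 is None:
        raise InvalidSpecError(
            f"{image_path}: no 35-mm-equivalent focal length (flag, EXIF or config)"
        )
    u = distance_cm if distance_cm is not None else cfg.default_distance_cm
    if u is None:
        raise GeometryError(f"{image_path}: object distance (cm) is required")

    camera = camera_spec_from_image(image_path, f35=f35)
    geometry = CaptureGeometry(object_distance=u)
    result = classify(image_path, classifier=classifier, label=label, trait=trait)

    image = load_image(image_path, camera=camera, geometry=geometry)
    region = segment_food(
        image,
        box=roi,
        canny_sigma=cfg.canny_sigma,
        closing_radius=cfg.closing_radius,
        min_region_px=cfg.min_region_px,
    )
    base = dict(
        image=str(image_path),
        label=result.label,
        trait=result.trait.value,
        f35_mm=float(f35),
        distance_cm=float(u),
        width_px=camera.width_px,
        height_px=camera.height_px,
    )
    if region is None:
        return EstimateReport(
            pixel_count=None, area_cm2=None, corrected_area_cm2=None,
            weight_g=None, clipped=False, model_id=None, **base,
        )

    from .camera_geometry import region_area

    est = region_area(region.pixel_count, camera, geometry)
    corrected = correct_area(est.area) if cfg.apply_area_correction else None
    area_for_model = corrected if corrected is not None else est.area
    w = predict_weight(area_for_model, result.trait, models=models)
    return EstimateReport(
        pixel_count=region.pixel_count,
        area_cm2=est.area,
        corrected_area_cm2=corrected,
        weight_g=w.weight,
        clipped=w.clipped,
        model_id=w.model_id,
        **base,
    )


def validate_estimates(estimates_csv: Path, measured_csv: Path) -> ValidationReport:
    """Join estimated and measured weights on image id and run the
    validation statistics on (estimated - measured)."""
    est = pd.read_csv(estimates_csv)
    mea = pd.read_csv(measured_csv)
    for df, name, col in ((est, "estimates", "weight_g"), (mea, "measured", "weight_g")):
        if "image" not in df.columns or col not in df.columns:
            raise StatsError(f"{name} CSV needs columns image,weight_g")
    joined = est.merge(mea, on="image", suffixes=("_est", "_meas"))
    if len(joined) < 3:
        raise StatsError(
            f"only {len(joined)} rows join on image id; need at least 3"
        )
    return validate_pairs(
        joined["weight_g_est"].to_numpy(), joined["weight_g_meas"].to_numpy()
    )
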