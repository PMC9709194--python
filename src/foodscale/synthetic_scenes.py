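"""Synthetic top-view plate scenes with exactly known ground truth.

The generator emulates the controlled capture protocol the shipped
calibration assumes: a phone held parallel to the table at a fixed
height (default 40.6 cm) with a fixed 35-mm-equivalent focal length
(default 46 mm), a white background, a round plate, and one food item.
Because the scene is specified in centimetres in the object plane and
mapped to pixels through the same camera geometry the estimator
inverts, every rendered image comes with its exact physical area, its
exact interior pixel count, and a trait-consistent weight — the ground
truth the closed-loop tests compare against.

What it does *not* emulate: food texture, specularity, shadows,
perspective of non-planar food, or lens distortion.  Passing
closed-loop tests therefore demonstrates that the geometry and
segmentation machinery is self-consistent, not that segmentation is
robust to photographic nuisance in real meals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .area_weight import CalibrationRecord, TraitClass, area_correction_model, default_models
from .camera_geometry import CameraSpec, CaptureGeometry, pixel_area_scale
from .errors import GeometryError
from .imaging_ops import FoodImage, RegionBox, count_pixels, save_image

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "default_scene_camera",
    "default_scene_geometry",
    "field_of_view_cm",
    "render",
    "random_scene",
    "random_convex_polygon",
    "generate_calibration_set",
    "noise_sd_for_target_r2",
    "default_noise_sd",
    "write_scene",
]

#: Capture protocol defaults: equivalent focal length 46 mm, shooting
#: height 40.6 cm, top view on a white background.
DEFAULT_F35_MM = 46.0
DEFAULT_DISTANCE_CM = 40.6

#: Calibration areas span 60-150 cm^2.  The shipped trait lines have
#: negative intercepts with zero crossings up to 28.2 cm^2, and the
#: residual noise implied by their R^2 is 12-19 g; starting at 60 cm^2
#: keeps every generated weight comfortably positive, so the
#: zero-truncation below is a guard that essentially never fires and
#: the generative model stays honestly linear.
DEFAULT_AREA_RANGE = (60.0, 150.0)


def default_scene_camera(width_px: int = 480, height_px: int = 640) -> CameraSpec:
    return CameraSpec(f35=DEFAULT_F35_MM, width_px=width_px, height_px=height_px, aspect="4:3")


def default_scene_geometry(u_cm: float = DEFAULT_DISTANCE_CM) -> CaptureGeometry:
    return CaptureGeometry(object_distance=u_cm)


def field_of_view_cm(camera: CameraSpec, geometry: CaptureGeometry) -> tuple[float, float]:
    """(short_cm, long_cm) extent of the object plane covered by the
    full image."""
    long_mm, short_mm = camera.frame_mm
    b = geometry.bracket(camera.f35)
    return (short_mm * b, long_mm * b)


@dataclass
class SceneSpec:
    """Full description of one synthetic scene.

    Plate centre/radius and food polygon vertices are in centimetres in
    the object plane, origin at the optical axis (image centre),
    axes parallel to image rows/columns.
    """

    camera: CameraSpec
    geometry: CaptureGeometry
    trait: TraitClass
    food_polygon_cm: np.ndarray  # (N, 2) cm, (row-axis, col-axis)
    plate_center_cm: tuple[float, float] = (0.0, 0.0)
    plate_radius_cm: float = 9.0
    background: float = 0.97
    plate: float = 0.88
    food: float = 0.25
    noise_sd: float = 0.02
    weight_noise_sd_g: float = 0.0
    seed: int = 0
    contrast_margin: float = 0.2

    def __post_init__(self) -> None:
        self.trait = TraitClass.parse(self.trait)
        poly = np.asarray(self.food_polygon_cm, dtype=float)
        if poly.size and (poly.ndim != 2 or poly.shape[1] != 2):
            raise GeometryError("food polygon must be (N, 2) cm coordinates")
        self.food_polygon_cm = poly
        if abs(self.food - self.background) < self.contrast_margin:
            raise GeometryError("food/background intensities closer than the contrast margin")
        if poly.size:
            short_cm, long_cm = field_of_view_cm(self.camera, self.geometry)
            if (np.abs(poly[:, 0]) > short_cm / 2).any() or (np.abs(poly[:, 1]) > long_cm / 2).any():
                raise GeometryError("food polygon extends outside the camera field of view")


@dataclass
class GroundTruth:
    """Exact generative quantities of a rendered scene, all computed
    before pixel noise is added."""

    area_cm2: float
    pixel_count: int
    weight_g: float
    weight_noise_g: float
    trait: TraitClass
    pixel_polygon: np.ndarray  # food boundary in continuous pixel coords
    food_box: RegionBox  # padded bounding box of the food, for segmentation
    scale_cm2_per_px: float

    def to_dict(self) -> dict:
        return {
            "area_cm2": self.area_cm2,
            "pixel_count": int(self.pixel_count),
            "weight_g": self.weight_g,
            "weight_noise_g": self.weight_noise_g,
            "trait": self.trait.value,
            "food_box": [
                self.food_box.row_start,
                self.food_box.col_start,
                self.food_box.row_stop,
                self.food_box.col_stop,
            ],
            "scale_cm2_per_px": self.scale_cm2_per_px,
        }


def _cm_to_px(points_cm: np.ndarray, camera: CameraSpec, geometry: CaptureGeometry) -> np.ndarray:
    """Map object-plane cm coordinates (origin on the optical axis) to
    continuous pixel coordinates, using the canonical short-side scale
    isotropically (the declared aspect guarantees the long-side scale
    agrees within 1%)."""
    scale = np.sqrt(pixel_area_scale(camera, geometry))  # cm per pixel
    h, w = camera.height_px, camera.width_px
    # rows run along the long image side when the image is portrait
    # (h >= w); the scene's first axis maps to rows, second to columns.
    center = np.array([h / 2.0, w / 2.0])
    return points_cm / scale + center


def render(scene: SceneSpec) -> tuple[FoodImage, GroundTruth]:
    """Rasterise a scene and return the image plus its exact ground truth.

    The image is portrait ``height_px x width_px`` grayscale.  The plate
    disk is drawn first, the food polygon on top, then seeded Gaussian
    pixel noise.  Ground truth (physical shoelace area, interior pixel
    count of the mapped polygon, trait-model weight plus a recorded
    noise draw) is computed before noise.
    """
    cam, geom = scene.camera, scene.geometry
    h, w = cam.height_px, cam.width_px
    img = np.full((h, w), scene.background, dtype=float)

    rng = np.random.default_rng(scene.seed)

    # plate disk
    pc = _cm_to_px(np.array([scene.plate_center_cm]), cam, geom)[0]
    scale = np.sqrt(pixel_area_scale(cam, geom))
    rr, cc = np.mgrid[0:h, 0:w]
    plate_r_px = scene.plate_radius_cm / scale
    plate_mask = (rr + 0.5 - pc[0]) ** 2 + (cc + 0.5 - pc[1]) ** 2 <= plate_r_px**2
    img[plate_mask] = scene.plate

    poly_cm = scene.food_polygon_cm
    if poly_cm.size == 0 or _ShapelyPolygon(poly_cm).area == 0:
        # degenerate food: nothing to draw
        gt = GroundTruth(
            area_cm2=0.0,
            pixel_count=0,
            weight_g=0.0,
            weight_noise_g=0.0,
            trait=scene.trait,
            pixel_polygon=np.empty((0, 2)),
            food_box=RegionBox(0, 0, h, w),
            scale_cm2_per_px=scale**2,
        )
    else:
        poly_px = _cm_to_px(poly_cm, cam, geom)
        n_true = count_pixels(poly_px)
        area_cm2 = float(_ShapelyPolygon(poly_cm).area)
        mask = _rasterize(poly_px, h, w)
        img[mask] = scene.food
        noise_draw = float(rng.normal(0.0, scene.weight_noise_sd_g)) if scene.weight_noise_sd_g > 0 else 0.0
        weight = max(0.0, default_models()[scene.trait].predict(area_cm2) + noise_draw)
        pad = 12
        box = RegionBox(
            max(0, int(np.floor(poly_px[:, 0].min())) - pad),
            max(0, int(np.floor(poly_px[:, 1].min())) - pad),
            min(h, int(np.ceil(poly_px[:, 0].max())) + pad),
            min(w, int(np.ceil(poly_px[:, 1].max())) + pad),
        )
        gt = GroundTruth(
            area_cm2=area_cm2,
            pixel_count=n_true,
            weight_g=weight,
            weight_noise_g=noise_draw,
            trait=scene.trait,
            pixel_polygon=poly_px,
            food_box=box,
            scale_cm2_per_px=scale**2,
        )

    if scene.noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, scene.noise_sd, size=img.shape), 0.0, 1.0)

    return FoodImage(img, camera=cam, geometry=geom), gt


def _rasterize(poly_px: np.ndarray, h: int, w: int) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside the polygon —
    the same inclusion rule ``count_pixels`` uses."""
    from .imaging_ops import points_in_polygon

    r_lo = max(0, int(np.floor(poly_px[:, 0].min())))
    r_hi = min(h, int(np.ceil(poly_px[:, 0].max())))
    c_lo = max(0, int(np.floor(poly_px[:, 1].min())))
    c_hi = min(w, int(np.ceil(poly_px[:, 1].max())))
    mask = np.zeros((h, w), dtype=bool)
    if r_hi <= r_lo or c_hi <= c_lo:
        return mask
    rr, cc = np.meshgrid(np.arange(r_lo, r_hi) + 0.5, np.arange(c_lo, c_hi) + 0.5, indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()])
    inside = points_in_polygon(pts, poly_px).reshape(r_hi - r_lo, c_hi - c_lo)
    mask[r_lo:r_hi, c_lo:c_hi] = inside
    return mask


def random_convex_polygon(
    rng: np.random.Generator,
    area_cm2: float,
    n_vertices: int = 14,
    irregularity: float = 0.35,
) -> np.ndarray:
    """A random convex polygon scaled to the requested area (cm^2),
    centred at the origin."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = 1.0 + irregularity * rng.uniform(-1, 1, n_vertices)
    pts = np.column_stack([radii * np.sin(angles), radii * np.cos(angles)])
    hull = _ShapelyPolygon(pts).convex_hull
    coords = np.asarray(hull.exterior.coords)[:-1]
    current = _ShapelyPolygon(coords).area
    coords *= np.sqrt(area_cm2 / current)
    return coords - coords.mean(axis=0)


def random_scene(
    seed: int,
    trait: Optional[TraitClass] = None,
    area_range_cm2: tuple[float, float] = (30.0, 100.0),
    camera: Optional[CameraSpec] = None,
    geometry: Optional[CaptureGeometry] = None,
    noise_sd: float = 0.02,
) -> SceneSpec:
    """A reproducible random scene: convex food blob of uniform-random
    area, slightly off-centre on a 9-cm-radius plate."""
    rng = np.random.default_rng(seed)
    camera = camera or default_scene_camera()
    geometry = geometry or default_scene_geometry()
    if trait is None:
        trait = list(TraitClass)[int(rng.integers(0, 3))]
    area = float(rng.uniform(*area_range_cm2))
    poly = random_convex_polygon(rng, area)
    offset = rng.uniform(-1.5, 1.5, size=2)
    return SceneSpec(
        camera=camera,
        geometry=geometry,
        trait=trait,
        food_polygon_cm=poly + offset,
        plate_center_cm=(0.0, 0.0),
        plate_radius_cm=9.0,
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Calibration-set generation


def noise_sd_for_target_r2(slope: float, r_squared: float, area_range: tuple[float, float]) -> float:
    """Residual SD (g) that makes a linear model over uniformly drawn
    areas produce the requested R^2 in expectation.

    With areas ~ U(lo, hi), the signal variance is slope^2 (hi-lo)^2/12
    and R^2 = signal / (signal + sd^2).
    """
    if not 0 < r_squared < 1:
        raise ValueError("target R^2 must be in (0, 1)")
    lo, hi = area_range
    signal_sd = abs(slope) * (hi - lo) / np.sqrt(12.0)
    return float(signal_sd * np.sqrt(1.0 / r_squared - 1.0))


def default_noise_sd(trait: TraitClass, area_range: tuple[float, float] = DEFAULT_AREA_RANGE) -> float:
    """Per-trait residual SD reproducing the shipped models' R^2 over
    the default calibration area range."""
    m = default_models()[TraitClass.parse(trait)]
    return noise_sd_for_target_r2(m.slope, m.r_squared, area_range)


def generate_calibration_set(
    n_per_trait: int = 204,
    noise_sd_g: Optional[float] = None,
    seed: int = 0,
    area_range: tuple[float, float] = DEFAULT_AREA_RANGE,
) -> list[CalibrationRecord]:
    """Simulate a trait-stratified calibration table.

    For each of the three traits, ``n_per_trait`` machine-recognised
    areas are drawn uniformly over ``area_range`` and weights generated
    from the shipped trait model plus N(0, sd) noise, truncated at zero.
    ``noise_sd_g=None`` uses the per-trait SD that reproduces each
    shipped model's R^2; pass 0 for noiseless records.  The paired
    actual area is the deterministic inverse of the shipped
    machine-vs-actual correction line, mirroring the systematic
    under-recognition of large dishes.
    """
    if n_per_trait < 3:
        raise ValueError("need n_per_trait >= 3")
    rng = np.random.default_rng(seed)
    corr = area_correction_model()
    models = default_models()
    records: list[CalibrationRecord] = []
    for trait in TraitClass:
        sd = default_noise_sd(trait, area_range) if noise_sd_g is None else float(noise_sd_g)
        areas = rng.uniform(*area_range, size=n_per_trait)
        noise = rng.normal(0.0, sd, size=n_per_trait) if sd > 0 else np.zeros(n_per_trait)
        for i, (a, e) in enumerate(zip(areas, noise)):
            w = max(1e-9, models[trait].predict(a) + e)
            records.append(
                CalibrationRecord(
                    food=f"synthetic-{trait.name.lower()}-{i}",
                    trait=trait,
                    machine_area=float(a),
                    actual_area=max(1e-9, (float(a) - corr.intercept) / corr.slope),
                    measured_weight=float(w),
                )
            )
    return records


def write_scene(scene: SceneSpec, truth: GroundTruth, image: FoodImage, stem: Path) -> tuple[Path, Path]:
    """Write a rendered scene as PNG plus a sidecar ground-truth JSON."""
    stem = Path(stem)
    png = stem.with_suffix(".png")
    meta = stem.with_suffix(".truth.json")
    save_image(image, png)
    payload = truth.to_dict()
    payload["capture"] = {
        "f35_mm": scene.camera.f35,
        "distance_cm": scene.geometry.object_distance,
        "width_px": scene.camera.width_px,
        "height_px": scene.camera.height_px,
        "aspect": scene.camera.aspect,
        "seed": scene.seed,
    }
    meta.write_text(json.dumps(payload, indent=2))
    return png, meta
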