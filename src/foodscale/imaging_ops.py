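"""Image preprocessing, augmentation and food-region localisation.

The measurement path is deliberately classical: a plate is found with a
circular Hough transform, and the food region is delineated by edge
detection inside a region-of-interest box, closed morphologically,
filled, and traced into a boundary polygon whose interior pixels are
counted.  Subject detection (choosing the box) is *not* done here: the
box is supplied by the caller, defaults to the whole image, or comes
from a pluggable detector — training one is out of scope.

Coordinate conventions, fixed once and used everywhere:

* coordinates are 0-based ``(row, col)``; boxes are half-open;
* polygon vertices live in continuous image coordinates in which pixel
  ``(i, j)`` occupies the unit square ``[i, i+1) x [j, j+1)`` and has
  its centre at ``(i + 0.5, j + 0.5)``;
* a pixel belongs to a region iff its *centre* lies strictly inside the
  boundary polygon under the even-odd rule; boundary pixels are
  excluded.  This rule is unambiguous and checkable against a
  brute-force point-in-polygon oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage import color, feature, measure, morphology, transform, util

from .camera_geometry import CameraSpec, CaptureGeometry
from .errors import SegmentationError

__all__ = [
    "FoodImage",
    "RegionBox",
    "FoodRegion",
    "PlateCircle",
    "preprocess",
    "augment",
    "augment_set",
    "detect_plate",
    "segment_food",
    "count_pixels",
    "points_in_polygon",
    "polygon_area",
    "load_image",
    "save_image",
]

AugmentMode = Literal["contrast_brightness", "noise", "rotate90"]

CLASSIFIER_INPUT_SIZE = 224  # square side fed to the recognition model


@dataclass
class FoodImage:
    """A photograph (grayscale or RGB float array in [0, 1]) with
    optional capture metadata.

    The native-resolution pixels are what area measurement uses; the
    224 x 224 preprocessing exists only for the classifier path.
    """

    data: np.ndarray
    camera: Optional[CameraSpec] = None
    geometry: Optional[CaptureGeometry] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.size == 0 or arr.ndim not in (2, 3):
            raise SegmentationError("image must be a non-empty 2-D or 3-D array")
        self.data = util.img_as_float(arr)
        if self.camera is not None:
            dims = sorted(self.data.shape[:2])
            declared = sorted((self.camera.width_px, self.camera.height_px))
            if dims != declared:
                raise SegmentationError(
                    f"camera spec {declared} does not match pixel dimensions {dims}"
                )

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    def gray(self) -> np.ndarray:
        if self.data.ndim == 3:
            return color.rgb2gray(self.data)
        return self.data


@dataclass(frozen=True)
class RegionBox:
    """Axis-aligned rectangle, 0-based, half-open: rows in
    ``[row_start, row_stop)``, cols in ``[col_start, col_stop)``."""

    row_start: int
    col_start: int
    row_stop: int
    col_stop: int

    def __post_init__(self) -> None:
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise SegmentationError(f"empty region box {self}")
        if self.row_start < 0 or self.col_start < 0:
            raise SegmentationError(f"region box {self} has negative bounds")

    @classmethod
    def full(cls, image: FoodImage) -> "RegionBox":
        return cls(0, 0, image.height, image.width)

    def clipped_to(self, image: FoodImage) -> "RegionBox":
        if self.row_stop > image.height or self.col_stop > image.width:
            raise SegmentationError(
                f"region box {self} exceeds image bounds {image.height}x{image.width}"
            )
        return self

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_stop - self.row_start, self.col_stop - self.col_start)

    @property
    def n_pixels(self) -> int:
        return self.shape[0] * self.shape[1]

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row_start, self.row_stop), slice(self.col_start, self.col_stop))


@dataclass
class FoodRegion:
    """A segmented food boundary: ordered polygon vertices in continuous
    ``(row, col)`` image coordinates, the interior pixel count, and the
    enclosing box the segmentation ran in."""

    polygon: np.ndarray  # (N, 2) float, (row, col)
    pixel_count: int
    box: RegionBox

    def __post_init__(self) -> None:
        poly = np.asarray(self.polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
            raise SegmentationError("boundary polygon needs at least 3 (row, col) vertices")
        self.polygon = poly
        if not _ShapelyPolygon(poly).is_simple:
            raise SegmentationError("boundary polygon is self-intersecting")
        if self.pixel_count > self.box.n_pixels:
            raise SegmentationError("pixel count exceeds the enclosing box area")

    def to_geojson(self) -> dict:
        """GeoJSON-like export: polygon ring as [row, col] pairs."""
        ring = self.polygon.tolist()
        if ring[0] != ring[-1]:
            ring.append(ring[0])
        return {
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": {
                "pixel_count": int(self.pixel_count),
                "box": [self.box.row_start, self.box.col_start, self.box.row_stop, self.box.col_stop],
            },
        }


@dataclass(frozen=True)
class PlateCircle:
    """Detected tableware circle (pixel coordinates).  Reported for the
    tableware's projected area only — physical scale always comes from
    capture geometry, never from the plate size."""

    center: tuple[float, float]  # (row, col)
    radius: float
    score: float = float("nan")

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise SegmentationError(f"plate radius must be positive, got {self.radius}")


# ---------------------------------------------------------------------------
# Preprocessing / augmentation (classifier path only)


def preprocess(image: FoodImage, size: int = CLASSIFIER_INPUT_SIZE) -> FoodImage:
    """Centre-crop to a 1:1 square and rescale to ``size`` x ``size``.

    This feeds the recognition model; it must never be used before area
    measurement, which runs on native-resolution pixels.
    """
    arr = image.data
    h, w = arr.shape[:2]
    side = min(h, w)
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    crop = arr[r0 : r0 + side, c0 : c0 + side]
    out_shape = (size, size) + crop.shape[2:]
    resized = transform.resize(crop, out_shape, anti_aliasing=side > size, preserve_range=True)
    return FoodImage(np.clip(resized, 0.0, 1.0))


def augment(image: FoodImage, mode: AugmentMode, seed: int = 0) -> FoodImage:
    """One deterministic augmentation: contrast/brightness boost, seeded
    Gaussian noise, or a lossless 90-degree rotation."""
    rng = np.random.default_rng(seed)
    arr = image.data
    if mode == "contrast_brightness":
        alpha = rng.uniform(1.1, 1.3)  # contrast gain about the mean
        beta = rng.uniform(0.05, 0.15)  # brightness offset
        mean = arr.mean()
        out = np.clip(alpha * (arr - mean) + mean + beta, 0.0, 1.0)
    elif mode == "noise":
        out = np.clip(arr + rng.normal(0.0, 0.02, size=arr.shape), 0.0, 1.0)
    elif mode == "rotate90":
        out = np.rot90(arr, axes=(0, 1)).copy()
    else:
        raise ValueError(f"unknown augmentation mode {mode!r}")
    return FoodImage(out)


def augment_set(images: Sequence[FoodImage], seed: int = 0) -> list[FoodImage]:
    """Expand a training set three-fold: every image under all three
    augmentation modes, deterministically seeded per image."""
    out: list[FoodImage] = []
    for i, im in enumerate(images):
        for j, mode in enumerate(("contrast_brightness", "noise", "rotate90")):
            out.append(augment(im, mode, seed=seed * 1_000 + i * 3 + j))
    return out


# ---------------------------------------------------------------------------
# Plate detection


def detect_plate(
    image: FoodImage,
    radius_range: tuple[float, float] = (0.1, 0.45),
    n_radii: int = 24,
    score_threshold: float = 0.25,
    canny_sigma: float = 2.0,
    canny_low: float = 0.01,
    canny_high: float = 0.03,
) -> Optional[PlateCircle]:
    """Locate the tableware circle with a circular Hough transform.

    ``radius_range`` is in fractions of the shorter image side.
    Candidates are ranked by total accumulator support (normalised peak
    score times radius, i.e. edge votes along the whole circumference),
    which favours the dominant plate over small round food items.
    Returns ``None`` when no circle clears ``score_threshold``.
    """
    gray = image.gray()
    # low absolute hysteresis thresholds: a plate rim on a white table
    # is a weak step, far below the default edge thresholds
    edges = feature.canny(gray, sigma=canny_sigma, low_threshold=canny_low, high_threshold=canny_high)
    if not edges.any():
        return None
    short = min(gray.shape)
    r_min = max(3, int(radius_range[0] * short))
    r_max = max(r_min + 1, int(radius_range[1] * short))
    coarse = np.unique(np.linspace(r_min, r_max, n_radii).astype(int))

    def _peaks(radii: np.ndarray):
        accum = transform.hough_circle(edges, radii)  # circumference-normalised
        scores, cols, rows, rads = transform.hough_circle_peaks(
            accum, radii, total_num_peaks=8
        )
        return (
            np.asarray(scores, dtype=float),
            np.asarray(rows, dtype=float),
            np.asarray(cols, dtype=float),
            np.asarray(rads, dtype=float),
        )

    scores, rows, cols, rads = _peaks(coarse)
    if len(scores) == 0:
        return None
    # rank by total edge support (score x circumference): the plate's
    # long rim beats smaller, equally crisp circles
    idx = int(np.argmax(scores * rads))
    # refine the winning radius at 1-px resolution
    r0 = int(rads[idx])
    fine = np.arange(max(3, r0 - 6), r0 + 7)
    scores, rows, cols, rads = _peaks(fine)
    if len(scores) == 0:
        return None
    idx = int(np.argmax(scores * rads))
    if scores[idx] < score_threshold:
        return None
    return PlateCircle(
        center=(rows[idx] + 0.5, cols[idx] + 0.5),
        radius=float(rads[idx]),
        score=float(scores[idx]),
    )


# ---------------------------------------------------------------------------
# Food segmentation


def segment_food(
    image: FoodImage,
    box: Optional[RegionBox] = None,
    canny_sigma: float = 1.6,
    closing_radius: int = 3,
    min_region_px: int = 64,
) -> Optional[FoodRegion]:
    """Delineate the food inside ``box`` and count its interior pixels.

    Pipeline: Canny edge detection on the grayscale crop, morphological
    closing to seal small gaps in the boundary, hole filling, largest
    connected component, sub-pixel boundary tracing.  The returned
    pixel count is computed from the boundary polygon with the
    even-odd centre-inclusion rule (:func:`count_pixels`), so the
    polygon and the count are consistent by construction.

    Returns ``None`` when no closed contour encloses at least
    ``min_region_px`` pixels (a legitimate not-found, not an error).
    """
    box = (box or RegionBox.full(image)).clipped_to(image)
    crop = image.gray()[box.slices()]
    edges = feature.canny(crop, sigma=canny_sigma)
    if not edges.any():
        return None
    closed = morphology.closing(edges, morphology.disk(closing_radius))
    filled = ndi.binary_fill_holes(closed)
    # strip the 1-px edge band the closing added outside the true boundary
    filled = morphology.erosion(filled, morphology.disk(1))
    labels, n_lab = ndi.label(filled)
    if n_lab == 0:
        return None
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_lab + 1))
    biggest = int(np.argmax(sizes)) + 1
    if sizes[biggest - 1] < min_region_px:
        return None
    mask = labels == biggest
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)
    # find_contours uses pixel-centre coordinates; shift to the
    # continuous frame where centres sit at half-integers, then offset
    # into full-image coordinates.
    poly = contour + 0.5 + np.array([box.row_start, box.col_start], dtype=float)
    poly = _decimate_ring(poly)
    if poly.shape[0] < 3:
        return None
    n = count_pixels(poly)
    if n < min_region_px:
        return None
    return FoodRegion(polygon=poly, pixel_count=n, box=box)


def _decimate_ring(poly: np.ndarray, max_vertices: int = 4000) -> np.ndarray:
    """Drop a closing duplicate vertex and subsample very long rings so
    downstream polygon work stays cheap."""
    if poly.shape[0] > 1 and np.allclose(poly[0], poly[-1]):
        poly = poly[:-1]
    if poly.shape[0] > max_vertices:
        step = int(np.ceil(poly.shape[0] / max_vertices))
        poly = poly[::step]
    return poly


# ---------------------------------------------------------------------------
# Pixel counting


def points_in_polygon(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Vectorised even-odd (ray casting) point-in-polygon test.

    A point is inside iff a horizontal ray to +infinity crosses the
    boundary an odd number of times; points on horizontal edges are
    excluded by the strict/non-strict comparison pairing.
    """
    pts = np.asarray(points, dtype=float)
    poly = np.asarray(polygon, dtype=float)
    py, px = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    y1, x1 = poly[:, 0], poly[:, 1]
    y2, x2 = np.roll(y1, -1), np.roll(x1, -1)
    for i in range(len(poly)):
        a_y, a_x, b_y, b_x = y1[i], x1[i], y2[i], x2[i]
        crosses = (a_y > py) != (b_y > py)
        if not crosses.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = a_x + (py - a_y) * (b_x - a_x) / (b_y - a_y)
        inside ^= crosses & (px < x_at)
    return inside


def count_pixels(polygon: np.ndarray) -> int:
    """Number of pixels whose centres lie strictly inside ``polygon``
    (even-odd rule; boundary pixels excluded).

    Vertices are in continuous coordinates where pixel ``(i, j)`` has
    its centre at ``(i + 0.5, j + 0.5)``; e.g. the axis-aligned square
    (0,0)-(10,10) contains exactly the 100 pixel centres 0.5..9.5.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise SegmentationError("polygon needs at least 3 (row, col) vertices")
    r_lo = int(np.floor(poly[:, 0].min()))
    r_hi = int(np.ceil(poly[:, 0].max()))
    c_lo = int(np.floor(poly[:, 1].min()))
    c_hi = int(np.ceil(poly[:, 1].max()))
    if r_hi <= r_lo or c_hi <= c_lo:
        return 0
    rr, cc = np.meshgrid(
        np.arange(r_lo, r_hi) + 0.5, np.arange(c_lo, c_hi) + 0.5, indexing="ij"
    )
    centers = np.column_stack([rr.ravel(), cc.ravel()])
    return int(points_in_polygon(centers, poly).sum())


def polygon_area(polygon: np.ndarray) -> float:
    """Shoelace area of a polygon (continuous units squared)."""
    return float(_ShapelyPolygon(np.asarray(polygon, dtype=float)).area)


# ---------------------------------------------------------------------------
# File I/O


def load_image(path, camera: Optional[CameraSpec] = None, geometry: Optional[CaptureGeometry] = None) -> FoodImage:
    """Read a PNG/JPEG into a float image, attaching optional metadata."""
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return FoodImage(arr, camera=camera, geometry=geometry)


def save_image(image: FoodImage, path) -> None:
    """Write a float image to PNG/JPEG as 8-bit."""
    from PIL import Image

    arr = np.clip(image.data, 0.0, 1.0)
    Image.fromarray((arr * 255).round().astype(np.uint8)).save(path)
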