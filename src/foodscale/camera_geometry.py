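"""Pixel-to-physical geometry for top-view food photographs.

Everything in this module rests on two ideas:

1. **35-mm-equivalent focal length.** Phone sensors differ in size, so
   the true focal length says nothing about field of view.  The
   35-mm-equivalent focal length ``f35`` is the focal length a
   full-frame (36 x 24 mm) camera would need for the same field of
   view; it lets the pixel-to-length arithmetic ignore the physical
   sensor entirely.  A photo with aspect ratio 4:3 behaves as if it
   were formed on an *equivalent frame* with the full-frame diagonal
   (43.3 mm) and 4:3 sides, i.e. 34.6 x 26.0 mm; a 3:2 photo uses the
   full frame itself, 36.0 x 24.0 mm.

2. **Thin-lens magnification.** With object distance ``u``, image
   distance ``v`` and focal length ``f`` related by ``1/v + 1/u = 1/f``,
   the magnification is ``v/u = f/(u - f)``, so a length ``L`` on the
   (equivalent) image frame corresponds to a real-world length
   ``L * (u - f)/f`` in the object plane.

Units convention (deliberate and load-bearing): **object distance u is
in centimetres, focal lengths are in millimetres, real-world lengths
come out in centimetres and areas in square centimetres.**  Writing the
thin-lens result with everything in millimetres gives
``A_mm = 26.0 * (x/a) * (u_mm/f - 1)`` for the short image side;
substituting ``u_mm = 10 * u_cm`` and dividing by ten to convert the
answer to centimetres turns the ``- 1`` into the ``- 0.1`` that appears
throughout this module:

    A_cm = 26.0 * (x/a) * (u_cm / f35 - 0.1)

No other unit pairing reproduces the thin-lens prediction, which is why
the mixed convention is kept rather than normalised away (the
``thin_lens_object_length`` oracle asserts the identity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .errors import GeometryError, InvalidSpecError

__all__ = [
    "FULL_FRAME_WIDTH_MM",
    "FULL_FRAME_HEIGHT_MM",
    "FULL_FRAME_DIAGONAL_MM",
    "EQUIV_FRAME_MM",
    "Aspect",
    "CameraSpec",
    "SensorSpec",
    "CaptureGeometry",
    "AreaEstimate",
    "derived_equivalent_frame",
    "derived_conversion_constants",
    "equivalent_focal_length",
    "ground_sample_length",
    "pixel_area_scale",
    "region_area",
    "thin_lens_object_length",
    "read_exif_f35",
    "camera_spec_from_image",
]

Aspect = Literal["4:3", "3:2"]

FULL_FRAME_WIDTH_MM = 36.0
FULL_FRAME_HEIGHT_MM = 24.0
FULL_FRAME_DIAGONAL_MM = math.hypot(FULL_FRAME_WIDTH_MM, FULL_FRAME_HEIGHT_MM)

#: Working equivalent-frame side lengths (long_mm, short_mm) per aspect,
#: rounded to the three significant figures conventional in the field.
#: ``derived_equivalent_frame`` recomputes them from first principles.
EQUIV_FRAME_MM: dict[str, tuple[float, float]] = {
    "4:3": (34.6, 26.0),
    "3:2": (36.0, 24.0),
}

_ASPECT_RATIO = {"4:3": 4.0 / 3.0, "3:2": 3.0 / 2.0}


def derived_equivalent_frame(aspect: Aspect) -> tuple[float, float]:
    """Equivalent-frame side lengths (long_mm, short_mm) derived from
    full-frame geometry: the frame shares the 43.27 mm full-frame
    diagonal and has the declared aspect ratio.

    For 3:2 this is the full frame itself (36 x 24 mm) exactly; for 4:3
    it is 34.61 x 25.96 mm, conventionally rounded to 34.6 x 26.0.
    """
    r = _ASPECT_RATIO[_norm_aspect(aspect)]
    short = FULL_FRAME_DIAGONAL_MM / math.hypot(r, 1.0)
    return (r * short, short)


def derived_conversion_constants() -> dict[str, float]:
    """The focal-length / frame conversion constants derived from the
    36 x 24 mm full frame: long and short equivalent sides for 4:3 and
    3:2, plus the diagonal constant (aspect-independent)."""
    l43, s43 = derived_equivalent_frame("4:3")
    l32, s32 = derived_equivalent_frame("3:2")
    return {
        "4:3_width": l43,
        "4:3_height": s43,
        "3:2_width": l32,
        "3:2_height": s32,
        "diagonal": FULL_FRAME_DIAGONAL_MM,
    }


def _norm_aspect(aspect: str) -> str:
    a = aspect.strip()
    if a in ("4:3", "3:4"):
        return "4:3"
    if a in ("3:2", "2:3"):
        return "3:2"
    raise InvalidSpecError(f"unsupported aspect ratio {aspect!r}; expected 4:3 or 3:2")


@dataclass(frozen=True)
class CameraSpec:
    """Field-of-view description of a capture: the 35-mm-equivalent
    focal length plus full-image pixel counts.

    ``width_px`` counts pixels along the physically *shorter* equivalent
    side (26.0 mm for 4:3), ``height_px`` along the longer side
    (34.6 mm).  Landscape/portrait orientation is normalised on
    construction so the pairing is unambiguous.
    """

    f35: float
    width_px: int
    height_px: int
    aspect: Aspect = "4:3"

    def __post_init__(self) -> None:
        if not (self.f35 > 0):
            raise InvalidSpecError(f"f35 must be positive, got {self.f35}")
        w, h = int(self.width_px), int(self.height_px)
        if w <= 0 or h <= 0:
            raise InvalidSpecError("pixel dimensions must be positive integers")
        if w > h:  # orientation normalisation: short side first
            w, h = h, w
        object.__setattr__(self, "width_px", w)
        object.__setattr__(self, "height_px", h)
        object.__setattr__(self, "aspect", _norm_aspect(self.aspect))
        declared = _ASPECT_RATIO[self.aspect]
        actual = h / w
        if abs(actual - declared) / declared > 0.01:
            raise InvalidSpecError(
                f"declared aspect {self.aspect} inconsistent with "
                f"{w}x{h} pixels (ratio {actual:.4f}) beyond 1%"
            )

    @property
    def frame_mm(self) -> tuple[float, float]:
        """(long_mm, short_mm) of the equivalent frame for this aspect."""
        return EQUIV_FRAME_MM[self.aspect]


@dataclass(frozen=True)
class SensorSpec:
    """Physical sensor description, used only to derive ``f35`` when the
    capture metadata does not carry it directly."""

    f: float  # true focal length, mm
    w: Optional[float] = None  # sensor width (long side), mm
    d: Optional[float] = None  # sensor diagonal, mm
    aspect: Aspect = "4:3"

    def __post_init__(self) -> None:
        if not (self.f > 0):
            raise InvalidSpecError(f"true focal length must be positive, got {self.f}")
        if self.w is None and self.d is None:
            raise InvalidSpecError("SensorSpec needs at least one of sensor width w or diagonal d")
        object.__setattr__(self, "aspect", _norm_aspect(self.aspect))
        if self.w is not None and self.d is not None:
            r = _ASPECT_RATIO[self.aspect]
            implied_d = self.w * math.hypot(r, 1.0) / r
            if abs(implied_d - self.d) / self.d > 0.01:
                raise InvalidSpecError(
                    f"sensor width {self.w} mm and diagonal {self.d} mm disagree "
                    f"with aspect {self.aspect} beyond 1%"
                )


@dataclass(frozen=True)
class CaptureGeometry:
    """Camera-to-food-plane distance for a top-view shot.

    ``object_distance`` is in **centimetres** (see module docstring for
    the mixed cm/mm convention).
    """

    object_distance: float  # cm

    def __post_init__(self) -> None:
        if not (self.object_distance > 0):
            raise GeometryError(f"object distance must be positive, got {self.object_distance}")

    def bracket(self, f35: float) -> float:
        """The ground-sampling bracket ``u/f35 - 0.1`` (u in cm, f35 in
        mm); must be positive for a real image of a scene beyond the
        focal plane."""
        b = self.object_distance / f35 - 0.1
        if b <= 0:
            raise GeometryError(
                f"object distance {self.object_distance} cm is at or inside the focal "
                f"plane for f35={f35} mm (u/f35 must exceed 0.1)"
            )
        return b


@dataclass(frozen=True)
class AreaEstimate:
    """A pixel count together with the physical scale that converts it
    to a real-world area."""

    pixel_count: float
    scale: float  # cm^2 per pixel
    area: float = field(init=False)  # cm^2

    def __post_init__(self) -> None:
        if self.pixel_count < 0 or self.scale < 0:
            raise GeometryError("pixel count and scale must be non-negative")
        object.__setattr__(self, "area", self.pixel_count * self.scale)


def equivalent_focal_length(sensor: SensorSpec) -> float:
    """Convert a true focal length to its 35-mm equivalent.

    Uses the diagonal form ``f35 = 43.3 * f / d`` when the diagonal is
    known (preferred: it is aspect-independent), otherwise the
    width form ``f35 = 34.6 * f / w`` (4:3) or ``36.0 * f / w`` (3:2).
    """
    if sensor.d is not None:
        return round(FULL_FRAME_DIAGONAL_MM, 1) * sensor.f / sensor.d
    long_mm, _ = EQUIV_FRAME_MM[sensor.aspect]
    return long_mm * sensor.f / sensor.w


def ground_sample_length(
    x: float,
    axis_px: int,
    u: float,
    f35: float,
    axis: Literal["short", "long"] = "short",
    aspect: Aspect = "4:3",
) -> float:
    """Real-world length (cm) spanned by ``x`` pixels along one image axis.

    ``axis_px`` is the full-image pixel count along that axis, ``u`` the
    object distance in cm, ``f35`` the equivalent focal length in mm.
    The short axis maps onto the 26.0 mm equivalent side (4:3), the long
    axis onto 34.6 mm.  The ``u/f35 - 0.1`` bracket is the thin-lens
    inverse magnification in the mixed cm/mm convention.
    """
    if not (0 <= x <= axis_px):
        raise GeometryError(f"pixel extent x={x} outside [0, {axis_px}]")
    long_mm, short_mm = EQUIV_FRAME_MM[_norm_aspect(aspect)]
    c = short_mm if axis == "short" else long_mm
    return c * (x / axis_px) * CaptureGeometry(u).bracket(f35)


def pixel_area_scale(spec: CameraSpec, geom: CaptureGeometry) -> float:
    """Physical area (cm^2) of a single pixel footprint in the object
    plane: ``[(26.0/a) * (u/f35 - 0.1)]^2`` with ``a`` the short-side
    pixel count.

    The short-side form is canonical; the long-side form agrees within
    the 1% aspect tolerance and is used only as a consistency check.
    """
    _, short_mm = spec.frame_mm
    side = (short_mm / spec.width_px) * geom.bracket(spec.f35)
    return side * side


def region_area(n: float, spec: CameraSpec, geom: CaptureGeometry) -> AreaEstimate:
    """Convert a segmented-region pixel count into a physical area
    estimate: ``S = n * [(26.0/a) * (u/f35 - 0.1)]^2``."""
    if n < 0:
        raise GeometryError(f"pixel count must be non-negative, got {n}")
    return AreaEstimate(pixel_count=n, scale=pixel_area_scale(spec, geom))


def thin_lens_object_length(image_length: float, u: float, f: float) -> float:
    """Independent thin-lens oracle: real-world length (mm) of a feature
    of length ``image_length`` mm on the equivalent frame, for object
    distance ``u`` mm and focal length ``f`` mm, all in millimetres.

    From ``1/v + 1/u = 1/f``: ``v = f*u/(u - f)``, magnification
    ``m = v/u = f/(u - f)``, object length = ``image_length / m``.
    This is the ground truth that ``ground_sample_length`` must match
    exactly under the cm/mm convention.
    """
    if u <= f:
        raise GeometryError(f"no real image: object distance {u} mm <= focal length {f} mm")
    return image_length * (u - f) / f


# ---------------------------------------------------------------------------
# EXIF helpers

_EXIF_F35_TAG = 0xA405  # FocalLengthIn35mmFilm


def read_exif_f35(path) -> Optional[float]:
    """Read the FocalLengthIn35mmFilm EXIF tag from an image file, or
    None when absent/zero."""
    from PIL import Image

    with Image.open(path) as im:
        exif = im.getexif()
        value = exif.get(_EXIF_F35_TAG)
        if value is None:
            return None
        f35 = float(value)
        return f35 if f35 > 0 else None


def camera_spec_from_image(path, f35: Optional[float] = None, aspect: Optional[Aspect] = None) -> CameraSpec:
    """Build a :class:`CameraSpec` from an image file's pixel dimensions
    and EXIF metadata.

    ``f35`` overrides EXIF; when ``aspect`` is not given it is inferred
    from the pixel dimensions (must match 4:3 or 3:2 within 1%).
    """
    from PIL import Image

    with Image.open(path) as im:
        w_px, h_px = im.size
    if f35 is None:
        f35 = read_exif_f35(path)
    if f35 is None:
        raise InvalidSpecError(
            f"{path}: no FocalLengthIn35mmFilm EXIF tag; pass f35 explicitly"
        )
    short, long_ = sorted((w_px, h_px))
    if aspect is None:
        ratio = long_ / short
        for cand, r in _ASPECT_RATIO.items():
            if abs(ratio - r) / r <= 0.01:
                aspect = cand  # type: ignore[assignment]
                break
        else:
            raise InvalidSpecError(
                f"{path}: pixel ratio {ratio:.4f} matches neither 4:3 nor 3:2 within 1%"
            )
    return CameraSpec(f35=f35, width_px=short, height_px=long_, aspect=aspect)
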