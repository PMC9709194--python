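import numpy as np
import pytest

from foodscale.camera_geometry import CameraSpec, CaptureGeometry
from foodscale.imaging_ops import FoodImage


@pytest.fixture
def camera() -> CameraSpec:
    """Default capture protocol camera: f35 = 46 mm, 480x640 4:3."""
    return CameraSpec(f35=46.0, width_px=480, height_px=640, aspect="4:3")


@pytest.fixture
def geometry() -> CaptureGeometry:
    """Default shooting height: 40.6 cm."""
    return CaptureGeometry(object_distance=40.6)


def make_disk_image(
    shape=(512, 512), center=(256.0, 256.0), radius=100.0,
    background=0.95, foreground=0.3,
) -> FoodImage:
    """Sharp disk on a uniform background; disk membership uses the same
    pixel-centre rule as the counting primitives."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.full(shape, background, dtype=float)
    mask = (rr + 0.5 - center[0]) ** 2 + (cc + 0.5 - center[1]) ** 2 <= radius**2
    img[mask] = foreground
    return FoodImage(img)


def brute_force_pixel_count(polygon: np.ndarray) -> int:
    """Independent even-odd point-in-polygon oracle: a plain per-pixel,
    per-edge crossing count, no vectorisation shared with the
    implementation."""
    poly = [(float(r), float(c)) for r, c in polygon]
    r_lo = int(np.floor(min(p[0] for p in poly)))
    r_hi = int(np.ceil(max(p[0] for p in poly)))
    c_lo = int(np.floor(min(p[1] for p in poly)))
    c_hi = int(np.ceil(max(p[1] for p in poly)))
    count = 0
    n = len(poly)
    for i in range(r_lo, r_hi):
        py = i + 0.5
        for j in range(c_lo, c_hi):
            px = j + 0.5
            inside = False
            for k in range(n):
                ay, ax = poly[k]
                by, bx = poly[(k + 1) % n]
                if (ay > py) != (by > py):
                    x_at = ax + (py - ay) * (bx - ax) / (by - ay)
                    if px < x_at:
                        inside = not inside
            if inside:
                count += 1
    return count
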