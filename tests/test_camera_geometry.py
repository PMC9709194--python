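"""Geometry: equivalent focal length, ground sampling, thin-lens oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foodscale.camera_geometry import (
    CameraSpec,
    CaptureGeometry,
    SensorSpec,
    derived_conversion_constants,
    equivalent_focal_length,
    ground_sample_length,
    pixel_area_scale,
    region_area,
    thin_lens_object_length,
)
from foodscale.errors import GeometryError, InvalidSpecError


class TestEquivalentFocalLength:
    @pytest.mark.parametrize(
        "sensor, expected",
        [
            (SensorSpec(f=10.0, w=34.6, aspect="4:3"), 10.0),  # w equals the 4:3 equivalent width
            (SensorSpec(f=8.0, d=8.0), 43.3),  # f = d isolates the diagonal constant
            (SensorSpec(f=4.25, w=5.76, aspect="4:3"), 25.53),  # typical phone sensor
            (SensorSpec(f=10.0, w=36.0, aspect="3:2"), 10.0),
        ],
    )
    def test_conversion(self, sensor, expected):
        assert equivalent_focal_length(sensor) == pytest.approx(expected, rel=1e-3)

    def test_missing_both_dimensions_rejected(self):
        with pytest.raises(InvalidSpecError):
            SensorSpec(f=4.0)

    def test_width_and_diagonal_forms_agree(self):
        # sensor whose w and d match 4:3 exactly: d = w * 5/4
        f = 4.25
        by_width = equivalent_focal_length(SensorSpec(f=f, w=5.76, aspect="4:3"))
        by_diag = equivalent_focal_length(SensorSpec(f=f, d=5.76 * 1.25, aspect="4:3"))
        assert abs(by_width - by_diag) / by_diag < 0.002

    def test_diagonal_preferred_when_both_given(self):
        s = SensorSpec(f=4.25, w=5.76, d=7.2, aspect="4:3")
        assert equivalent_focal_length(s) == pytest.approx(43.3 * 4.25 / 7.2)

    def test_inconsistent_width_diagonal_rejected(self):
        with pytest.raises(InvalidSpecError):
            SensorSpec(f=4.0, w=5.76, d=9.0, aspect="4:3")


class TestDerivedConstants:
    def test_full_frame_derivation_matches_printed_values(self):
        c = derived_conversion_constants()
        assert round(c["4:3_width"], 1) == 34.6
        assert round(c["4:3_height"], 1) == 26.0
        assert round(c["diagonal"], 1) == 43.3
        assert round(c["3:2_width"], 1) == 36.0


class TestGroundSampleLength:
    def test_zero_pixels_is_zero_length(self):
        assert ground_sample_length(0, 3000, 50.6, 46.0) == 0.0

    def test_unit_bracket_recovers_frame_constant(self):
        # u = 1.1 * f35 numerically makes (u/f35 - 0.1) = 1
        assert ground_sample_length(3000, 3000, 50.6, 46.0, axis="short") == pytest.approx(26.0)

    def test_protocol_long_side_extent(self):
        # full long side at the 46 mm / 40.6 cm capture protocol
        got = ground_sample_length(4000, 4000, 40.6, 46.0, axis="long")
        assert got == pytest.approx(27.08, abs=0.005)

    def test_object_inside_focal_plane_rejected(self):
        with pytest.raises(GeometryError):
            ground_sample_length(100, 3000, 0.4, 46.0)

    def test_pixel_extent_out_of_range_rejected(self):
        with pytest.raises(GeometryError):
            ground_sample_length(3001, 3000, 40.6, 46.0)

    def test_unit_consistency_mm_route(self):
        # converting u to mm and working in mm reproduces the cm result
        u_cm, f35, x, a = 40.6, 46.0, 1234, 3000
        a_cm = ground_sample_length(x, a, u_cm, f35, axis="short")
        a_mm = 26.0 * (x / a) * (10 * u_cm / f35 - 1)
        assert a_cm == pytest.approx(a_mm / 10, rel=1e-12)


class TestThinLensOracle:
    def test_unit_magnification_at_twice_focal_length(self):
        assert thin_lens_object_length(26.0, u=2 * 46.0, f=46.0) == pytest.approx(26.0)

    def test_tenfold_at_eleven_focal_lengths(self):
        assert thin_lens_object_length(26.0, u=11 * 46.0, f=46.0) == pytest.approx(260.0)

    def test_no_real_image_inside_focal_length(self):
        with pytest.raises(GeometryError):
            thin_lens_object_length(26.0, u=40.0, f=46.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        u=st.floats(min_value=10.0, max_value=500.0),
        f35=st.floats(min_value=10.0, max_value=90.0),
    )
    def test_ground_sample_length_is_the_thin_lens_prediction(self, u, f35):
        # identity: full short side in cm x 10 == thin-lens object length
        # of the 26.0 mm frame side with everything in mm
        if u / f35 <= 0.1 + 1e-6:
            return
        a_cm = ground_sample_length(3000, 3000, u, f35, axis="short")
        oracle_mm = thin_lens_object_length(26.0, u=10 * u, f=f35)
        assert a_cm * 10 == pytest.approx(oracle_mm, rel=1e-9)


class TestPixelAreaScale:
    def test_unit_bracket_unit_pixel(self):
        spec = CameraSpec(f35=46.0, width_px=26, height_px=35, aspect="4:3")
        assert pixel_area_scale(spec, CaptureGeometry(50.6)) == pytest.approx(1.0, rel=1e-6)

    def test_protocol_scale(self):
        spec = CameraSpec(f35=46.0, width_px=3000, height_px=4000)
        got = pixel_area_scale(spec, CaptureGeometry(40.6))
        assert got == pytest.approx(4.601e-5, rel=1e-3)

    def test_short_and_long_side_forms_agree(self):
        spec = CameraSpec(f35=46.0, width_px=3000, height_px=4000)
        geom = CaptureGeometry(40.6)
        short_form = pixel_area_scale(spec, geom)
        long_form = (34.6 / spec.height_px * geom.bracket(spec.f35)) ** 2
        assert abs(short_form - long_form) / long_form < 0.01


class TestRegionArea:
    def test_zero_pixels_zero_area(self, camera, geometry):
        assert region_area(0, camera, geometry).area == 0.0

    def test_protocol_example(self):
        spec = CameraSpec(f35=46.0, width_px=3000, height_px=4000)
        est = region_area(1_000_000, spec, CaptureGeometry(40.6))
        assert est.area == pytest.approx(46.01, abs=0.01)

    def test_negative_count_rejected(self, camera, geometry):
        with pytest.raises(GeometryError):
            region_area(-1, camera, geometry)

    def test_additive_in_pixel_count(self, camera, geometry):
        a1 = region_area(1000, camera, geometry).area
        a2 = region_area(2345, camera, geometry).area
        both = region_area(3345, camera, geometry).area
        assert both == pytest.approx(a1 + a2, rel=1e-12)

    def test_quadratic_in_bracket(self):
        spec = CameraSpec(f35=46.0, width_px=3000, height_px=4000)
        f35 = spec.f35
        u1 = 40.6
        b1 = u1 / f35 - 0.1
        u2 = (2 * b1 + 0.1) * f35  # doubles the bracket
        a1 = region_area(5000, spec, CaptureGeometry(u1)).area
        a2 = region_area(5000, spec, CaptureGeometry(u2)).area
        assert a2 == pytest.approx(4 * a1, rel=1e-9)


class TestSpecs:
    def test_orientation_normalised(self):
        spec = CameraSpec(f35=46.0, width_px=640, height_px=480)
        assert (spec.width_px, spec.height_px) == (480, 640)

    def test_aspect_mismatch_rejected(self):
        with pytest.raises(InvalidSpecError):
            CameraSpec(f35=46.0, width_px=480, height_px=720, aspect="4:3")

    def test_capture_geometry_positive(self):
        with pytest.raises(GeometryError):
            CaptureGeometry(object_distance=-1.0)
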