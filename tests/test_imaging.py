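"""Synthetic plate rendering and the automated ray-measurement workflow."""

import numpy as np
import pytest

from conftest import make_plate
from mycometry import (
    CalibratedImage,
    MeasureConfig,
    RenderConfig,
    calibrate_plate_image,
    calibrate_scale,
    detect_dish,
    extract_plate_traces,
    fit_extension_rate,
    measure_ray_crossings,
    render_plate_image,
)
from mycometry.errors import (
    DishDetectionError,
    ExtractionError,
    GeometryError,
    ValidationError,
)

MMPP = 0.1


def ring_plate(radii, n_axes=3):
    return make_plate({f"axis{a + 1}": list(radii) for a in range(n_axes)})


@pytest.fixture(scope="module")
def clean_image():
    """Noise-free plate with rings at 5, 10, 15 mm from the plug edge."""
    return render_plate_image(
        ring_plate([5.0, 10.0, 15.0]), RenderConfig(noise_sd=0.0)
    )


def test_ring_pixel_geometry_without_plug():
    """Plug radius 0: ring crossings sit at radius/mm_per_pixel from centre."""
    img = render_plate_image(
        ring_plate([5.0, 10.0, 15.0]), RenderConfig(noise_sd=0.0),
        plug_radius_mm=0.0,
    )
    cal = calibrate_plate_image(img)
    for angle in (0.0, 40.0, 133.0, 287.5):
        ray = measure_ray_crossings(cal, img.center_xy, angle, expected_n=3)
        assert not ray.mismatch
        px = np.array(ray.crossings_mm) / img.mm_per_pixel
        assert np.allclose(px, [50.0, 100.0, 150.0], atol=2.0)


class TestCalibration:
    def test_scale_is_exact_ratio(self):
        assert calibrate_scale(900, 90.0) == pytest.approx(0.1)
        assert calibrate_scale(450, 90.0) == pytest.approx(0.2)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            calibrate_scale(0, 90.0)
        with pytest.raises(ValidationError):
            calibrate_scale(100, -1.0)


class TestDetectDish:
    def test_detects_rendered_rim_within_two_pixels(self, clean_image):
        (cx, cy), diameter = detect_dish(clean_image.pixels)
        assert abs(cx - clean_image.center_xy[0]) <= 2.0
        assert abs(cy - clean_image.center_xy[1]) <= 2.0
        assert abs(diameter / 2 - clean_image.dish_diameter_px / 2) <= 2.0

    def test_blank_image_raises(self):
        with pytest.raises(DishDetectionError, match="manual"):
            detect_dish(np.full((200, 200), 0.8))

    def test_manual_override_returned_verbatim(self):
        manual = ((12.5, 13.5), 181.0)
        assert detect_dish(np.zeros((5, 5)), manual=manual) == manual


class TestRayCrossings:
    def test_uniform_image_yields_no_crossings(self):
        cal = CalibratedImage(np.full((400, 400), 0.7), (200.0, 200.0), 360.0)
        ray = measure_ray_crossings(cal, (200.0, 200.0), 0.0, expected_n=3)
        assert ray.crossings_mm == []
        assert ray.mismatch

    def test_rings_closer_than_stroke_are_merged(self):
        # two rings 0.6 mm apart with a 0.8 mm stroke blur into one band
        img = render_plate_image(
            ring_plate([10.0, 10.6]), RenderConfig(noise_sd=0.0), plug_radius_mm=0.0
        )
        cal = calibrate_plate_image(img)
        ray = measure_ray_crossings(cal, img.center_xy, 0.0, expected_n=2)
        assert len(ray.crossings_mm) == 1
        assert ray.mismatch

    def test_ray_exiting_image_raises(self, clean_image):
        cropped = clean_image.pixels[:, : clean_image.pixels.shape[1] // 2]
        cal = CalibratedImage(cropped, clean_image.center_xy,
                              clean_image.dish_diameter_px)
        with pytest.raises(GeometryError, match="exits"):
            measure_ray_crossings(cal, clean_image.center_xy, 0.0)


class TestExtraction:
    def test_round_trip_zero_noise(self, clean_image):
        cal = calibrate_plate_image(clean_image)
        plate = extract_plate_traces(cal, 3, plug_radius_mm=2.5)
        assert not any(plate.axis_flags.values())
        tol = 2 * clean_image.mm_per_pixel
        for axis, day, radius in plate.observations:
            assert radius == pytest.approx(
                clean_image.true_radii_mm[axis][int(day)], abs=tol
            )

    def test_wavy_rings_stay_exact_on_axes(self):
        img = render_plate_image(
            ring_plate([6.0, 12.0, 18.0]),
            RenderConfig(noise_sd=0.0, waviness_mm=0.8, waviness_cycles=6),
        )
        cal = calibrate_plate_image(img)
        plate = extract_plate_traces(cal, 3)
        tol = 2 * img.mm_per_pixel
        for axis, day, radius in plate.observations:
            assert radius == pytest.approx(img.true_radii_mm[axis][int(day)], abs=tol)

    def test_missing_ring_flags_axes_but_returns_partial(self, clean_image):
        cal = calibrate_plate_image(clean_image)
        plate = extract_plate_traces(cal, 5)  # only 3 rings exist
        assert all(plate.axis_flags.values())
        days = {int(o[1]) for o in plate.observations}
        assert days == {1, 2, 3}

    def test_blank_plate_raises_extraction_error(self):
        blank = np.full((500, 500), 0.8)
        cal = CalibratedImage(blank, (250.0, 250.0), 450.0)
        with pytest.raises(ExtractionError):
            extract_plate_traces(cal, 3)

    def test_rotation_by_axis_spacing_is_equivariant(self):
        """A rotationally symmetric plate reads the same after rotating the
        reference axis by 360/n_axes degrees."""
        img = render_plate_image(ring_plate([5.0, 10.0, 15.0]),
                                 RenderConfig(noise_sd=0.0))
        cal = calibrate_plate_image(img)
        a = extract_plate_traces(cal, 3, reference_angle_deg=0.0)
        b = extract_plate_traces(cal, 3, reference_angle_deg=120.0)
        ra = sorted(round(o[2], 3) for o in a.observations)
        rb = sorted(round(o[2], 3) for o in b.observations)
        assert np.allclose(ra, rb, atol=2 * img.mm_per_pixel)

    def test_round_trip_recovers_rate(self):
        """Render -> extract -> fit recovers the drawn plate's slope."""
        plate_in = ring_plate([4.0, 8.1, 11.9, 16.0, 20.1])
        img = render_plate_image(plate_in, RenderConfig(noise_sd=0.01, seed=4))
        cal = calibrate_plate_image(img, auto_detect=True)
        plate_out = extract_plate_traces(cal, 5)
        fit_in = fit_extension_rate(plate_in)
        fit_out = fit_extension_rate(plate_out)
        assert fit_out.rate == pytest.approx(fit_in.rate, abs=0.05)


class TestRenderValidation:
    def test_zero_stroke_rejected(self):
        with pytest.raises(ValidationError, match="stroke"):
            render_plate_image(ring_plate([5.0]), RenderConfig(stroke_mm=0.0))

    def test_ring_beyond_dish_rejected(self):
        with pytest.raises(GeometryError):
            render_plate_image(ring_plate([44.0, 44.5]), RenderConfig())

    def test_seeded_noise_is_deterministic(self):
        cfg = RenderConfig(noise_sd=0.02, seed=9)
        img1 = render_plate_image(ring_plate([5.0, 10.0]), cfg)
        img2 = render_plate_image(ring_plate([5.0, 10.0]), cfg)
        assert np.array_equal(img1.pixels, img2.pixels)

    def test_finer_resolution_does_not_hurt_accuracy(self):
        errs = {}
        for mmpp in (0.2, 0.1):
            img = render_plate_image(ring_plate([5.13, 10.07, 14.91]),
                                     RenderConfig(noise_sd=0.0, mm_per_pixel=mmpp))
            plate = extract_plate_traces(calibrate_plate_image(img), 3)
            errs[mmpp] = np.median([
                abs(r - img.true_radii_mm[a][int(d)]) for a, d, r in plate.observations
            ])
        # allow half a sub-pixel sampling step of quantization slack
        assert errs[0.1] <= errs[0.2] + 0.5 * 0.25 * 0.1
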