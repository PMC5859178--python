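"""Tests for contour detection, geometry measurement and contrast index."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import ellipe

from guvpore.errors import (
    DegenerateContourError,
    EmptyTrackError,
    InsufficientPixelsError,
    NoContourError,
)
from guvpore.segmentation import (
    CalibrationParams,
    contrast_index,
    detect_contour,
    measure_geometry,
    track_movie,
)
from guvpore.synthetic import (
    OpticalParams,
    ShapeState,
    contrast_loss_scenario,
    generate_movie,
    pore_flash_scenario,
    render_frame,
    shrinkage_scenario,
    static_scenario,
)


def circle_polygon(radius_px: float, n: int = 1024, center=(0.0, 0.0)) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius_px * np.cos(theta), center[1] + radius_px * np.sin(theta)]
    )


class TestMeasureGeometry:
    def test_analytic_circle_ff_is_one(self, calibration):
        """A circular contour calibrates the estimator: FF must be 1."""
        geom = measure_geometry(circle_polygon(50.0), calibration)
        assert geom.form_factor == pytest.approx(1.0, abs=1e-4)
        assert geom.area_um2 == pytest.approx(math.pi * 25.0**2, rel=1e-4)

    def test_square_ff_is_pi_over_4(self, calibration):
        square = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], dtype=float)
        geom = measure_geometry(square, calibration)
        assert geom.form_factor == pytest.approx(math.pi / 4.0, rel=1e-12)

    def test_two_to_one_ellipse_ff(self, calibration):
        """FF of a 2:1 ellipse checked against the elliptic-integral perimeter
        P = 4 a E(e^2); FF = pi^2 / (8 E^2) ~ 0.841."""
        a, b = 40.0, 20.0
        theta = np.linspace(0.0, 2.0 * math.pi, 4096, endpoint=False)
        poly = np.column_stack([a * np.cos(theta), b * np.sin(theta)])
        expected_ff = math.pi**2 / (8.0 * float(ellipe(1.0 - (b / a) ** 2)) ** 2)
        geom = measure_geometry(poly, calibration)
        assert expected_ff == pytest.approx(0.841, abs=2e-3)
        assert geom.form_factor == pytest.approx(expected_ff, abs=1e-3)

    def test_ff_recomputable_from_stored_area_perimeter(self, calibration):
        geom = measure_geometry(circle_polygon(30.0), calibration)
        assert geom.form_factor == pytest.approx(
            4.0 * math.pi * geom.area_um2 / geom.perimeter_um**2, abs=1e-12
        )

    def test_degenerate_polygon_rejected(self, calibration):
        with pytest.raises(DegenerateContourError):
            measure_geometry(np.array([[0.0, 0.0], [1.0, 1.0]]), calibration)
        with pytest.raises(DegenerateContourError):
            measure_geometry(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]), calibration)

    @given(scale=st.floats(0.1, 10.0))
    def test_scale_equivariance(self, scale):
        """Scaling pixel_size by k scales A by k^2, P by k and leaves FF fixed."""
        poly = circle_polygon(40.0, n=256)
        base = measure_geometry(poly, CalibrationParams(pixel_size=0.5))
        scaled = measure_geometry(poly, CalibrationParams(pixel_size=0.5 * scale))
        assert scaled.area_um2 == pytest.approx(base.area_um2 * scale**2, rel=1e-12)
        assert scaled.perimeter_um == pytest.approx(base.perimeter_um * scale, rel=1e-12)
        assert scaled.form_factor == pytest.approx(base.form_factor, rel=1e-12)


class TestDetectContour:
    def test_rendered_circle_area_within_one_percent(self, calibration, noiseless_optics):
        shape = ShapeState(base_radius=25.0)  # 50 px at 0.5 um/px
        img = render_frame(shape, noiseless_optics, 0.5, 128)
        geom = measure_geometry(detect_contour(img, calibration), calibration)
        assert geom.area_um2 == pytest.approx(math.pi * 25.0**2, rel=0.01)

    def test_blank_image_raises(self, calibration):
        with pytest.raises(NoContourError):
            detect_contour(np.full((128, 128), 0.5), calibration)

    def test_largest_object_wins(self, calibration, noiseless_optics):
        """With two vesicles in frame the tracker keeps the larger one."""
        big = ShapeState(base_radius=25.0, center=(-16.0, 0.0))
        small = ShapeState(base_radius=10.0, center=(26.0, 0.0))
        ext = noiseless_optics.exterior_intensity
        img_big = render_frame(big, noiseless_optics, 0.5, 192)
        img_small = render_frame(small, noiseless_optics, 0.5, 192)
        img = np.clip(img_big + img_small - ext, 0.0, 1.0)
        geom = measure_geometry(detect_contour(img, calibration), calibration)
        assert geom.area_um2 == pytest.approx(math.pi * 25.0**2, rel=0.02)
        assert geom.centroid_um[0] < 0.5 * 192 * 0.5  # centred on the big one

    def test_candidates_below_min_radius_rejected(self, noiseless_optics):
        shape = ShapeState(base_radius=5.0)  # 10 px
        img = render_frame(shape, noiseless_optics, 0.5, 128)
        with pytest.raises(NoContourError):
            detect_contour(img, CalibrationParams(pixel_size=0.5, min_radius_px=20.0))

    def test_truth_vs_measured_oracle(self, calibration, noiseless_optics):
        """On noiseless renders the measured (A, P, FF) match the ground truth
        within 1% / 1% / 0.02 for radii >= 30 px."""
        for shape in (
            ShapeState(base_radius=15.0),
            ShapeState(base_radius=25.0),
            ShapeState(base_radius=20.0, ellipse_aspect=1.3),
        ):
            area, perim, ff = shape.true_geometry()
            img = render_frame(shape, noiseless_optics, 0.5, 160)
            geom = measure_geometry(detect_contour(img, calibration), calibration)
            assert geom.area_um2 == pytest.approx(area, rel=0.01)
            assert geom.perimeter_um == pytest.approx(perim, rel=0.01)
            assert geom.form_factor == pytest.approx(ff, abs=0.02)

    def test_isometry_invariance(self, calibration, noiseless_optics):
        """Translating and rotating the vesicle changes FF by < 0.005."""
        base = ShapeState(base_radius=20.0, ellipse_aspect=1.2)
        ff_ref = measure_geometry(
            detect_contour(render_frame(base, noiseless_optics, 0.5, 160), calibration),
            calibration,
        ).form_factor
        for moved in (
            ShapeState(base_radius=20.0, ellipse_aspect=1.2, center=(7.3, -5.1)),
            ShapeState(base_radius=20.0, ellipse_aspect=1.2, rotation=0.9),
            ShapeState(base_radius=20.0, ellipse_aspect=1.2, center=(-4.0, 6.0), rotation=2.2),
        ):
            ff = measure_geometry(
                detect_contour(render_frame(moved, noiseless_optics, 0.5, 160), calibration),
                calibration,
            ).form_factor
            assert abs(ff - ff_ref) < 0.005


class TestContrastIndex:
    def test_equal_intensities_give_zero(self, calibration):
        optics = OpticalParams(interior_intensity=0.5, exterior_intensity=0.5,
                               rim_amplitude=0.0, noise_sd=0.0)
        shape = ShapeState(base_radius=20.0)
        img = render_frame(shape, optics, 0.5, 128)
        poly = circle_polygon(40.0, center=(63.5, 63.5))
        assert contrast_index(img, poly) == pytest.approx(0.0, abs=1e-6)

    def test_definition_arithmetic(self):
        """Interior 0.2, exterior 0.6 -> C = 0.4/0.8 = 0.5."""
        optics = OpticalParams(interior_intensity=0.2, exterior_intensity=0.6, noise_sd=0.0)
        shape = ShapeState(base_radius=20.0)
        img = render_frame(shape, optics, 0.5, 128)
        poly = circle_polygon(40.0, center=(63.5, 63.5))
        assert contrast_index(img, poly) == pytest.approx(0.5, abs=0.02)

    def test_sign_preserved_for_bright_interior(self):
        optics = OpticalParams(interior_intensity=0.7, exterior_intensity=0.3, noise_sd=0.0)
        img = render_frame(ShapeState(base_radius=20.0), optics, 0.5, 128)
        poly = circle_polygon(40.0, center=(63.5, 63.5))
        assert contrast_index(img, poly) < -0.3

    def test_monotone_contrast_decay_measured(self, calibration):
        """A scenario with steadily fading interior yields a strictly
        decreasing measured contrast trace (noiseless)."""
        scenario = contrast_loss_scenario(
            frames=12, loss_start=0, decay_time_s=1.0,
            optics=OpticalParams(noise_sd=0.0),
        )
        stack, _ = generate_movie(scenario)
        track = track_movie(stack, calibration)
        trace = [g.contrast_index for g in track.geometries]
        assert all(b < a for a, b in zip(trace, trace[1:]))

    def test_empty_exterior_raises(self, calibration):
        img = np.full((64, 64), 0.5)
        huge = circle_polygon(80.0, center=(32.0, 32.0))
        with pytest.raises(InsufficientPixelsError):
            contrast_index(img, huge)


class TestTrackMovie:
    def test_static_circle_movie(self, calibration, noiseless_optics):
        stack, _ = generate_movie(static_scenario(frames=10, optics=noiseless_optics))
        track = track_movie(stack, calibration)
        assert track.n_frames == 10
        assert track.gap_fraction == 0.0
        for geom in track.geometries:
            assert 0.98 <= geom.form_factor <= 1.02

    def test_pore_frame_becomes_gap(self, calibration, noiseless_optics):
        stack, _ = generate_movie(
            pore_flash_scenario(frames=7, pore_frame=3, optics=noiseless_optics)
        )
        track = track_movie(stack, calibration)
        assert track.gap_frames == (3,)

    def test_shrinkage_tracked_within_two_percent(self, calibration):
        """Measured area follows the 30%-shrinkage ground truth to < 2%."""
        scenario = shrinkage_scenario(frames=30, seed=5)
        stack, truth = generate_movie(scenario)
        track = track_movie(stack, calibration)
        measured = np.array([g.area_um2 for g in track.geometries])
        rel = np.abs(measured / truth.area_um2 - 1.0)
        assert track.gap_fraction == 0.0
        assert rel.max() < 0.02

    def test_all_gaps_raises(self, calibration):
        stack = np.full((3, 64, 64), 0.5)
        with pytest.raises(EmptyTrackError):
            track_movie(stack, calibration)

    def test_dataframe_schema(self, calibration, noiseless_optics):
        stack, _ = generate_movie(static_scenario(frames=4, optics=noiseless_optics))
        df = track_movie(stack, calibration).to_dataframe(fps=10.0)
        assert list(df.columns) == [
            "frame", "time_s", "area_um2", "perimeter_um", "ff", "contrast", "gap_flag"
        ]
        assert df.gap_flag.sum() == 0
        assert df.time_s.iloc[1] == pytest.approx(0.1)
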