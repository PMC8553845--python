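"""Image stage: centre detection, profiles, registration, facet diameters."""

import numpy as np
import pytest

from pseudopupil.errors import (
    InvalidInputError,
    NoSignalError,
    RegistrationError,
    UnboundedProfileError,
)
from pseudopupil.hexlattice import LatticeCoord, LatticeFrame, lattice_to_cart
from pseudopupil.pupil_detect import (
    DetectionResult,
    ImageFrame,
    IntensityProfile,
    centre_offset,
    detect_centre,
    facet_diameter_line,
    line_profile,
    pixel_to_lattice,
    profile_fwhm,
    profile_peak,
    solve_lattice_frame,
)
from pseudopupil.synthetic_eye import GonioPose, OpticsParams, render_frame


def gaussian_frame(centre_rc, sigma_px=6.0, shape=(64, 64), scale=1.0, offset=0.0):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.exp(-((rr - centre_rc[0]) ** 2 + (cc - centre_rc[1]) ** 2) / (2 * sigma_px**2))
    return ImageFrame(intensities=scale * img + offset, pixel_scale_um=2.0)


class TestDetectCentre:
    def test_single_hot_pixel(self):
        img = np.zeros((32, 32))
        img[10, 20] = 1.0
        det = detect_centre(ImageFrame(img, 1.0))
        assert det.centre_px == pytest.approx((10.0, 20.0))
        assert det.n_pixels == 1

    def test_subpixel_gaussian_centre(self):
        frame = gaussian_frame((30.3, 24.7))
        det = detect_centre(frame)
        assert det.centre_px[0] == pytest.approx(30.3, abs=0.1)
        assert det.centre_px[1] == pytest.approx(24.7, abs=0.1)

    def test_flat_frame_is_no_signal(self):
        with pytest.raises(NoSignalError):
            detect_centre(ImageFrame(np.ones((16, 16)), 1.0))

    def test_affine_intensity_invariance(self):
        a = detect_centre(gaussian_frame((20.2, 33.8)))
        b = detect_centre(gaussian_frame((20.2, 33.8), scale=37.0, offset=5.0))
        assert a.centre_px == pytest.approx(b.centre_px, abs=1e-9)

    def test_dark_mode_matches_bright_on_inverted_signal(self):
        bright = gaussian_frame((22.4, 18.9))
        dark = ImageFrame(1.0 - bright.intensities, bright.pixel_scale_um)
        a = detect_centre(bright, mode="bright")
        b = detect_centre(dark, mode="dark")
        assert a.centre_px == pytest.approx(b.centre_px, abs=1e-9)

    def test_bad_threshold_rejected(self):
        with pytest.raises(InvalidInputError):
            detect_centre(gaussian_frame((10, 10)), threshold_frac=1.5)


class TestLineProfile:
    def test_constant_region_flagged_flat(self):
        frame = ImageFrame(np.full((32, 32), 0.7), 1.0)
        prof = line_profile(frame, (5, 2), (5, 29), 21)
        assert prof.flat
        assert np.all(prof.values == 0)

    def test_linear_ramp_profile(self):
        img = np.tile(np.linspace(0, 1, 40), (40, 1))
        prof = line_profile(ImageFrame(img, 1.0), (10, 0), (10, 39), 40)
        np.testing.assert_allclose(prof.values, np.linspace(0, 1, 40), atol=1e-9)

    def test_positions_in_um(self):
        frame = gaussian_frame((32, 32), shape=(64, 64))  # scale 2 um/px
        prof = line_profile(frame, (32, 0), (32, 63), 64)
        assert prof.positions[-1] == pytest.approx(63 * 2.0)

    def test_peak_at_detected_centre(self):
        frame = gaussian_frame((31.5, 40.2), sigma_px=5.0)
        det = detect_centre(frame)
        prof = line_profile(frame, (det.centre_px[0], 0), (det.centre_px[0], 63), 64)
        step = prof.positions[1] - prof.positions[0]
        assert profile_peak(prof) == pytest.approx(det.centre_px[1] * 2.0, abs=step)

    def test_endpoints_outside_frame_rejected(self):
        frame = gaussian_frame((10, 10), shape=(32, 32))
        with pytest.raises(InvalidInputError):
            line_profile(frame, (0, 0), (0, 200), 10)


class TestProfilePeakAndFwhm:
    def test_peak_simple_and_tie_rule(self):
        prof = IntensityProfile(np.array([0.0, 5.0, 10.0]), np.array([0.0, 1.0, 0.0]))
        assert profile_peak(prof) == 5.0
        plateau = IntensityProfile(
            np.array([0.0, 5.0, 10.0, 15.0]), np.array([0.0, 1.0, 1.0, 0.0])
        )
        assert profile_peak(plateau) == 5.0  # first plateau sample wins

    def test_peak_of_sampled_gaussian(self):
        pos = np.linspace(0, 15, 301)
        prof = IntensityProfile(pos, np.exp(-((pos - 7.3) ** 2) / 4))
        step = pos[1] - pos[0]
        assert profile_peak(prof) == pytest.approx(7.3, abs=step / 2 + 1e-12)

    def test_fwhm_triangle(self):
        pos = np.linspace(0, 16, 161)
        vals = np.clip(1 - np.abs(pos - 8) / 8, 0, None)  # half-width 4 per side
        assert profile_fwhm(IntensityProfile(pos, vals)) == pytest.approx(8.0, abs=1e-9)

    def test_fwhm_gaussian_analytic(self):
        pos = np.linspace(-15, 15, 601)
        vals = np.exp(-(pos**2) / (2 * 3.0**2))
        expected = 2 * np.sqrt(2 * np.log(2)) * 3.0  # 7.064
        assert profile_fwhm(IntensityProfile(pos, vals)) == pytest.approx(expected, rel=0.02)

    def test_monotone_ramp_unbounded(self):
        pos = np.linspace(0, 10, 50)
        with pytest.raises(UnboundedProfileError):
            profile_fwhm(IntensityProfile(pos, pos / 10))

    def test_flat_profile_no_signal(self):
        prof = IntensityProfile(np.arange(5.0), np.zeros(5), flat=True)
        with pytest.raises(NoSignalError):
            profile_peak(prof)


class TestCentreOffset:
    def test_identical_and_pythagorean(self):
        a = DetectionResult((0.0, 0.0), 1, 1.0)
        b = DetectionResult((3.0, 4.0), 1, 1.0)
        assert centre_offset(a, a, 2.0) == 0.0
        assert centre_offset(a, b, 2.0) == pytest.approx(10.0)


class TestLatticeRegistration:
    def test_origin_and_unit_pitch(self):
        ref = LatticeFrame(pitch_px=10.0, orientation_deg=0.0, origin_px=(50.0, 50.0))
        assert pixel_to_lattice((50.0, 50.0), ref) == pytest.approx((0.0, 0.0), abs=1e-12)
        # one pitch along u: +10 px in col
        assert pixel_to_lattice((50.0, 60.0), ref) == pytest.approx((1.0, 0.0), abs=1e-12)

    def test_round_trip_random_coords(self, rng):
        ref = LatticeFrame(pitch_px=7.3, orientation_deg=23.0, origin_px=(40.0, 55.0))
        th = np.radians(ref.orientation_deg)
        for _ in range(50):
            u, v = rng.uniform(-4, 4, size=2)
            x, y = lattice_to_cart((u, v))
            xr = np.cos(th) * x - np.sin(th) * y
            yr = np.sin(th) * x + np.cos(th) * y
            px = (ref.origin_px[0] - ref.pitch_px * yr, ref.origin_px[1] + ref.pitch_px * xr)
            got = pixel_to_lattice(px, ref)
            assert got == pytest.approx((u, v), abs=1e-9)

    def test_two_exact_correspondences_zero_residual(self):
        ref = LatticeFrame(pitch_px=8.0, orientation_deg=0.0, origin_px=(30.0, 30.0))
        lattice = [LatticeCoord(0, 0), LatticeCoord(3, -1)]
        px = []
        for c in lattice:
            x, y = lattice_to_cart(c)
            px.append((ref.origin_px[0] - 8.0 * y, ref.origin_px[1] + 8.0 * x))
        solved, rms = solve_lattice_frame(px, lattice)
        assert rms == pytest.approx(0.0, abs=1e-9)
        assert solved.pitch_px == pytest.approx(8.0, abs=1e-9)
        assert solved.orientation_deg == pytest.approx(0.0, abs=1e-9)

    def test_single_landmark_rejected(self):
        with pytest.raises(RegistrationError):
            solve_lattice_frame([(0.0, 0.0)], [LatticeCoord(0, 0)])

    def test_coincident_landmarks_rejected(self):
        with pytest.raises(RegistrationError):
            solve_lattice_frame(
                [(0.0, 0.0), (1.0, 1.0)], [LatticeCoord(0, 0), LatticeCoord(0, 0)]
            )

    def test_recovers_generator_frame_from_landmarks(self, render_eye_model, rng):
        optics = OpticsParams(landmark_count=6)
        frame = render_frame(
            render_eye_model, GonioPose(0, 10), optics, "fluorescent", rng,
            orientation_deg=12.0,
        )
        assert len(frame.landmarks_px) >= 3
        # jitter the known pixel positions as a stand-in for manual clicking
        jitter = rng.normal(0, 0.2, size=(len(frame.landmarks_px), 2))
        px = [
            (r + dr, c + dc)
            for (r, c), (dr, dc) in zip(frame.landmarks_px, jitter)
        ]
        solved, rms = solve_lattice_frame(px, list(frame.landmarks_lattice))
        truth = frame.lattice_frame
        assert solved.pitch_px == pytest.approx(truth.pitch_px, rel=0.01)
        assert solved.orientation_deg == pytest.approx(truth.orientation_deg, abs=0.5)
        assert rms < 1.0


class TestFacetDiameter:
    @pytest.mark.parametrize(
        "p0, p1, n, scale, expected",
        [((0, 0), (0, 150), 6, 1.0, 25.0), ((0, 0), (0, 120), 6, 0.5, 10.0)],
    )
    def test_arithmetic(self, p0, p1, n, scale, expected):
        assert facet_diameter_line(p0, p1, n, scale) == pytest.approx(expected)

    def test_zero_length_rejected(self):
        with pytest.raises(InvalidInputError):
            facet_diameter_line((5, 5), (5, 5), 6, 1.0)

    def test_count_outside_recommended_range_warns(self):
        with pytest.warns(UserWarning):
            facet_diameter_line((0, 0), (0, 30), 3, 1.0)

    def test_measures_generator_pitch(self, render_eye_model, rng):
        optics = OpticsParams()
        frame = render_frame(render_eye_model, GonioPose(0, 0), optics, "fluorescent", rng)
        ref = frame.lattice_frame
        # a horizontal line across 6 facet pitches along the u row
        r0, c0 = ref.origin_px
        d = facet_diameter_line((r0, c0), (r0, c0 + 6 * ref.pitch_px), 6, optics.pixel_scale_um)
        assert d == pytest.approx(render_eye_model.pitch_um, abs=0.5)


class TestRenderedPairProperties:
    def test_brightest_facet_is_on_axis(self, render_eye_model, rng):
        frame = render_frame(render_eye_model, GonioPose(0, 10), OpticsParams(), "fluorescent", rng)
        det = detect_centre(frame)
        r, c = det.centre_px
        tr, tc = frame.true_centre_px
        assert np.hypot(r - tr, c - tc) < frame.lattice_frame.pitch_px / 2

    def test_dark_centre_coincides_with_fluorescent(self, render_eye_model, rng):
        pose = GonioPose(0, 10)
        optics = OpticsParams()
        fl = render_frame(render_eye_model, pose, optics, "fluorescent", rng)
        dk = render_frame(render_eye_model, pose, optics, "dark", rng)
        df = detect_centre(fl, mode="bright")
        # broad dark pupils are centred on their darkest core
        dd = detect_centre(dk, threshold_frac=0.7, mode="dark")
        offset_facets = centre_offset(df, dd, 1.0) / fl.lattice_frame.pitch_px
        assert offset_facets < 0.2

    def test_na_increases_fwhm_peak_fixed(self, render_eye_model, rng):
        pose = GonioPose(0, 10)
        widths, peaks = [], []
        for na in (0.05, 0.1, 0.15):
            frame = render_frame(render_eye_model, pose, OpticsParams(na=na), "fluorescent", rng)
            det = detect_centre(frame)
            n = frame.shape[1]
            prof = line_profile(frame, (det.centre_px[0], 0), (det.centre_px[0], n - 1), n)
            widths.append(profile_fwhm(prof))
            peaks.append(profile_peak(prof))
        assert widths[0] < widths[1] < widths[2]
        step = frame.pixel_scale_um  # one sample per pixel
        assert max(peaks) - min(peaks) <= 2 * step
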