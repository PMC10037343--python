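"""Rigid estimation, LUT calibration/interpolation, accuracy metrics."""

import numpy as np
import pytest
from skimage.transform import EuclideanTransform

from fibrojoint import registration as reg
from fibrojoint import synthetic as syn
from fibrojoint.errors import CalibrationError, EstimationError


def make_pairs(rng, n=50, theta=9.0, t=(10.0, -5.0)):
    pts = rng.uniform(10, 90, size=(n, 2))
    true = reg.RigidTransform(theta, t[0], t[1])
    return pts, true.apply_points(pts), true


class TestProcrustes:
    def test_matches_independent_euclidean_fit(self, rng):
        """Closed-form equivalence against skimage's Euclidean estimator."""
        a, b, _ = make_pairs(rng)
        a_n = a + rng.normal(0, 0.3, a.shape)
        ours = reg.procrustes_rigid(a_n, b)
        # skimage uses (x, y) = (col, row) coordinates
        skt = EuclideanTransform.from_estimate(a_n[:, ::-1], b[:, ::-1])
        assert skt
        theta_sk = np.degrees(skt.rotation)
        assert ours.theta_deg == pytest.approx(theta_sk, abs=1e-9)
        assert np.allclose(
            [ours.tc_px, ours.tr_px], skt.translation, atol=1e-9
        )

    def test_exact_recovery(self, rng):
        a, b, true = make_pairs(rng)
        fit = reg.procrustes_rigid(a, b)
        assert fit.theta_deg == pytest.approx(true.theta_deg, abs=1e-10)
        assert np.allclose(fit.translation, true.translation, atol=1e-9)

    def test_single_pair_raises(self):
        with pytest.raises(EstimationError):
            reg.procrustes_rigid(np.ones((1, 2)), np.ones((1, 2)))


class TestEstimateRigid:
    def test_oracle_equivalence_outlier_free(self, rng):
        """With no outliers the RANSAC result equals the global Procrustes fit."""
        a, b, _ = make_pairs(rng)
        a_n = a + rng.normal(0, 0.1, a.shape)
        ransac, mask = reg.estimate_rigid(a_n, b, seed=1)
        direct = reg.procrustes_rigid(a_n, b)
        assert mask.all()
        assert ransac.theta_deg == pytest.approx(direct.theta_deg, abs=1e-9)
        assert np.allclose(ransac.translation, direct.translation, atol=1e-9)

    def test_robust_to_gross_outliers(self, rng):
        a, b, true = make_pairs(rng, n=50)
        n_out = 10  # 20% gross outliers
        b_corrupt = b.copy()
        b_corrupt[:n_out] += rng.uniform(10, 40, size=(n_out, 2))
        fit, mask = reg.estimate_rigid(a, b_corrupt, seed=2)
        assert fit.theta_deg == pytest.approx(true.theta_deg, abs=0.01)
        assert np.allclose(fit.translation, true.translation, atol=0.05)
        assert mask[:n_out].sum() == 0

    def test_identical_points_give_identity(self, rng):
        pts = rng.uniform(0, 100, size=(30, 2))
        fit, _ = reg.estimate_rigid(pts, pts, seed=0)
        assert fit.theta_deg == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fit.translation, 0.0, atol=1e-12)

    def test_one_pair_raises(self):
        with pytest.raises(EstimationError):
            reg.estimate_rigid(np.ones((1, 2)), np.ones((1, 2)))


class TestDetectAndMatch:
    def test_identical_images_many_zero_displacement_matches(self, scene):
        img = syn.render_capture(scene, 0.0, syn.CaptureConfig())
        pa, pb = reg.detect_and_match(img, img)
        assert len(pa) >= 20
        assert np.linalg.norm(pa - pb, axis=1).max() < 1e-9

    def test_rotated_pair_consistent_with_rigid_motion(self, scene, sensor_center):
        cap = syn.CaptureConfig()
        f0 = syn.render_capture(scene, 0.0, cap)
        f9 = syn.render_capture(scene, 9.0, cap)
        pa, pb = reg.detect_and_match(f9, f0)
        fit, mask = reg.estimate_rigid(pa, pb, seed=0)
        assert mask.sum() >= 10
        assert fit.recenter(sensor_center).theta_deg == pytest.approx(9.0, abs=0.3)

    def test_uniform_image_no_matches(self):
        img = np.full((64, 64), 1000, dtype=np.uint16)
        pa, pb = reg.detect_and_match(img, img)
        assert len(pa) == 0


class TestApplyRigid:
    def test_identity_is_bit_identical(self, rng):
        img = rng.integers(0, 65535, size=(40, 40)).astype(np.uint16)
        out, valid = reg.apply_rigid(img, reg.RigidTransform.identity())
        assert np.array_equal(out, img)
        assert valid.all()

    def test_rotation_round_trip(self, scene):
        img = syn.render_capture(scene, 0.0, syn.CaptureConfig()).astype(float)
        c = ((img.shape[0] - 1) / 2,) * 2
        fwd = reg.RigidTransform(25.0, 0.0, 0.0, c)
        once, _ = reg.apply_rigid(img, fwd)
        back, valid = reg.apply_rigid(once, fwd.inverse())
        interior = np.zeros_like(valid)
        interior[25:-25, 25:-25] = True
        err = np.abs(back - img)[interior]
        assert err.max() < 0.01 * 65535

    def test_halfpixel_shift_on_linear_ramp(self):
        ramp = np.tile(np.arange(64, dtype=float) * 10.0, (64, 1))
        t = reg.RigidTransform(0.0, 0.0, 0.5)  # shift content +0.5 col
        out, valid = reg.apply_rigid(ramp, t)
        inner = out[10:-10, 10:-10]
        expect = ramp[10:-10, 10:-10] - 5.0  # sampled half a step earlier
        assert np.allclose(inner, expect, atol=1e-6)

    def test_nonfinite_transform_rejected(self):
        with pytest.raises(ValueError):
            reg.RigidTransform(np.nan, 0.0, 0.0)

    def test_mean_intensity_conserved_for_rotation(self, scene):
        # a central disk maps onto itself under rotation about the center,
        # so its mean is conserved up to interpolation error
        img = syn.render_capture(scene, 0.0, syn.CaptureConfig()).astype(float)
        n = img.shape[0]
        c = ((n - 1) / 2,) * 2
        out, _ = reg.apply_rigid(img, reg.RigidTransform(10.0, 0.0, 0.0, c))
        rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        disk = np.hypot(rr - c[0], cc - c[1]) < 30.0
        rel = abs(out[disk].mean() - img[disk].mean()) / img[disk].mean()
        assert rel < 1e-3


class TestMetrics:
    @pytest.mark.parametrize(
        "field_mm, px, expected", [(2.5, 100, 25.0), (1.0, 100, 10.0), (2.5, 50, 50.0)]
    )
    def test_pixel_pitch(self, field_mm, px, expected):
        assert reg.pixel_pitch(field_mm, px) == pytest.approx(expected)

    def test_pixel_pitch_invalid(self):
        with pytest.raises(ValueError):
            reg.pixel_pitch(0.0, 100)

    def test_transform_errors(self):
        t = reg.RigidTransform(0.5, 1.0, 0.0)
        trans, rot = reg.transform_errors(t, 25.0)
        assert trans == pytest.approx(25.0)
        assert rot == pytest.approx(30.0)
        assert reg.transform_errors(reg.RigidTransform.identity(), 25.0) == (0.0, 0.0)
        with pytest.raises(ValueError):
            reg.transform_errors(t, 0.0)

    def test_biased_area_edge(self):
        assert reg.biased_area_fraction(1.0, 25.0, "edge") == pytest.approx(0.04)

    def test_biased_area_diagonal(self):
        frac = reg.biased_area_fraction(1.0, 25.0, "diagonal")
        assert round(frac * 100, 1) == 5.6

    def test_biased_area_zero_and_bounds(self):
        assert reg.biased_area_fraction(0.0, 25.0, "edge") == 0.0
        assert reg.biased_area_fraction(0.0, 25.0, "diagonal") == 0.0
        with pytest.raises(ValueError):
            reg.biased_area_fraction(26.0, 25.0)

    def test_intensity_variation(self):
        ref = np.full((10, 10), 10000.0)
        _, frac = reg.intensity_variation(ref, ref)
        assert frac == 1.0
        _, frac = reg.intensity_variation(ref + 0.003 * 65535, ref)
        assert frac == 0.0
        _, frac = reg.intensity_variation(ref + 0.0025 * 65535, ref)
        assert frac == 1.0  # inclusive bound
        with pytest.raises(ValueError):
            reg.intensity_variation(ref, ref[:5])


@pytest.fixture(scope="module")
def ecc_lut(scene):
    cap = syn.CaptureConfig(ecc_um=(50.0, 0.0))
    ref = syn.render_capture(scene, 0.0, cap)
    angles = np.linspace(9.0, 345.0, 8)
    captures = [(float(a), syn.render_capture(scene, float(a), cap)) for a in angles]
    return reg.calibrate_lut(captures, ref, seed=0)


class TestLut:
    def test_translations_follow_chord(self, ecc_lut, scene):
        for (theta, tr, tc), ang in zip(ecc_lut.params, ecc_lut.angles_deg):
            if ang == 0.0:
                continue
            chord = 2 * 50.0 * np.sin(np.radians(ang) / 2)
            assert np.hypot(tr, tc) * scene.pitch_um == pytest.approx(chord, abs=2.0)

    def test_eccentricity_recovered_within_2um(self, ecc_lut, scene):
        e_um = reg.fit_eccentricity(ecc_lut) * scene.pitch_um
        assert np.linalg.norm(e_um - np.array([50.0, 0.0])) < 2.0

    def test_theta_matches_motor_angle_without_eccentricity(self, scene):
        cap = syn.CaptureConfig()
        ref = syn.render_capture(scene, 0.0, cap)
        angles = [40.0, 160.0, 280.0]
        captures = [(a, syn.render_capture(scene, a, cap)) for a in angles]
        lut = reg.calibrate_lut(captures, ref, seed=0)
        for (theta, tr, tc), ang in zip(lut.params, lut.angles_deg):
            if ang == 0.0:
                continue
            assert theta == pytest.approx(ang, abs=0.05)
            assert np.hypot(tr, tc) * scene.pitch_um < 2.0

    def test_query_at_stored_angle_exact(self, ecc_lut):
        a = ecc_lut.angles_deg[3]
        t = reg.lut_offsets(ecc_lut, a)
        assert (t.theta_deg, t.tr_px, t.tc_px) == tuple(ecc_lut.params[3])

    def test_query_at_oref_is_identity(self, ecc_lut):
        t = reg.lut_offsets(ecc_lut, 0.0)
        assert (t.theta_deg, t.tr_px, t.tc_px) == (0.0, 0.0, 0.0)

    def test_midpoint_interpolation(self):
        lut = reg.RegistrationLUT(
            angles_deg=np.array([10.0, 30.0]),
            params=np.array([[10.0, 1.0, 0.0], [30.0, 3.0, 4.0]]),
            center_px=(49.5, 49.5),
        )
        t = reg.lut_offsets(lut, 20.0)
        assert (t.theta_deg, t.tr_px, t.tc_px) == (20.0, 2.0, 2.0)

    def test_wraparound_interpolation(self):
        lut = reg.RegistrationLUT(
            angles_deg=np.array([15.0, 345.0]),
            params=np.array([[15.0, 1.0, 1.0], [345.0, 3.0, 3.0]]),
            center_px=(49.5, 49.5),
        )
        t = reg.lut_offsets(lut, 350.0)  # 1/6 of the way from 345 to 375
        assert t.theta_deg == pytest.approx(350.0)
        assert t.tr_px == pytest.approx(3.0 + (1.0 + 360.0 - 360.0 - 3.0) / 6, abs=1e-9)

    def test_empty_lut_rejected(self):
        with pytest.raises(ValueError):
            reg.RegistrationLUT(
                angles_deg=np.array([]), params=np.empty((0, 3)), center_px=(0, 0)
            )

    def test_too_few_calibration_angles(self, scene):
        ref = syn.render_capture(scene, 0.0, syn.CaptureConfig())
        with pytest.raises(CalibrationError):
            reg.calibrate_lut([(9.0, ref)], ref)


class TestCharacterization:
    def test_ideal_system_near_zero_errors(self, scene):
        from fibrojoint import joint as jm

        cap = syn.CaptureConfig()  # no noise, no eccentricity
        cfg = jm.MotorConfig(backlash_usteps=0)
        rep = reg.simulate_characterization(
            scene, cap, cfg, "NM", n_images=3, seed=0, hr_jitter_deg=0.0, hr_jitter_um=0.0
        )
        assert rep.median_translation_um < 0.05
        assert rep.median_rotation_arcmin < 0.05

    def test_fixed_seed_reproducible(self, scene):
        from fibrojoint import joint as jm

        cap = syn.CaptureConfig(ecc_um=(30.0, 40.0), noise_sd_counts=80.0)
        cfg = jm.MotorConfig(backlash_usteps=5)
        r1 = reg.simulate_characterization(scene, cap, cfg, "HR", n_images=3, seed=9)
        r2 = reg.simulate_characterization(scene, cap, cfg, "HR", n_images=3, seed=9)
        assert r1.translation_err_um == r2.translation_err_um
        assert r1.frac_within_quarter_pct == r2.frac_within_quarter_pct
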