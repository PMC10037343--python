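"""VSD chain: dF/F, bleach fit/correction, FFT notch, smoothing, end-to-end."""

import numpy as np
import pytest

from fibrojoint import synthetic as syn
from fibrojoint import vsd
from fibrojoint.errors import ConfigurationError


def seq_from(frames, dt_ms=2.0, preexposure_s=0.0, units="dff"):
    return vsd.FluorescenceSequence(
        frames=np.asarray(frames, dtype=float),
        dt_ms=dt_ms,
        preexposure_s=preexposure_s,
        units=units,
    )


class TestComputeDff:
    def test_constant_sequence_all_zero(self):
        seq = seq_from(np.full((10, 4, 4), 500.0), units="counts")
        out = vsd.compute_dff(seq, ref_frame=2)
        assert np.allclose(out.frames, 0.0)

    def test_one_percent_increase(self):
        frames = np.full((10, 4, 4), 1000.0)
        frames[7] = 1010.0
        out = vsd.compute_dff(seq_from(frames, units="counts"), ref_frame=2)
        assert np.allclose(out.frames[7], 0.01)

    def test_zero_baseline_flagged_invalid(self):
        frames = np.full((10, 4, 4), 1000.0)
        frames[:, 0, 0] = 0.0
        out = vsd.compute_dff(seq_from(frames, units="counts"), ref_frame=2)
        assert not out.valid[0, 0]
        assert np.all(np.isfinite(out.frames))

    @pytest.mark.parametrize("ref", [0, 9])
    def test_window_out_of_range(self, ref):
        seq = seq_from(np.ones((10, 4, 4)), units="counts")
        with pytest.raises(ValueError):
            vsd.compute_dff(seq, ref_frame=ref)


class TestFitBleach:
    def test_exact_quadratic_recovered(self):
        a, b, c = 0.004, -0.09, 0.02
        t = 1.5 + np.arange(400) * 0.002
        trace = a * t**2 + b * t + c
        frames = np.tile(trace[:, None, None], (1, 4, 4))
        fit = vsd.fit_bleach(seq_from(frames, preexposure_s=1.5))
        assert np.allclose(fit.poly, (a, b, c), rtol=1e-6, atol=1e-9)

    def test_flat_trace_near_zero_coefficients(self):
        fit = vsd.fit_bleach(seq_from(np.full((200, 4, 4), 0.3)))
        assert abs(fit.poly[0]) < 1e-9 and abs(fit.poly[1]) < 1e-9

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            vsd.fit_bleach(seq_from(np.ones((5, 4, 4))))


class TestCorrectBleach:
    def test_pure_bleach_flattened(self):
        t = 2.0 + np.arange(512) * 0.002
        trace = 0.005 * t**2 - 0.1 * t + 0.15
        frames = np.tile(trace[:, None, None], (1, 4, 4))
        seq = seq_from(frames, preexposure_s=2.0)
        corrected = vsd.correct_bleach(seq, vsd.fit_bleach(seq))
        resid = corrected.roi_trace()
        uncorrected_range = trace.max() - trace.min()
        assert np.sqrt((resid**2).mean()) < 0.05 * uncorrected_range

    def test_wave_amplitude_preserved(self):
        t = 2.0 + np.arange(512) * 0.002
        bleach = 0.005 * t**2 - 0.1 * t
        wave = -0.005 * np.exp(-((np.arange(512) - 200) ** 2) / (2 * 15.0**2))
        frames = np.tile((bleach + wave)[:, None, None], (1, 4, 4))
        seq = seq_from(frames, preexposure_s=2.0)
        corrected = vsd.correct_bleach(seq, vsd.fit_bleach(seq))
        resid = corrected.roi_trace()
        resid = resid - np.median(resid)
        assert resid.min() == pytest.approx(-0.005, rel=0.10)

    def test_zero_fit_is_identity(self):
        seq = seq_from(np.random.default_rng(0).normal(size=(20, 4, 4)))
        fit = vsd.BleachFit(
            poly=(0.0, 0.0, 0.0), cutoff_hz=2.5, order=4, roi_trace=np.zeros(20)
        )
        out = vsd.correct_bleach(seq, fit)
        assert np.array_equal(out.frames, seq.frames)

    def test_length_mismatch_raises(self):
        seq = seq_from(np.ones((20, 4, 4)))
        fit = vsd.BleachFit(poly=(0, 0, 0), cutoff_hz=2.5, order=4, roi_trace=np.zeros(10))
        with pytest.raises(ValueError):
            vsd.correct_bleach(seq, fit)


class TestBleachVsPreexposure:
    @staticmethod
    def fit_with_a(a, tpre):
        return vsd.BleachFit(
            poly=(a, 0.0, 0.0),
            cutoff_hz=2.5,
            order=4,
            roi_trace=np.zeros(10),
            preexposure_s=tpre,
        )

    def test_recovers_log_linear_model(self):
        c = (-0.08, -0.5, -1.2)  # ln a = c2 + c1 t + c0 t^2
        tpre = np.linspace(0.5, 5.0, 12)
        fits = [self.fit_with_a(np.exp(np.polyval(c, t)), t) for t in tpre]
        regression = vsd.bleach_vs_preexposure(fits)
        assert np.allclose(regression.coeffs, c, atol=1e-3)
        band = regression.confidence_band(tpre)
        assert np.all(band >= 0)

    def test_identical_preexposures_rejected(self):
        fits = [self.fit_with_a(0.01, 2.0) for _ in range(5)]
        with pytest.raises(ValueError):
            vsd.bleach_vs_preexposure(fits)

    def test_two_trials_rejected(self):
        fits = [self.fit_with_a(0.01, t) for t in (1.0, 2.0)]
        with pytest.raises(ValueError):
            vsd.bleach_vs_preexposure(fits)

    def test_nonpositive_a_excluded_with_warning(self):
        tpre = [1.0, 2.0, 3.0, 4.0]
        fits = [self.fit_with_a(a, t) for a, t in zip([0.01, -0.01, 0.02, 0.03], tpre)]
        with pytest.warns(UserWarning):
            regression = vsd.bleach_vs_preexposure(fits)
        assert len(regression.preexposure_s) == 3


class TestRemovePatternedNoise:
    def test_injected_sinusoid_nulled_others_untouched(self, rng):
        h = w = 64
        fy, fx = 5 / h, 9 / w
        rows = np.arange(h)[:, None]
        cols = np.arange(w)[None, :]
        clean = rng.normal(size=(3, h, w))
        pattern = 0.5 * np.sin(2 * np.pi * (fy * rows + fx * cols) + 0.3)
        seq = seq_from(clean + pattern)
        out = vsd.remove_patterned_noise(seq, vsd.NoiseMask(((fy, fx),)))
        spec_in = np.fft.fft2(seq.frames, axes=(1, 2))
        spec_out = np.fft.fft2(out.frames, axes=(1, 2))
        assert np.abs(spec_out[:, 5, 9]).max() < 1e-10 * np.abs(spec_in[:, 5, 9]).max()
        assert np.abs(spec_out[:, (h - 5), (w - 9)]).max() < 1e-8
        mask = np.ones((h, w), dtype=bool)
        mask[5, 9] = mask[h - 5, w - 9] = False
        assert np.allclose(spec_out[:, mask], spec_in[:, mask], atol=1e-8)

    def test_empty_mask_identity(self, rng):
        seq = seq_from(rng.normal(size=(2, 16, 16)))
        out = vsd.remove_patterned_noise(seq, vsd.NoiseMask())
        assert np.array_equal(out.frames, seq.frames)

    def test_absent_bin_leaves_signal(self, rng):
        seq = seq_from(rng.normal(size=(2, 32, 32)))
        out = vsd.remove_patterned_noise(seq, vsd.NoiseMask(((15 / 32, 15 / 32),)))
        # only the (low-energy) masked bin changes
        assert np.allclose(out.frames, seq.frames, atol=0.5)
        assert out.frames.dtype.kind == "f"

    def test_dc_mask_rejected(self):
        with pytest.raises(ConfigurationError):
            vsd.NoiseMask(((0.0, 0.0),))

    def test_parseval_energy_drop_equals_masked_energy(self, rng):
        seq = seq_from(rng.normal(size=(2, 32, 32)))
        mask = vsd.NoiseMask(((4 / 32, 7 / 32),))
        iy, ix = mask.to_indices((32, 32))
        spec = np.fft.fft2(seq.frames, axes=(1, 2))
        masked_energy = (np.abs(spec[:, iy, ix]) ** 2).sum() / (32 * 32)
        out = vsd.remove_patterned_noise(seq, mask)
        e_in = (seq.frames**2).sum()
        e_out = (out.frames**2).sum()
        assert e_in - e_out == pytest.approx(masked_energy, rel=1e-9)

    def test_linearity(self, rng):
        a = seq_from(rng.normal(size=(2, 16, 16)))
        b = seq_from(rng.normal(size=(2, 16, 16)))
        mask = vsd.NoiseMask(((3 / 16, 2 / 16),))
        both = vsd.remove_patterned_noise(seq_from(a.frames + b.frames), mask)
        sep = vsd.remove_patterned_noise(a, mask).frames + vsd.remove_patterned_noise(
            b, mask
        ).frames
        assert np.allclose(both.frames, sep, atol=1e-12)


class TestSpatialSmooth:
    def test_constant_unchanged(self):
        seq = seq_from(np.full((2, 16, 16), 1.5))
        out = vsd.spatial_smooth(seq)
        assert np.allclose(out.frames, 1.5)

    def test_impulse_gives_normalized_kernel(self):
        frames = np.zeros((1, 17, 17))
        frames[0, 8, 8] = 1.0
        out = vsd.spatial_smooth(seq_from(frames), kernel_px=5, sigma_px=1.0)
        k = vsd.gaussian_kernel(5, 1.0)
        assert np.allclose(out.frames[0, 6:11, 6:11], k, atol=1e-12)
        assert out.frames.sum() == pytest.approx(1.0)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            vsd.spatial_smooth(seq_from(np.ones((1, 8, 8))), kernel_px=4)


class TestEndToEnd:
    def test_wave_recovered_through_full_pipeline(self, scene):
        """dF/F -> bleach correction -> FFT notch -> smoothing recovers the
        embedded depolarization wave's peak frame exactly and its amplitude
        within 15%."""
        moire = (0.23, 0.31, 0.7, 0.004)
        cfg = syn.VsdSimConfig(
            n_frames=512,
            dt_ms=2.0,
            wave=(150, (50.0, 50.0), 1.5, -0.005, 8.0),
            noise_sd=0.002,
            moire=moire,
            rng_seed=5,
        )
        seq16, truth = syn.make_vsd_sequence(scene, cfg)
        fs = vsd.FluorescenceSequence(
            frames=seq16.frames, dt_ms=cfg.dt_ms, preexposure_s=cfg.preexposure_s
        )
        dff = vsd.compute_dff(fs, ref_frame=5)
        corrected = vsd.correct_bleach(dff, vsd.fit_bleach(dff))
        cleaned = vsd.remove_patterned_noise(
            corrected, vsd.NoiseMask(((moire[1], moire[0]),))
        )
        smoothed = vsd.spatial_smooth(cleaned)

        roi = np.zeros((scene.sensor_px,) * 2, dtype=bool)
        roi[40:60, 40:60] = True
        # dF/F is normalized to the reference frame's baseline, so the
        # ground-truth wave (fraction of shutter-open fluorescence) is
        # rescaled by the bleach level at the reference window
        scale = 1.0 + truth["bleach"][4:7].mean()
        gt = truth["wave"][:, roi].mean(axis=1) / scale
        est = smoothed.frames[:, roi].mean(axis=1)
        assert est.argmin() == gt.argmin()
        assert est.min() == pytest.approx(gt.min(), rel=0.15)
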