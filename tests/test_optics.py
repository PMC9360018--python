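"""DPC forward model, transfer functions, Tikhonov inversion, calibration."""

import numpy as np
import pytest

from qpiscreen import (
    DPCFrameSet,
    OpticalConfig,
    PhaseImage,
    bead_phantom,
    build_phase_transfer_function,
    calibrate_with_beads,
    check_led_alignment,
    compute_phase_gradient,
    reconstruct_frameset,
    simulate_dpc_frames,
    tikhonov_reconstruct,
)

SHAPE = (128, 128)


def _uniform_frames(top=1.0, bottom=1.0, left=1.0, right=1.0, shape=SHAPE):
    return DPCFrameSet(
        top=np.full(shape, top), bottom=np.full(shape, bottom),
        left=np.full(shape, left), right=np.full(shape, right),
    )


class TestConfig:
    def test_coherence_sigma_from_apertures(self, config):
        assert config.coherence_sigma == pytest.approx(0.39 / 0.25)

    @pytest.mark.parametrize(
        "kwargs", [dict(wavelength_um=-1), dict(na_objective=0.5, na_illumination=0.39),
                   dict(regularization_beta=0.0), dict(pixel_size_um=0.0)]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            OpticalConfig(**kwargs)


class TestLedAlignment:
    def test_identical_frames_aligned(self):
        rep = check_led_alignment(_uniform_frames())
        assert rep.aligned
        assert all(d == 0 for d in rep.deviations.values())

    def test_scaled_top_flagged(self):
        rep = check_led_alignment(_uniform_frames(top=1.2))
        # (1.2 - 1.05)/1.05 relative to the grand mean
        assert rep.deviations["top"] == pytest.approx(0.15 / 1.05)
        assert not rep.aligned

    def test_within_five_percent_passes(self):
        rep = check_led_alignment(_uniform_frames(top=1.04, bottom=0.98))
        assert rep.aligned

    def test_zero_intensity_frame_invalid(self):
        with pytest.raises(ValueError, match="invalid acquisition"):
            check_led_alignment(_uniform_frames(top=0.0))


class TestPhaseGradient:
    def test_equal_frames_zero(self):
        g = compute_phase_gradient(np.ones(SHAPE), np.ones(SHAPE))
        assert np.all(g == 0)

    def test_three_one_gives_half(self):
        g = compute_phase_gradient(np.full(SHAPE, 3.0), np.full(SHAPE, 1.0))
        assert np.allclose(g, 0.5)

    def test_bounded(self, rng):
        g = compute_phase_gradient(rng.random(SHAPE), rng.random(SHAPE) + 1e-6)
        assert g.min() >= -1 and g.max() <= 1

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            compute_phase_gradient(np.ones((4, 4)), np.ones((5, 5)))

    def test_forward_model_gradient_like_signal(self, config):
        # the DPC signal acts like a derivative along the axis: an even
        # (cosine) phase profile yields an odd (sine-like) pair difference
        yy = np.indices(SHAPE)[0].astype(float)
        phant = 0.1 * np.cos(2 * np.pi * 4 * yy / SHAPE[0])
        frames = simulate_dpc_frames(PhaseImage(phant, config.pixel_size_um), config)
        g = compute_phase_gradient(frames.top, frames.bottom)
        assert np.abs(g).max() > 0
        idx = (-np.arange(SHAPE[0])) % SHAPE[0]
        assert np.allclose(g, -g[np.ix_(idx, (-np.arange(SHAPE[1])) % SHAPE[1])], atol=1e-9)


class TestTransferFunction:
    @pytest.mark.parametrize("axis", [90, 180])
    def test_zero_at_dc_imaginary_antisymmetric(self, config, axis):
        H = build_phase_transfer_function(config, axis, SHAPE)
        assert H[0, 0] == 0
        assert np.abs(H.real).max() == 0
        idx = (-np.arange(SHAPE[0])) % SHAPE[0]
        assert np.abs(H + H[np.ix_(idx, idx)]).max() < 1e-12

    def test_zero_beyond_cutoff(self, config):
        H = build_phase_transfer_function(config, 90, SHAPE)
        fy = np.fft.fftfreq(SHAPE[0], d=config.pixel_size_um)
        fx = np.fft.fftfreq(SHAPE[1], d=config.pixel_size_um)
        UY, UX = np.meshgrid(fy, fx, indexing="ij")
        beyond = np.sqrt(UX**2 + UY**2) > config.cutoff_frequency
        assert np.abs(H[beyond]).max() == 0

    def test_unsupported_axis(self, config):
        with pytest.raises(ValueError, match="unsupported DPC axis"):
            build_phase_transfer_function(config, 45, SHAPE)


class TestTikhonov:
    def test_zero_gradients_zero_phase(self, config):
        H = build_phase_transfer_function(config, 90, SHAPE)
        phi = tikhonov_reconstruct([np.zeros(SHAPE)], [H])
        assert np.all(phi.phase == 0)

    def test_round_trip_bandpass(self, config, bandpass_phantom):
        pm = PhaseImage(bandpass_phantom, config.pixel_size_um)
        rec = reconstruct_frameset(simulate_dpc_frames(pm, config), config)
        err = np.linalg.norm(rec.phase - bandpass_phantom) / np.linalg.norm(bandpass_phantom)
        assert err < 0.05
        corr = np.corrcoef(rec.phase.ravel(), bandpass_phantom.ravel())[0, 1]
        assert corr > 0.99

    def test_linearity(self, config, bandpass_phantom):
        pm1 = PhaseImage(bandpass_phantom, config.pixel_size_um)
        pm2 = PhaseImage(0.5 * bandpass_phantom, config.pixel_size_um)
        r1 = reconstruct_frameset(simulate_dpc_frames(pm1, config), config)
        r2 = reconstruct_frameset(simulate_dpc_frames(pm2, config), config)
        assert np.allclose(r2.phase, 0.5 * r1.phase, atol=1e-9)

    def test_monotone_damping_in_beta(self, config, bandpass_phantom):
        pm = PhaseImage(bandpass_phantom, config.pixel_size_um)
        frames = simulate_dpc_frames(pm, config)
        grads = [compute_phase_gradient(*frames.pair(a)) for a in (90, 180)]
        tfs = [build_phase_transfer_function(config, a, SHAPE) for a in (90, 180)]
        lo = tikhonov_reconstruct(grads, tfs, beta=1e-3)
        hi = tikhonov_reconstruct(grads, tfs, beta=2e-3)
        amp_lo = np.abs(np.fft.fft2(lo.phase))
        amp_hi = np.abs(np.fft.fft2(hi.phase))
        assert np.all(amp_hi <= amp_lo + 1e-9)

    def test_beta_must_be_positive(self, config):
        H = build_phase_transfer_function(config, 90, SHAPE)
        with pytest.raises(ValueError):
            tikhonov_reconstruct([np.zeros(SHAPE)], [H], beta=0.0)


class TestSimulate:
    def test_zero_phantom_uniform_frames(self, config):
        pm = PhaseImage(np.zeros(SHAPE), config.pixel_size_um)
        fr = simulate_dpc_frames(pm, config)
        for name in ("top", "bottom", "left", "right"):
            assert np.allclose(getattr(fr, name), 1.0)

    def test_deterministic_per_seed(self, config, bandpass_phantom):
        pm = PhaseImage(bandpass_phantom, config.pixel_size_um)
        a = simulate_dpc_frames(pm, config, noise_level=0.01, seed=3)
        b = simulate_dpc_frames(pm, config, noise_level=0.01, seed=3)
        assert np.array_equal(a.top, b.top) and np.array_equal(a.right, b.right)

    def test_vertical_gradient_separates_top_bottom(self, config):
        yy = np.indices(SHAPE)[0].astype(float)
        pm = PhaseImage(0.002 * (yy - yy.mean()), config.pixel_size_um)
        fr = simulate_dpc_frames(pm, config)
        assert np.abs(fr.top - fr.bottom).max() > 1e-4
        assert np.abs(fr.left - fr.right).max() < np.abs(fr.top - fr.bottom).max() / 10


class TestBeadCalibration:
    def test_zero_phase_gives_medium_index(self, config):
        pm = PhaseImage(np.zeros((64, 64)), config.pixel_size_um)
        res = calibrate_with_beads(pm, [(32, 32)], radius_um=3.0, medium_index=1.56)
        assert res.mean_refractive_index == pytest.approx(1.56)

    def test_phantom_integration_exact(self, config):
        # on the noiseless phantom itself the integral recovers the index
        pm = bead_phantom((128, 128), [(64, 64)], radius_um=5.0)
        res = calibrate_with_beads(pm, [(64, 64)], radius_um=5.0)
        assert res.mean_refractive_index == pytest.approx(1.583, abs=2e-4)

    def test_reconstructed_beads_within_tenth_percent(self, config):
        centers = [(64, 64), (128, 190), (200, 100)]
        pm = bead_phantom((256, 256), centers, radius_um=5.0)
        rec = reconstruct_frameset(simulate_dpc_frames(pm, config), config)
        res = calibrate_with_beads(rec, centers, radius_um=5.0)
        assert abs(res.mean_refractive_index - 1.583) / 1.583 < 1e-3

    def test_temporal_cv_matches_sample(self, config):
        centers = [(40, 40)]
        rng = np.random.default_rng(0)
        base = bead_phantom((96, 96), centers, radius_um=3.0)
        images = [
            PhaseImage(base.phase * (1 + 0.02 * rng.standard_normal()), base.pixel_size_um)
            for _ in range(30)
        ]
        res = calibrate_with_beads(images, centers, radius_um=3.0)
        assert res.temporal_cv is not None and res.temporal_cv > 0

    def test_border_bead_excluded(self, config):
        pm = bead_phantom((96, 96), [(2, 2), (48, 48)], radius_um=3.0)
        with pytest.warns(UserWarning, match="border"):
            res = calibrate_with_beads(pm, [(2, 2), (48, 48)], radius_um=3.0)
        assert len(res.per_bead_indices) == 1

    def test_zero_radius_rejected(self, config):
        pm = PhaseImage(np.zeros((32, 32)), config.pixel_size_um)
        with pytest.raises(ValueError, match="volume"):
            calibrate_with_beads(pm, [(16, 16)], radius_um=0.0)
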