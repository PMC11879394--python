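"""Phantoms, illumination patterns, forward model and noise injection."""

import math

import numpy as np
import pytest

from mcism import (
    PinholeArrayGeometry,
    ScanTrajectory,
    add_noise_to_snr,
    forward_model,
    gaussian_psf_from_config,
    illumination_pattern,
    illumination_stack,
    make_phantom,
    scan_preset,
    simulate_stack,
    tilt_for_uniform_coverage,
)
from mcism.simulate import PhantomError


class TestPhantoms:
    def test_line_pair_spacing_in_pixels(self, cfg):
        ph = make_phantom("line_pairs", {"spacing_nm": 140.0}, (32, 32), 32.5)
        cols = ph.image.sum(axis=0)
        centroids = []
        for half in (cols[: len(cols) // 2], cols[len(cols) // 2 :]):
            x = np.arange(len(half), dtype=float)
            centroids.append(np.sum(x * half) / half.sum())
        sep = centroids[1] + len(cols) // 2 - centroids[0]
        assert sep == pytest.approx(140.0 / 32.5, abs=0.01)  # 4.31 px
        # each line carries unit intensity per row
        assert ph.image.sum() == pytest.approx(2 * 32, rel=1e-9)

    def test_subpixel_line_spacing_rejected(self):
        with pytest.raises(PhantomError):
            make_phantom("line_pairs", {"spacing_nm": 20.0}, (32, 32), 32.5)

    def test_plate_constant(self):
        ph = make_phantom("plate", {"intensity": 2.5}, (16, 16), 32.5)
        assert np.all(ph.image == 2.5)

    def test_beads_deterministic_under_seed(self):
        a = make_phantom("beads", {"n": 10, "seed": 1}, (64, 64), 32.5)
        b = make_phantom("beads", {"n": 10, "seed": 1}, (64, 64), 32.5)
        assert np.array_equal(a.image, b.image)
        c = make_phantom("beads", {"n": 10, "seed": 2}, (64, 64), 32.5)
        assert not np.array_equal(a.image, c.image)

    def test_unknown_kind(self):
        with pytest.raises(PhantomError):
            make_phantom("squares", {}, (16, 16), 32.5)

    def test_sphere_shell_radius(self):
        ph = make_phantom("sphere_shell", {"radius_nm": 300.0}, (64, 64), 32.5)
        rr, cc = np.nonzero(ph.image > 0.5)
        dist = np.hypot(rr - 31.5, cc - 31.5) * 32.5
        assert dist.mean() == pytest.approx(300.0, abs=32.5)


class TestIlluminationPatterns:
    def test_point_pinhole_pattern_equals_excitation_kernel(self, cfg, psf_ex):
        """In the vanishing-diameter limit a single pinhole's pattern is the
        excitation PSF itself."""
        geom = PinholeArrayGeometry(pitch_nm=5000.0, diameter_nm=0.0, tilt_deg=8.0)
        traj = ScanTrajectory(n_frames=1, step_nm=0.0)
        pat = illumination_pattern(geom, traj, psf_ex, 0, (33, 33), cfg.pixel_nm)
        kern = psf_ex.kernel() / psf_ex.kernel().max()
        r = kern.shape[0] // 2
        inner = pat[16 - r : 17 + r, 16 - r : 17 + r]
        assert np.allclose(inner, kern, atol=1e-6)

    def test_frames_are_step_translates(self, cfg, geom49, psf_ex):
        """Consecutive patterns differ by exactly the scan step."""
        step_px = 4  # choose a step of an integer number of grid pixels
        traj = ScanTrajectory(n_frames=3, step_nm=step_px * cfg.pixel_nm)
        pats = illumination_stack(geom49, traj, psf_ex, (64, 64), cfg.pixel_nm)
        # pats1(x) = pats0(x - step); compare on a common interior window
        err = np.abs(pats[1][:, step_px + 12 : -12] - pats[0][:, 12 : -12 - step_px]).max()
        assert err < 1e-6 * pats[1].max()

    def test_pattern_minima_dark_between_spots(self, cfg, geom49, traj49, patterns49):
        """0.5 AU pinholes at 1:3 pitch leave <2% of peak between spots."""
        pat = patterns49[0]
        interior = pat[16:48, 16:48]
        assert interior.min() < 0.02 * patterns49.max()

    def test_pattern_sum_uniform_for_full_preset(self, cfg, psf_ex):
        """Total excitation over a commensurate n^2-frame scan is flat."""
        au = cfg.airy_unit_nm
        geom = PinholeArrayGeometry(
            pitch_nm=1.5 * au, diameter_nm=0.5 * au, tilt_deg=tilt_for_uniform_coverage(7)
        )
        _, traj = scan_preset(7, 1.5 * au)
        pats = illumination_stack(geom, traj, psf_ex, (64, 64), cfg.pixel_nm)
        total = pats.sum(axis=0)[16:48, 16:48]
        assert total.max() / total.min() < 1.05


class TestForwardModel:
    def test_zero_phantom_gives_zero_stack(self, cfg, geom49, traj49):
        ph = make_phantom("plate", {"intensity": 0.0}, (32, 32), cfg.pixel_nm)
        stack = simulate_stack(ph, geom49, traj49, cfg)
        assert not stack.frames.any()

    def test_linearity_in_phantom(self, cfg, geom49, patterns49):
        traj = ScanTrajectory(n_frames=49, step_nm=0.25 * cfg.airy_unit_nm)
        a = make_phantom("beads", {"n": 4, "seed": 3}, (64, 64), cfg.pixel_nm)
        b = make_phantom("beads", {"n": 4, "seed": 4}, (64, 64), cfg.pixel_nm)
        combo = a.image + 2.0 * b.image
        ph = make_phantom("plate", {}, (64, 64), cfg.pixel_nm)
        ph.image = combo
        sa = simulate_stack(a, geom49, traj, cfg, patterns=patterns49).frames
        sb = simulate_stack(b, geom49, traj, cfg, patterns=patterns49).frames
        sc = simulate_stack(ph, geom49, traj, cfg, patterns=patterns49).frames
        assert np.allclose(sc, sa + 2.0 * sb, rtol=1e-9, atol=1e-12 * sc.max())

    def test_point_source_frame_matches_direct_convolution(
        self, cfg, geom49, traj49, patterns49, psf_det
    ):
        """A point emitter yields P_i(r0) times the shifted detection PSF."""
        ph = make_phantom(
            "beads", {"positions_px": [[30, 34]], "diameter_nm": 0.0}, (64, 64), cfg.pixel_nm
        )
        stack = simulate_stack(ph, geom49, traj49, cfg, patterns=patterns49)
        k = int(np.argmax(stack.frames.reshape(49, -1).max(axis=1)))
        kern = psf_det.kernel()
        expected = patterns49[k, 30, 34] * np.pad(kern, 100)[
            100 + kern.shape[0] // 2 - 30 : 164 + kern.shape[0] // 2 - 30,
            100 + kern.shape[1] // 2 - 34 : 164 + kern.shape[1] // 2 - 34,
        ]
        assert np.allclose(stack.frames[k], expected, atol=1e-9 * expected.max())

    def test_forward_model_bitwise_matches_simulator(
        self, cfg, geom49, traj49, patterns49, psf_det
    ):
        ph = make_phantom("beads", {"n": 6, "seed": 9}, (64, 64), cfg.pixel_nm)
        stack = simulate_stack(ph, geom49, traj49, cfg, patterns=patterns49)
        k = 17
        direct = forward_model(ph.image, patterns49[k], psf_det.kernel())
        assert np.array_equal(stack.frames[k], direct)

    def test_negative_background_rejected(self, cfg, geom49, traj49):
        ph = make_phantom("plate", {}, (32, 32), cfg.pixel_nm)
        with pytest.raises(ValueError):
            simulate_stack(ph, geom49, traj49, cfg, background=-1.0)

    def test_camera_binning(self, cfg, geom49, traj49, patterns49):
        ph = make_phantom("plate", {}, (64, 64), cfg.pixel_nm)
        full = simulate_stack(ph, geom49, traj49, cfg, patterns=patterns49)
        binned = simulate_stack(ph, geom49, traj49, cfg, patterns=patterns49, bin_factor=2)
        assert binned.frames.shape == (49, 32, 32)
        assert binned.pixel_nm == pytest.approx(2 * cfg.pixel_nm)
        manual = full.frames.reshape(49, 32, 2, 32, 2).mean(axis=(2, 4))
        assert np.allclose(binned.frames, manual)


class TestNoise:
    def test_gaussian_noise_hits_requested_snr(self, plate_stack49):
        noisy = add_noise_to_snr(plate_stack49, 10.0, "gaussian", seed=0)
        signal = plate_stack49.frames
        support = signal > 0.01 * signal.max()
        noise = noisy.frames - signal
        snr = 10 * np.log10(np.mean(signal[support] ** 2) / noise.var())
        assert snr == pytest.approx(10.0, abs=0.1)

    def test_seed_reproducibility(self, plate_stack49):
        a = add_noise_to_snr(plate_stack49, 10.0, "gaussian", seed=5)
        b = add_noise_to_snr(plate_stack49, 10.0, "gaussian", seed=5)
        assert np.array_equal(a.frames, b.frames)

    def test_infinite_snr_is_identity(self, plate_stack49):
        out = add_noise_to_snr(plate_stack49, math.inf, "gaussian", seed=0)
        assert np.array_equal(out.frames, plate_stack49.frames)

    def test_all_zero_stack_rejected(self, cfg, geom49, traj49):
        ph = make_phantom("plate", {"intensity": 0.0}, (16, 16), cfg.pixel_nm)
        stack = simulate_stack(ph, geom49, ScanTrajectory(n_frames=2, step_nm=100), cfg)
        with pytest.raises(ValueError):
            add_noise_to_snr(stack, 10.0, "gaussian", seed=0)

    def test_poisson_preserves_mean_in_expectation(self, cfg, geom49):
        """Photon noise is unbiased: frame means agree to 3 sigma over seeds."""
        ph = make_phantom("plate", {}, (16, 16), cfg.pixel_nm)
        traj = ScanTrajectory(n_frames=2, step_nm=100.0)
        stack = simulate_stack(ph, geom49, traj, cfg)
        true_mean = stack.frames.mean()
        means, scales = [], []
        for seed in range(100):
            noisy = add_noise_to_snr(stack, 15.0, "poisson", seed=seed)
            means.append(noisy.frames.mean())
            scales.append(noisy.meta["noise"]["photon_scale"])
        n_pix = stack.frames.size
        # var of the grand mean: sum(var(count/scale))/N^2 = mean/(scale*N)
        sem = math.sqrt(true_mean / (scales[0] * n_pix) / len(means))
        assert abs(np.mean(means) - true_mean) < 3 * sem

    def test_noise_metadata_recorded(self, plate_stack49):
        noisy = add_noise_to_snr(plate_stack49, 12.0, "mixed", seed=3)
        rec = noisy.meta["noise"]
        assert rec["kind"] == "mixed" and rec["snr_db"] == 12.0 and rec["seed"] == 3
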