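"""Digital pinholes, sub-image extraction and the 2x reassignment canvas."""

import math

import numpy as np
import pytest
from scipy.signal import fftconvolve

from mcism import (
    DigitalPinhole,
    ScanTrajectory,
    SpotGrid,
    apply_digital_pinhole,
    estimate_sigma_base,
    extract_subimages,
    make_phantom,
    marginal_fwhm,
    mcism_reconstruct,
    pr_psf_sigma_canvas_px,
    reassign_and_accumulate,
    simulate_stack,
    scan_preset,
    upsample_stack,
)
from mcism import OpticalConfig, PinholeArrayGeometry, tilt_for_uniform_coverage
from mcism.reassign import ReassignmentError, SubImage, default_window_radius, pr_pipeline
from mcism.stackio import RawStack


def _spot_frames(centers_per_frame, shape, sigma, amp=1.0):
    frames = []
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for centers in centers_per_frame:
        f = np.zeros(shape)
        for r, c in centers:
            f += amp * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma**2))
        frames.append(f)
    return np.asarray(frames)


def _grid(centers_per_frame, shape):
    return SpotGrid(
        centers=[np.asarray(c, dtype=float) for c in centers_per_frame],
        lattice=np.eye(2) * 20,
        step_px=np.array([0.0, 1.0]),
        origin_px=np.zeros(2),
        shape=shape,
    )


class TestSigmaBase:
    def test_recovers_known_spot_width(self, cfg, geom49, traj49, plate_stack49, sigma_spot_nm, psf_det):
        spots = SpotGrid.from_geometry(geom49, traj49, (64, 64), cfg.pixel_nm)
        ph = estimate_sigma_base(plate_stack49, spots, window_radius_px=10)
        expected = math.hypot(sigma_spot_nm, psf_det.sigma_lateral_nm) / cfg.pixel_nm
        assert ph.sigma_base_px == pytest.approx(expected, rel=0.03)

    def test_doubling_width_doubles_sigma_base(self):
        rng = np.random.default_rng(0)
        # well-separated spots on a loose grid with sub-pixel scatter
        base = np.array([[18.0, 18.0], [18.0, 44.0], [44.0, 18.0], [44.0, 44.0]])
        centers = [base + rng.uniform(-0.5, 0.5, size=base.shape) for _ in range(4)]
        for sigma in (2.0, 4.0):
            frames = _spot_frames(centers, (64, 64), sigma)
            ph = estimate_sigma_base(frames, _grid(centers, (64, 64)), window_radius_px=12)
            assert ph.sigma_base_px == pytest.approx(sigma, rel=0.05)

    def test_averaging_beats_single_spot_fits(self):
        """The aligned-average fit has lower spread than single-spot fits."""
        from scipy import optimize
        from mcism.reassign import _gaussian2d

        rng0 = np.random.default_rng(3)
        centers = [rng0.uniform(15, 48, size=(4, 2)) for _ in range(4)]
        avg_fits, single_fits = [], []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            frames = _spot_frames(centers, (64, 64), 3.0)
            frames += rng.normal(0, 0.1, size=frames.shape)
            ph = estimate_sigma_base(frames, _grid(centers, (64, 64)), window_radius_px=10)
            avg_fits.append(ph.sigma_base_px)
            # single-spot fit on one cut-out
            r, c = np.round(centers[0][0]).astype(int)
            cut = frames[0, r - 10 : r + 11, c - 10 : c + 11]
            rr, cc = np.mgrid[0:21, 0:21]
            popt, _ = optimize.curve_fit(
                _gaussian2d, (rr, cc), cut.ravel(), p0=(1.0, 10, 10, 3.0, 0.0), maxfev=5000
            )
            single_fits.append(abs(popt[3]))
        assert np.std(avg_fits) < np.std(single_fits)

    def test_too_few_spots_rejected(self):
        frames = _spot_frames([[(20, 20)]], (41, 41), 3.0)
        with pytest.raises(ReassignmentError):
            estimate_sigma_base(frames, _grid([[(20, 20)]], (41, 41)))


class TestSubImages:
    def test_single_spot_energy_captured(self):
        centers = [[(32.0, 32.0)]]
        frames = _spot_frames(centers, (64, 64), 3.0)
        subs = extract_subimages(frames, _grid(centers, (64, 64)), window_radius_px=12)
        assert len(subs) == 1
        assert subs[0].data.sum() > 0.99 * frames[0].sum()
        assert not subs[0].truncated

    def test_corner_spot_flagged_truncated(self):
        centers = [[(2.0, 2.0)]]
        frames = _spot_frames(centers, (64, 64), 3.0)
        subs = extract_subimages(frames, _grid(centers, (64, 64)), window_radius_px=12)
        assert subs[0].truncated

    def test_window_overlapping_neighbor_rejected(self):
        centers = [[(32.0, 20.0), (32.0, 44.0)]]
        frames = _spot_frames(centers, (64, 64), 3.0)
        with pytest.raises(ReassignmentError):
            extract_subimages(frames, _grid(centers, (64, 64)), window_radius_px=14, pitch_px=24.0)
        # radius = pitch/2 - 1 is allowed
        subs = extract_subimages(frames, _grid(centers, (64, 64)), window_radius_px=11, pitch_px=24.0)
        assert len(subs) == 2

    def test_default_radius_capped_with_warning(self):
        with pytest.warns(UserWarning):
            r = default_window_radius(sigma_base_px=10.0, pitch_px=40.0)
        assert r == 19


class TestDigitalPinhole:
    def test_infinite_pinhole_is_identity(self):
        sub = SubImage(0, np.array([10.0, 10.0]), np.ones((21, 21)))
        out = apply_digital_pinhole(sub, DigitalPinhole(math.inf, 5.0))
        assert out.data is sub.data

    def test_gaussian_times_matched_mask_narrows_by_sqrt2(self):
        sigma = 4.0
        rr, cc = np.mgrid[0:41, 0:41]
        spot = np.exp(-((rr - 20.0) ** 2 + (cc - 20.0) ** 2) / (2 * sigma**2))
        sub = SubImage(0, np.array([20.0, 20.0]), spot)
        out = apply_digital_pinhole(sub, DigitalPinhole(1.0, sigma))
        f = marginal_fwhm(out.data)
        assert f == pytest.approx(2.3548 * sigma / math.sqrt(2), rel=0.01)

    def test_mask_centered_on_subpixel_center(self):
        sub = SubImage(0, np.array([20.4, 19.7]), np.ones((41, 41)))
        out = apply_digital_pinhole(sub, DigitalPinhole(1.0, 4.0))
        peak = np.unravel_index(np.argmax(out.mask), out.mask.shape)
        assert peak == (20, 20)  # nearest pixel to the fractional centre


class TestReassignment:
    def test_point_subimage_lands_at_doubled_center(self):
        centers = [[(20.0, 24.0)]]
        frames = _spot_frames(centers, (64, 64), 2.0)
        subs = extract_subimages(frames, _grid(centers, (64, 64)), window_radius_px=9)
        pr = reassign_and_accumulate(subs, (128, 128))
        peak = np.unravel_index(np.argmax(pr.canvas), pr.canvas.shape)
        assert peak == (40, 48)

    def test_empty_subimage_list_rejected(self):
        with pytest.raises(ReassignmentError):
            reassign_and_accumulate([], (64, 64))

    def test_linearity_in_the_stack(self, cfg, geom49, traj49, patterns49):
        a = make_phantom("beads", {"n": 3, "seed": 1}, (64, 64), cfg.pixel_nm)
        b = make_phantom("beads", {"n": 3, "seed": 2}, (64, 64), cfg.pixel_nm)
        sa = simulate_stack(a, geom49, traj49, cfg, patterns=patterns49)
        sb = simulate_stack(b, geom49, traj49, cfg, patterns=patterns49)
        spots = SpotGrid.from_geometry(geom49, traj49, (64, 64), cfg.pixel_nm, upsample=2)
        pitch_px = geom49.pitch_nm * 2 / cfg.pixel_nm / 2

        def pr_canvas(frames):
            up = upsample_stack(frames, 2)
            subs = extract_subimages(up, spots, window_radius_px=11)
            return reassign_and_accumulate(subs, (256, 256)).canvas

        ca = pr_canvas(sa.frames)
        cb = pr_canvas(sb.frames)
        cab = pr_canvas(sa.frames + 2.0 * sb.frames)
        assert np.allclose(cab, ca + 2.0 * cb, atol=1e-9 * cab.max())

    def test_uniform_phantom_reconstructs_flat(self, cfg, psf_ex):
        """Weight-normalized PR of a plate stays flat in the interior for a
        dense full preset (0.8 AU pitch keeps the sampling combs below the
        spot width)."""
        au = cfg.airy_unit_nm
        geom = PinholeArrayGeometry(
            pitch_nm=0.8 * au, diameter_nm=0.25 * au, tilt_deg=tilt_for_uniform_coverage(7)
        )
        _, traj = scan_preset(7, 0.8 * au)
        plate = make_phantom("plate", {}, (64, 64), cfg.pixel_nm)
        stack = simulate_stack(plate, geom, traj, cfg)
        up = upsample_stack(stack, 2)
        spots = SpotGrid.from_geometry(geom, traj, (64, 64), cfg.pixel_nm, upsample=2)
        sig_det = 0.51 * cfg.lambda_em / cfg.na / 2.3548
        sig_spot = math.hypot(0.51 * cfg.lambda_ex / cfg.na / 2.3548, geom.diameter_nm / 4)
        pr = pr_pipeline(
            up,
            spots,
            sigma_base_px=math.hypot(sig_spot, sig_det) / up.pixel_nm,
            pitch_px=geom.pitch_nm / up.pixel_nm,
            input_pixel_nm=up.pixel_nm,
        )
        interior = pr.image[64:192, 64:192]
        assert interior.max() / interior.min() < 1.05

    def test_center_error_robustness(self, cfg, geom49, psf_det):
        """Displacing every located centre by up to 1 px leaves the PR peak
        FWHM essentially unchanged (sub-image still covers the spot)."""
        au = cfg.airy_unit_nm
        eq = OpticalConfig(lambda_ex=680, lambda_em=680, na=1.49, pixel_nm=32.5)
        geom = PinholeArrayGeometry(
            pitch_nm=1.5 * au, diameter_nm=0.0, tilt_deg=tilt_for_uniform_coverage(7)
        )
        _, traj = scan_preset(7, 1.5 * au)
        ph = make_phantom(
            "beads", {"positions_px": [[31, 31]], "diameter_nm": 0.0}, (64, 64), eq.pixel_nm
        )
        stack = simulate_stack(ph, geom, traj, eq)
        up = upsample_stack(stack, 2)
        spots = SpotGrid.from_geometry(geom, traj, (64, 64), eq.pixel_nm, upsample=2)
        sig = 0.51 * 680 / 1.49 / 2.3548
        sbase = math.hypot(sig, sig) / up.pixel_nm

        def fwhm_with(grid):
            with pytest.warns(UserWarning):
                pr = pr_pipeline(
                    up, grid, sigma_base_px=sbase,
                    pitch_px=geom.pitch_nm / up.pixel_nm, input_pixel_nm=up.pixel_nm,
                )
            return marginal_fwhm(pr.image, pr.canvas_pixel_nm)

        base = fwhm_with(spots)
        shifted = fwhm_with(spots.shifted((0.9, -0.7)))
        assert abs(shifted - base) / base < 0.01


class TestMcismReconstruct:
    def _pr(self):
        centers = [[(32.0, 32.0)]]
        frames = _spot_frames(centers, (64, 64), 3.0)
        subs = extract_subimages(frames, _grid(centers, (64, 64)), window_radius_px=12)
        return reassign_and_accumulate(subs, (128, 128))

    def test_zero_iterations_returns_pr_image(self):
        pr = self._pr()
        out = mcism_reconstruct(pr, np.ones((3, 3)) / 9.0, n_iter=0)
        assert np.array_equal(out, pr.image)

    def test_negative_iterations_rejected(self):
        with pytest.raises(ValueError):
            mcism_reconstruct(self._pr(), np.ones((3, 3)) / 9.0, n_iter=-1)

    def test_flux_conserved_through_rl(self):
        from mcism.optics import gaussian_kernel

        pr = self._pr()
        kern = gaussian_kernel(2.5, 10)
        out = mcism_reconstruct(pr, kern, n_iter=30)
        assert out.sum() == pytest.approx(pr.image.sum(), rel=1e-6)

    def test_pr_psf_sigma_helper(self):
        # equal widths: canvas sigma = sqrt(2)*sigma/pixel; sample-scale
        # width is 1/sqrt(2) of either PSF
        assert pr_psf_sigma_canvas_px(100.0, 100.0, 16.25) == pytest.approx(
            math.sqrt(2) * 100 / 16.25
        )
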