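"""Shared fixtures: the study optics/geometry and reusable simulated stacks.

Study conditions used throughout: 640/680 nm excitation/emission, NA 1.49,
32.5 nm object grid, 0.5 AU pinholes at 1:3 diameter:pitch, 0.25 AU scan
step, 49-frame (n=7) or 25-frame (n=5) tilted 1-D scans.
"""

import math

import numpy as np
import pytest

from mcism import (
    OpticalConfig,
    PinholeArrayGeometry,
    ScanTrajectory,
    frame_reduction_step_ratio,
    gaussian_psf_from_config,
    illumination_stack,
    make_phantom,
    simulate_stack,
    tilt_for_uniform_coverage,
)


@pytest.fixture(scope="session")
def cfg():
    return OpticalConfig(lambda_ex=640.0, lambda_em=680.0, na=1.49, pixel_nm=32.5)


@pytest.fixture(scope="session")
def geom49(cfg):
    au = cfg.airy_unit_nm
    return PinholeArrayGeometry(
        pitch_nm=1.5 * au, diameter_nm=0.5 * au, tilt_deg=tilt_for_uniform_coverage(7)
    )


@pytest.fixture(scope="session")
def traj49(cfg):
    return ScanTrajectory(n_frames=49, step_nm=0.25 * cfg.airy_unit_nm)


@pytest.fixture(scope="session")
def geom25(cfg):
    au = cfg.airy_unit_nm
    return PinholeArrayGeometry(
        pitch_nm=1.5 * au, diameter_nm=0.5 * au, tilt_deg=tilt_for_uniform_coverage(5)
    )


@pytest.fixture(scope="session")
def traj25(cfg):
    step = 0.25 * cfg.airy_unit_nm * frame_reduction_step_ratio(49, 25)
    return ScanTrajectory(n_frames=25, step_nm=step)


@pytest.fixture(scope="session")
def psf_ex(cfg):
    return gaussian_psf_from_config(cfg, "excitation")


@pytest.fixture(scope="session")
def psf_det(cfg):
    return gaussian_psf_from_config(cfg, "emission")


@pytest.fixture(scope="session")
def sigma_spot_nm(cfg, geom49, psf_ex):
    # illumination-spot width: pinhole disk (sigma = D/4) blurred by the
    # excitation PSF
    return math.hypot(psf_ex.sigma_lateral_nm, geom49.diameter_nm / 4.0)


@pytest.fixture(scope="session")
def patterns49(geom49, traj49, psf_ex):
    return illumination_stack(geom49, traj49, psf_ex, (64, 64), 32.5)


@pytest.fixture(scope="session")
def plate_stack49(cfg, geom49, traj49, patterns49):
    plate = make_phantom("plate", {}, (64, 64), cfg.pixel_nm)
    return simulate_stack(plate, geom49, traj49, cfg, patterns=patterns49)


@pytest.fixture(scope="session")
def linepair140_stack25(cfg, geom25, traj25, psf_ex):
    phantom = make_phantom("line_pairs", {"spacing_nm": 140.0}, (64, 64), cfg.pixel_nm)
    patterns = illumination_stack(geom25, traj25, psf_ex, (64, 64), cfg.pixel_nm)
    stack = simulate_stack(phantom, geom25, traj25, cfg, patterns=patterns)
    return phantom, patterns, stack
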