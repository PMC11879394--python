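"""Synthetic-data generator: optical forward model for multifocal scanning.

Image formation follows the standard incoherent two-step model: the object
``O`` is modulated by the per-frame illumination pattern ``P_i`` (excitation
pinhole disks convolved with the excitation PSF) and then convolved with
the detection PSF ``h``::

    I_i = h * (P_i . O)  (+ background)  (+ noise)

Out-of-focus light is modelled as a frame-independent additive component —
exactly the premise that lets optical lock-in detection remove it.
Convolutions are zero-padded (FFT overlap-free); the object grid may be
finer than the camera grid, with camera sampling by block averaging.

Default study conditions (used by the presets and tests): 640/680 nm
excitation/emission, NA 1.49, 32.5 nm object grid, 0.5 AU pinholes at a
1:3 diameter:pitch ratio, 0.25 AU scan step, 49- or 25-frame 1-D tilted
scans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .geometry import PinholeArrayGeometry, ScanTrajectory, scan_positions
from .optics import OpticalConfig, PSFModel, gaussian_psf_from_config
from .stackio import RawStack

PHANTOM_KINDS = ("line_pairs", "beads", "filaments", "plate", "sphere_shell")


class PhantomError(ValueError):
    """Raised for phantoms that cannot be rendered on the requested grid."""


@dataclass
class Phantom:
    """Nonnegative object intensity grid with its pixel size and recipe."""

    image: np.ndarray
    pixel_nm: float
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if not np.isfinite(self.image).all() or (self.image < 0).any():
            raise PhantomError("phantom must be finite and nonnegative")


def _tent_deposit(img: np.ndarray, row: float, col: float, amplitude: float = 1.0) -> None:
    """Bilinear (area-weighted) deposit of a point at sub-pixel (row, col)."""
    h, w = img.shape
    r0, c0 = int(math.floor(row)), int(math.floor(col))
    fr, fc = row - r0, col - c0
    for dr, wr in ((0, 1 - fr), (1, fr)):
        for dc, wc in ((0, 1 - fc), (1, fc)):
            r, c = r0 + dr, c0 + dc
            if 0 <= r < h and 0 <= c < w:
                img[r, c] += amplitude * wr * wc


def _vertical_line(img: np.ndarray, col: float) -> None:
    """Unit-intensity, one-pixel-wide vertical line at sub-pixel column."""
    w = img.shape[1]
    c0 = int(math.floor(col))
    fc = col - c0
    for dc, wc in ((0, 1 - fc), (1, fc)):
        c = c0 + dc
        if 0 <= c < w:
            img[:, c] += wc


def _disk(img: np.ndarray, row: float, col: float, radius_px: float, amplitude: float = 1.0) -> None:
    """Anti-aliased filled disk (edge coverage approximated linearly)."""
    h, w = img.shape
    r_lo = max(0, int(math.floor(row - radius_px - 1)))
    r_hi = min(h, int(math.ceil(row + radius_px + 2)))
    c_lo = max(0, int(math.floor(col - radius_px - 1)))
    c_hi = min(w, int(math.ceil(col + radius_px + 2)))
    if r_hi <= r_lo or c_hi <= c_lo:
        return
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    dist = np.hypot(rr - row, cc - col)
    img[r_lo:r_hi, c_lo:c_hi] += amplitude * np.clip(radius_px - dist + 0.5, 0.0, 1.0)


def make_phantom(
    kind: str,
    params: dict,
    shape: tuple[int, int],
    pixel_nm: float,
    seed: int | None = None,
) -> Phantom:
    """Render a deterministic test object.

    Kinds
    -----
    ``line_pairs``
        Two parallel unit-intensity vertical lines at ``spacing_nm``,
        centred in the field (sub-pixel, area-weighted rendering).
    ``beads``
        ``n`` point/disk emitters of ``diameter_nm`` (0 = ideal point) at
        seeded uniform positions, or explicit ``positions_px``.
    ``filaments``
        Smooth random curves (seeded angular random walk).
    ``plate``
        Uniform field of ``intensity`` (default 1).
    ``sphere_shell``
        Ring of ``radius_nm`` and ``thickness_nm`` (equatorial section of
        a spherical shell).

    Structures finer than one grid pixel raise :class:`PhantomError`
    instructing a finer grid.
    """
    h, w = shape
    img = np.zeros((h, w), dtype=float)
    params = dict(params)
    rng = np.random.default_rng(params.pop("seed", seed))

    if kind == "line_pairs":
        spacing_nm = float(params["spacing_nm"])
        if spacing_nm < pixel_nm:
            raise PhantomError(
                f"line spacing {spacing_nm} nm is below one grid pixel "
                f"({pixel_nm} nm); use a finer grid"
            )
        cx = (w - 1) / 2.0
        half = spacing_nm / (2.0 * pixel_nm)
        _vertical_line(img, cx - half)
        _vertical_line(img, cx + half)
    elif kind == "beads":
        diameter_nm = float(params.get("diameter_nm", 0.0))
        if 0.0 < diameter_nm < pixel_nm:
            raise PhantomError(
                f"bead diameter {diameter_nm} nm is below one grid pixel; use a finer grid"
            )
        radius_px = diameter_nm / (2.0 * pixel_nm)
        positions = params.get("positions_px")
        if positions is None:
            n = int(params.get("n", 10))
            margin = params.get("margin_px", max(4.0, radius_px + 2.0))
            positions = np.column_stack(
                [
                    rng.uniform(margin, h - 1 - margin, size=n),
                    rng.uniform(margin, w - 1 - margin, size=n),
                ]
            )
        for row, col in np.asarray(positions, dtype=float):
            if radius_px > 0:
                _disk(img, row, col, radius_px)
            else:
                _tent_deposit(img, row, col)
    elif kind == "filaments":
        n = int(params.get("n", 3))
        step_px = 0.3
        for _ in range(n):
            row, col = rng.uniform(0.2, 0.8, size=2) * np.array([h - 1, w - 1])
            angle = rng.uniform(0, 2 * math.pi)
            for _ in range(int(params.get("length_px", max(h, w)) / step_px)):
                _tent_deposit(img, row, col, amplitude=step_px)
                angle += rng.normal(0.0, 0.08)
                row += step_px * math.sin(angle)
                col += step_px * math.cos(angle)
                if not (0 <= row < h and 0 <= col < w):
                    break
    elif kind == "plate":
        img[:] = float(params.get("intensity", 1.0))
    elif kind == "sphere_shell":
        radius_nm = float(params["radius_nm"])
        thickness_nm = float(params.get("thickness_nm", 2 * pixel_nm))
        if thickness_nm < pixel_nm:
            raise PhantomError("shell thickness below one grid pixel; use a finer grid")
        rr, cc = np.mgrid[0:h, 0:w]
        dist = np.hypot(rr - (h - 1) / 2.0, cc - (w - 1) / 2.0) * pixel_nm
        img = np.clip((thickness_nm / 2.0 - np.abs(dist - radius_nm)) / pixel_nm + 0.5, 0.0, 1.0)
    else:
        raise PhantomError(f"unknown phantom kind {kind!r}; choose from {PHANTOM_KINDS}")

    return Phantom(image=img, pixel_nm=pixel_nm, kind=kind, params=params)


# ---------------------------------------------------------------------------
# illumination patterns
# ---------------------------------------------------------------------------

def _spot_base_image(
    spots_xy_nm: np.ndarray, shape: tuple[int, int], pixel_nm: float, diameter_nm: float
) -> np.ndarray:
    """Pinhole apertures (disks, or sub-pixel deltas for diameter 0)."""
    h, w = shape
    img = np.zeros((h, w), dtype=float)
    radius_px = diameter_nm / (2.0 * pixel_nm)
    for x, y in np.asarray(spots_xy_nm, dtype=float):
        row = y / pixel_nm + (h - 1) / 2.0
        col = x / pixel_nm + (w - 1) / 2.0
        if radius_px > 0:
            _disk(img, row, col, radius_px)
        else:
            _tent_deposit(img, row, col)
    return img


def illumination_stack(
    geom: PinholeArrayGeometry,
    traj: ScanTrajectory,
    psf_ex: PSFModel,
    shape: tuple[int, int],
    pixel_nm: float,
) -> np.ndarray:
    """All per-frame illumination patterns, peak-normalized to 1.

    Each pattern is the pinhole-disk comb at that frame's scan position
    convolved with the excitation PSF.  Normalization uses the peak of a
    single isolated spot so that every frame shares one global scale
    (required for the forward model to be linear across frames).
    """
    h, w = shape
    field_nm = (w * pixel_nm, h * pixel_nm)
    # spots outside the field still shine in: include everything whose
    # blurred disk could contribute above ~1e-8 of a spot peak
    margin = geom.diameter_nm / 2.0 + 6.0 * psf_ex.sigma_lateral_nm
    frames_spots = scan_positions(geom, traj, field_nm, margin_nm=margin)
    kernel = psf_ex.kernel()

    # reference peak: one spot rendered at the field centre
    ref = _spot_base_image(np.array([[0.0, 0.0]]), shape, pixel_nm, geom.diameter_nm)
    ref = fftconvolve(ref, kernel, mode="same")
    peak = ref.max()

    patterns = np.empty((traj.n_frames, h, w), dtype=float)
    for k, spots in enumerate(frames_spots):
        base = _spot_base_image(spots, shape, pixel_nm, geom.diameter_nm)
        patterns[k] = fftconvolve(base, kernel, mode="same")
    patterns = np.clip(patterns, 0.0, None) / peak
    return patterns


def illumination_pattern(
    geom: PinholeArrayGeometry,
    traj: ScanTrajectory,
    psf_ex: PSFModel,
    frame_index: int,
    shape: tuple[int, int],
    pixel_nm: float,
) -> np.ndarray:
    """Single-frame illumination pattern (see :func:`illumination_stack`)."""
    if not (0 <= frame_index < traj.n_frames):
        raise IndexError(f"frame_index {frame_index} out of range for {traj.n_frames} frames")
    return illumination_stack(geom, traj, psf_ex, shape, pixel_nm)[frame_index]


# ---------------------------------------------------------------------------
# forward model and noise
# ---------------------------------------------------------------------------

def simulate_stack(
    phantom: Phantom,
    geom: PinholeArrayGeometry,
    traj: ScanTrajectory,
    optics: OpticalConfig,
    background: float | np.ndarray = 0.0,
    bin_factor: int = 1,
    patterns: np.ndarray | None = None,
) -> RawStack:
    """Noise-free multifocal stack: ``h_det * (P_i . O) + background``.

    ``background`` is a frame-independent additive plane (scalar or 2-D
    array on the object grid), standing in for out-of-focus light.
    ``bin_factor`` block-averages the object grid down to the camera grid.
    Precomputed ``patterns`` may be injected to skip re-rendering.
    """
    from .deconv import forward_model  # shared code path; avoids import cycle

    O = phantom.image
    if np.isscalar(background):
        if background < 0:
            raise ValueError("background must be nonnegative")
        bg = float(background)
    else:
        bg = np.asarray(background, dtype=float)
        if (bg < 0).any():
            raise ValueError("background must be nonnegative")
        if bg.shape != O.shape:
            raise ValueError("background plane must match the object grid")

    psf_ex = gaussian_psf_from_config(optics, "excitation")
    h_det = gaussian_psf_from_config(optics, "emission").kernel()
    if patterns is None:
        patterns = illumination_stack(geom, traj, psf_ex, O.shape, phantom.pixel_nm)
    if patterns.shape != (traj.n_frames, *O.shape):
        raise ValueError("patterns do not match trajectory/object grid")

    frames = np.empty_like(patterns)
    for k in range(traj.n_frames):
        frames[k] = forward_model(O, patterns[k], h_det)
    frames = frames + bg

    pixel_nm = phantom.pixel_nm
    if bin_factor > 1:
        n, h, w = frames.shape
        h2, w2 = h // bin_factor, w // bin_factor
        frames = frames[:, : h2 * bin_factor, : w2 * bin_factor]
        frames = frames.reshape(n, h2, bin_factor, w2, bin_factor).mean(axis=(2, 4))
        pixel_nm *= bin_factor

    meta = {
        "optics": optics.to_dict(),
        "geometry": geom.to_dict(),
        "trajectory": traj.to_dict(),
        "phantom": {"kind": phantom.kind, "params": phantom.params},
        "background": "array" if not np.isscalar(background) else float(background),
        "bin_factor": bin_factor,
        "noise": None,
    }
    return RawStack(frames=frames, pixel_nm=pixel_nm, meta=meta)


def add_noise_to_snr(
    stack: RawStack, snr_db: float, kind: str = "gaussian", seed: int | None = 0
) -> RawStack:
    """Degrade a noise-free stack to a target SNR.

    SNR is defined as ``10 log10(mean(signal^2) / sigma_noise^2)`` over
    the signal support (pixels above 1% of the stack maximum); this
    definition is recorded in the metadata so results are auditable.
    ``kind`` is ``gaussian`` (additive, exact sigma), ``poisson`` (photon
    scaling chosen so the support-averaged shot variance meets the
    target), or ``mixed`` (half the noise power from each).
    """
    signal = np.asarray(stack.frames, dtype=float)
    if signal.max() <= 0:
        raise ValueError("cannot set an SNR on an all-zero stack")
    if np.isinf(snr_db):
        return stack.with_frames(signal.copy(), noise={"kind": "none", "snr_db": "inf"})
    support = signal > 0.01 * signal.max()
    mean_sq = float(np.mean(signal[support] ** 2))
    target_var = mean_sq / 10.0 ** (snr_db / 10.0)
    rng = np.random.default_rng(seed)

    if kind == "gaussian":
        sigma = math.sqrt(target_var)
        noisy = signal + rng.normal(0.0, sigma, size=signal.shape)
        record = {"kind": kind, "snr_db": snr_db, "seed": seed, "sigma": sigma}
    elif kind == "poisson":
        mean_support = float(np.mean(signal[support]))
        scale = mean_support / target_var  # E[var]/scale^2 = mean/scale = target
        noisy = rng.poisson(np.clip(signal, 0, None) * scale) / scale
        record = {"kind": kind, "snr_db": snr_db, "seed": seed, "photon_scale": scale}
    elif kind == "mixed":
        mean_support = float(np.mean(signal[support]))
        scale = mean_support / (target_var / 2.0)
        sigma = math.sqrt(target_var / 2.0)
        noisy = rng.poisson(np.clip(signal, 0, None) * scale) / scale
        noisy = noisy + rng.normal(0.0, sigma, size=signal.shape)
        record = {
            "kind": kind,
            "snr_db": snr_db,
            "seed": seed,
            "sigma": sigma,
            "photon_scale": scale,
        }
    else:
        raise ValueError(f"unknown noise kind {kind!r}")

    record["definition"] = "10*log10(mean(signal^2)/var_noise) over signal > 1% max"
    return stack.with_frames(noisy, noise=record)
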