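"""Optical lock-in detection (OLID) preprocessing.

Multifocal scanning modulates every in-focus pixel periodically as spots
sweep past (AC), while out-of-focus light stays constant from frame to
frame (DC).  Filtering each pixel's temporal spectrum along the frame
axis and attenuating the zero-frequency bin therefore removes the
scan-invariant background while keeping the modulated in-focus signal.
With ``dc_attenuation = 0`` (default) this is exact annihilation of any
frame-constant component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stackio import RawStack


@dataclass(frozen=True)
class OlidParams:
    """``dc_attenuation`` in [0, 1] scales the zero-frequency bin
    (0 = full removal); ``clamp_negative`` zeroes negative excursions of
    the filtered frames."""

    dc_attenuation: float = 0.0
    clamp_negative: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.dc_attenuation <= 1.0):
            raise ValueError("dc_attenuation must lie in [0, 1]")


def olid_filter(stack: RawStack | np.ndarray, params: OlidParams | None = None):
    """Attenuate the per-pixel zero-frequency (frame-axis) component.

    Accepts a :class:`RawStack` or a bare (n, H, W) array and returns the
    same type; requires at least two frames (a single frame has no
    modulation axis).
    """
    params = params or OlidParams()
    frames = stack.frames if isinstance(stack, RawStack) else np.asarray(stack, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("OLID needs a stack of >= 2 frames (no modulation axis otherwise)")

    spectrum = np.fft.rfft(frames, axis=0)
    spectrum[0] *= params.dc_attenuation
    out = np.fft.irfft(spectrum, n=frames.shape[0], axis=0)
    if params.clamp_negative:
        out = np.maximum(out, 0.0)

    if isinstance(stack, RawStack):
        return stack.with_frames(
            out,
            olid={
                "dc_attenuation": params.dc_attenuation,
                "clamp_negative": params.clamp_negative,
            },
        )
    return out
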