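"""Raw multifocal stacks and their on-disk format.

A :class:`RawStack` is the frames-by-height-by-width intensity array a
multifocal scan produces, together with the acquisition metadata needed
to reconstruct it (optics, lattice geometry, trajectory, noise record).
On disk a stack is a multi-page grayscale TIFF with a JSON sidecar
(`<stem>.json`) holding the metadata; dtype is preserved so write->read
round-trips are lossless.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


class StackFormatError(ValueError):
    """Raised for unreadable or inconsistent stack files."""


@dataclass
class RawStack:
    """Scan stack: ``frames`` with shape (n_frames, H, W) plus metadata.

    Noise-free simulator output is nonnegative; stacks carrying additive
    Gaussian noise may contain negative excursions (no camera offset is
    modelled), which downstream stages tolerate.
    """

    frames: np.ndarray
    pixel_nm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise StackFormatError(f"frames must be 3-D, got shape {self.frames.shape}")
        if not np.isfinite(self.frames).all():
            raise StackFormatError("frames contain NaN/Inf")
        if self.pixel_nm <= 0:
            raise StackFormatError("pixel_nm must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    def with_frames(self, frames: np.ndarray, **meta_updates) -> "RawStack":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return RawStack(frames=frames, pixel_nm=self.pixel_nm, meta=meta)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_stack(stack: RawStack, path: str | Path) -> Path:
    """Write a multi-page TIFF plus JSON sidecar; returns the TIFF path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames, photometric="minisblack")
    sidecar = {
        "pixel_nm": stack.pixel_nm,
        "n_frames": stack.n_frames,
        "dtype": str(stack.frames.dtype),
        "meta": _jsonable(stack.meta),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_stack(path: str | Path) -> RawStack:
    """Read a stack written by :func:`write_stack`.

    A missing sidecar loads the pixel data with metadata marked unknown;
    a frame-count mismatch between TIFF and sidecar is an error.
    """
    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - tifffile error text varies
        raise StackFormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise StackFormatError(
            f"{path}: expected a multi-page grayscale stack, got shape {frames.shape}"
        )
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        warnings.warn(f"no sidecar metadata for {path}; metadata marked unknown")
        return RawStack(frames=frames, pixel_nm=1.0, meta={"unknown": True})
    sidecar = json.loads(sidecar_file.read_text())
    if sidecar.get("n_frames") != frames.shape[0]:
        raise StackFormatError(
            f"{path}: sidecar records {sidecar.get('n_frames')} frames, "
            f"TIFF holds {frames.shape[0]}"
        )
    return RawStack(frames=frames, pixel_nm=float(sidecar["pixel_nm"]), meta=sidecar.get("meta", {}))
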