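"""Illumination-spot localization and global lattice/trajectory fitting.

Pixel reassignment needs the sub-pixel centre of every illumination spot
in every frame.  Individual spots are found by matched filtering
(correlation with the excitation kernel) followed by sub-pixel peak
interpolation; the per-frame candidates are then regularized by a global
least-squares fit of a rigid lattice plus a constant per-frame scan step,
so that dim or edge spots inherit their position from the geometry.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve, resample
from skimage.feature import peak_local_max

from .geometry import PinholeArrayGeometry, ScanTrajectory, scan_positions
from .stackio import RawStack

_log = logging.getLogger(__name__)


class LocalizationError(RuntimeError):
    pass


@dataclass
class SpotGrid:
    """Per-frame spot centres tied to a fitted lattice and scan trajectory.

    ``centers[k]`` is an (m_k, 2) array of (row, col) positions in px
    (possibly on an upsampled grid); ``lattice`` holds the two lattice
    vectors as rows; ``step_px`` is the per-frame scan displacement.
    """

    centers: list  # list of (m, 2) float arrays, (row, col)
    lattice: np.ndarray  # (2, 2), rows are lattice vectors (row, col)
    step_px: np.ndarray  # (2,), per-frame displacement (row, col)
    origin_px: np.ndarray  # (2,)
    rms_residual: float = 0.0
    shape: tuple | None = None

    @property
    def n_frames(self) -> int:
        return len(self.centers)

    def frame_offsets(self) -> np.ndarray:
        k = np.arange(self.n_frames, dtype=float)[:, None]
        return k * self.step_px[None, :]

    def shifted(self, delta_px: tuple[float, float]) -> "SpotGrid":
        d = np.asarray(delta_px, dtype=float)
        return SpotGrid(
            centers=[c + d[None, :] for c in self.centers],
            lattice=self.lattice.copy(),
            step_px=self.step_px.copy(),
            origin_px=self.origin_px + d,
            rms_residual=self.rms_residual,
            shape=self.shape,
        )

    @classmethod
    def from_geometry(
        cls,
        geom: PinholeArrayGeometry,
        traj: ScanTrajectory,
        shape: tuple[int, int],
        pixel_nm: float,
        upsample: int = 1,
        margin_px: float = 0.0,
    ) -> "SpotGrid":
        """Predicted spot centres from known acquisition geometry.

        This is the calibration path: on a simulated stack (or after an
        instrument calibration) the lattice and trajectory are known
        exactly, so localization can be skipped.
        """
        h, w = shape
        field_nm = (w * pixel_nm, h * pixel_nm)
        frames = scan_positions(
            geom, traj, field_nm, margin_nm=margin_px * pixel_nm / max(upsample, 1)
        )
        centers = []
        for pts in frames:
            rows = (pts[:, 1] / pixel_nm + (h - 1) / 2.0) * upsample
            cols = (pts[:, 0] / pixel_nm + (w - 1) / 2.0) * upsample
            centers.append(np.column_stack([rows, cols]))
        theta = geom.tilt_rad
        pitch_px = geom.pitch_nm / pixel_nm * upsample
        lattice = pitch_px * np.array(
            [[math.sin(theta), math.cos(theta)], [math.cos(theta), -math.sin(theta)]]
        )
        step = traj.step_nm / pixel_nm * upsample
        step_px = step * np.array([traj.direction[1], traj.direction[0]])
        return cls(
            centers=centers,
            lattice=lattice,
            step_px=step_px,
            origin_px=np.array([(h - 1) / 2.0 * upsample, (w - 1) / 2.0 * upsample]),
            rms_residual=0.0,
            shape=(h * upsample, w * upsample),
        )


def _subpixel_peak(score: np.ndarray, row: int, col: int) -> tuple[float, float]:
    """Separable 3-point Gaussian interpolation of a peak; falls back to the
    integer position when neighbours are nonpositive."""
    out = [float(row), float(col)]
    for axis, (r, c) in enumerate(((row, col), (row, col))):
        if axis == 0:
            triple = score[row - 1 : row + 2, col] if 0 < row < score.shape[0] - 1 else None
        else:
            triple = score[row, col - 1 : col + 2] if 0 < col < score.shape[1] - 1 else None
        if triple is None or np.any(triple <= 0):
            continue
        lm, l0, lp = np.log(triple)
        denom = lm - 2.0 * l0 + lp
        if denom >= 0:
            continue
        out[axis] += 0.5 * (lm - lp) / denom
    return out[0], out[1]


def detect_spot_candidates(
    frame: np.ndarray,
    kernel: np.ndarray,
    min_separation_px: float,
    threshold_rel: float = 0.2,
) -> np.ndarray:
    """Sub-pixel spot candidates via matched filtering.

    Correlates the frame with the (symmetric) excitation kernel, takes
    local maxima separated by ``min_separation_px`` and above
    ``threshold_rel`` of the global maximum, and refines each with
    3-point Gaussian peak interpolation.  Returns an (m, 2) array of
    (row, col); empty with a warning when nothing clears the threshold.
    """
    frame = np.asarray(frame, dtype=float)
    score = fftconvolve(frame, np.flip(kernel), mode="same")
    if score.max() <= 0:
        warnings.warn("no spot candidates above threshold")
        return np.empty((0, 2))
    # spots whose support is clipped by the field edge localize poorly;
    # the lattice fit recovers their positions instead
    border = kernel.shape[0] // 2
    peaks = peak_local_max(
        score,
        min_distance=max(1, int(round(min_separation_px))),
        threshold_abs=threshold_rel * score.max(),
        exclude_border=border,
    )
    if len(peaks) == 0:
        warnings.warn("no spot candidates above threshold")
        return np.empty((0, 2))
    refined = [_subpixel_peak(np.maximum(score, 0.0), r, c) for r, c in peaks]
    return np.asarray(refined, dtype=float)


def fit_grid_to_frames(
    candidates: list,
    geometry_prior: dict,
    trajectory_prior: dict,
    shape: tuple[int, int] | None = None,
    n_rounds: int = 5,
    outlier_sigma: float = 3.0,
) -> SpotGrid:
    """Least-squares lattice + scan-step fit through per-frame candidates.

    ``geometry_prior`` needs ``pitch_px`` and ``tilt_deg``;
    ``trajectory_prior`` needs ``step_px`` (scalar, fast axis = +col).
    Candidates are assigned integer lattice indices from the prior, the
    model ``c = origin + i*a1 + j*a2 + k*step`` is solved in closed form,
    and candidates beyond ``outlier_sigma`` times the rms residual are
    discarded before refitting.  Predicted centres are returned for every
    lattice site in bounds (including spots too dim to detect).
    """
    n_frames = len(candidates)
    cands = [np.asarray(c, dtype=float).reshape(-1, 2) for c in candidates]
    n_total = sum(len(c) for c in cands)
    if n_total < 4 * n_frames:
        warnings.warn("fewer than 4 candidates per frame on average; fit may be unstable")
    if n_total < 4:
        raise LocalizationError("not enough candidates to fit a lattice")

    theta = math.radians(geometry_prior["tilt_deg"])
    pitch = float(geometry_prior["pitch_px"])
    a1 = pitch * np.array([math.sin(theta), math.cos(theta)])
    a2 = pitch * np.array([math.cos(theta), -math.sin(theta)])
    step = np.array([0.0, float(trajectory_prior["step_px"])])
    # anchor the lattice on the candidate closest to the centroid of frame 0
    ref = cands[0] if len(cands[0]) else np.concatenate(cands)
    origin = ref[np.argmin(np.linalg.norm(ref - ref.mean(axis=0), axis=1))].copy()

    active = [np.ones(len(c), dtype=bool) for c in cands]
    rms = np.inf
    for _ in range(n_rounds):
        rows, targets = [], []
        basis = np.column_stack([a1, a2])  # (2, 2): columns are lattice vectors
        inv = np.linalg.pinv(basis)
        for k, c in enumerate(cands):
            keep = active[k]
            if not keep.any():
                continue
            rel = c[keep] - origin[None, :] - k * step[None, :]
            ij = np.rint(rel @ inv.T)
            for (i, j), target in zip(ij, c[keep]):
                rows.append([1.0, i, j, float(k)])
                targets.append(target)
        design = np.asarray(rows)
        targets = np.asarray(targets)
        if len(design) < 4 or np.linalg.matrix_rank(design) < 4:
            raise LocalizationError("degenerate candidate geometry (collinear spots?)")
        sol, *_ = np.linalg.lstsq(design, targets, rcond=None)
        origin, a1, a2, step = sol[0], sol[1], sol[2], sol[3]
        resid = targets - design @ sol
        dist = np.linalg.norm(resid, axis=1)
        rms = float(np.sqrt(np.mean(dist**2)))
        cutoff = max(outlier_sigma * rms, 1e-9)
        # re-flag outliers against the fresh fit
        pos = 0
        for k, c in enumerate(cands):
            keep_idx = np.flatnonzero(active[k])
            for idx in keep_idx:
                if dist[pos] > cutoff:
                    active[k][idx] = False
                pos += 1

    lattice = np.vstack([a1, a2])
    if abs(np.linalg.det(lattice)) < 1e-6 * pitch**2:
        raise LocalizationError("degenerate fitted lattice")

    # predicted centres for every site in bounds
    centers = []
    if shape is None:
        allc = np.concatenate(cands)
        shape = (int(allc[:, 0].max()) + 1, int(allc[:, 1].max()) + 1)
    h, w = shape
    span = int(math.ceil((h + w) / min(np.linalg.norm(a1), np.linalg.norm(a2)))) + 2
    ii, jj = np.meshgrid(np.arange(-span, span + 1), np.arange(-span, span + 1), indexing="ij")
    base = origin[None, :] + ii.ravel()[:, None] * a1 + jj.ravel()[:, None] * a2
    for k in range(n_frames):
        pts = base + k * step[None, :]
        keep = (
            (pts[:, 0] >= -0.5)
            & (pts[:, 0] <= h - 0.5)
            & (pts[:, 1] >= -0.5)
            & (pts[:, 1] <= w - 0.5)
        )
        centers.append(pts[keep])

    _log.info("lattice fit: rms %.4f px, step (%.3f, %.3f) px", rms, step[0], step[1])
    return SpotGrid(
        centers=centers,
        lattice=lattice,
        step_px=step,
        origin_px=origin,
        rms_residual=rms,
        shape=shape,
    )


def upsample_stack(stack: RawStack | np.ndarray, factor: int):
    """Band-limited (Fourier zero-padding) upsampling of every frame.

    Only factors 1, 2 and 4 are supported; factor 1 is the identity.  The
    DC component (frame mean) is preserved and signals below the original
    Nyquist frequency are interpolated exactly.
    """
    if factor not in (1, 2, 4):
        raise ValueError("upsample factor must be one of {1, 2, 4}")
    frames = stack.frames if isinstance(stack, RawStack) else np.asarray(stack, dtype=float)
    single = frames.ndim == 2
    if single:
        frames = frames[None]
    if factor == 1:
        out = frames.copy()
    else:
        n, h, w = frames.shape
        out = resample(resample(frames, h * factor, axis=1), w * factor, axis=2)
    if single:
        out = out[0]
    if isinstance(stack, RawStack):
        return RawStack(
            frames=out,
            pixel_nm=stack.pixel_nm / factor,
            meta={**stack.meta, "upsample_factor": factor * stack.meta.get("upsample_factor", 1)},
        )
    return out
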