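"""Pinhole-array lattice and 1-D tilted scan trajectories.

The excitation pinholes form a square lattice rotated by a small tilt
angle relative to the scan fast axis.  A single galvanometer sweeps the
whole lattice along the fast axis only; the tilt is chosen so that the
projection of the scan samples onto the lattice's slow direction lands on
a uniform grid, which lets a 1-D sweep of n^2 frames cover every unit
cell of the lattice on an (approximately) n x n sub-grid.

Coordinates are sample-plane nanometres, origin at the field centre,
fast axis = +x, slow axis = +y.  Pixel (row, col) maps to (y, x) with
pixel centres at integer indices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np


class GeometryError(ValueError):
    """Raised for invalid lattice/scan parameter combinations."""


@dataclass(frozen=True)
class PinholeArrayGeometry:
    """Square pinhole lattice at the sample plane.

    ``pitch_nm`` is the centre-to-centre spacing, ``diameter_nm`` the
    pinhole diameter (``diameter_nm = 0`` means ideal point pinholes),
    ``tilt_deg`` the rotation of the lattice relative to the scan fast
    axis.  The default diameter:pitch ratio used throughout is 1:3.
    """

    pitch_nm: float
    diameter_nm: float
    tilt_deg: float

    def __post_init__(self) -> None:
        if self.pitch_nm <= 0:
            raise GeometryError("pitch_nm must be positive")
        if self.diameter_nm < 0:
            raise GeometryError("diameter_nm must be nonnegative")
        if self.pitch_nm < self.diameter_nm:
            raise GeometryError("pitch must be at least the pinhole diameter")
        if not (0.0 < self.tilt_deg < 45.0):
            raise GeometryError("tilt_deg must lie in (0, 45)")

    @property
    def tilt_rad(self) -> float:
        return math.radians(self.tilt_deg)

    def lattice_vectors(self) -> np.ndarray:
        """Rows are the lattice vectors (x, y) in nm."""
        c, s = math.cos(self.tilt_rad), math.sin(self.tilt_rad)
        return self.pitch_nm * np.array([[c, s], [-s, c]])

    def to_dict(self) -> dict:
        return {
            "pitch_nm": self.pitch_nm,
            "diameter_nm": self.diameter_nm,
            "tilt_deg": self.tilt_deg,
        }


@dataclass(frozen=True)
class ScanTrajectory:
    """1-D scan: ``n_frames`` equal steps of ``step_nm`` along the fast axis."""

    n_frames: int
    step_nm: float
    direction: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise GeometryError("n_frames must be >= 1")
        if self.step_nm < 0:
            raise GeometryError("step_nm must be nonnegative")
        norm = math.hypot(*self.direction)
        if norm == 0:
            raise GeometryError("direction must be a nonzero vector")
        object.__setattr__(
            self, "direction", (self.direction[0] / norm, self.direction[1] / norm)
        )

    @property
    def positions(self) -> np.ndarray:
        """Per-frame lattice displacement (n_frames, 2) in nm; frame 0 at origin."""
        k = np.arange(self.n_frames, dtype=float)[:, None]
        return k * self.step_nm * np.asarray(self.direction)[None, :]

    def to_dict(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "step_nm": self.step_nm,
            "direction": list(self.direction),
        }


def tilt_for_uniform_coverage(n: int) -> float:
    """Tilt angle (degrees) for uniform slow-axis coverage: ``arctan(1/n)``.

    With this tilt a 1-D scan of n^2 frames samples each lattice unit cell
    on an n x n sub-grid.
    """
    if not (isinstance(n, (int, np.integer)) and n >= 2):
        raise GeometryError("frames-per-side n must be an integer >= 2")
    return math.degrees(math.atan2(1.0, n))


def coverage_step_nm(pitch_nm: float, n: int) -> float:
    """Scan step for exact unit-cell coverage with n^2 frames at tilt arctan(1/n).

    Equates the total slow-axis travel ``n^2 * step * sin(theta)`` with one
    pitch: ``step = pitch * sqrt(n^2 + 1) / n^2``.
    """
    if n < 2:
        raise GeometryError("n must be >= 2")
    return pitch_nm * math.sqrt(n * n + 1.0) / (n * n)


def frame_reduction_step_ratio(n_frames_a: int, n_frames_b: int) -> float:
    """Step-size ratio ``step_b / step_a`` when reducing an n_a^2-frame scan
    to n_b^2 frames at fixed slow-axis sampling.

    With tilt ``arctan(1/n)`` the slow-axis sampling interval is
    ``step / sqrt(n^2 + 1)``; holding it constant gives
    ``step ∝ sqrt(n^2 + 1)``, e.g. 49 -> 25 frames enlarges the step by
    ``sqrt(50)/sqrt(26) ≈ 1.39``.
    """
    ratios = []
    for count in (n_frames_a, n_frames_b):
        n = math.isqrt(int(count))
        if n * n != count or n < 2:
            raise GeometryError(f"frame count {count} is not a perfect square n^2, n>=2")
        ratios.append(math.sqrt(n * n + 1.0))
    return ratios[0] / ratios[1]


def scan_preset(n: int, pitch_nm: float, step_nm: float | None = None) -> tuple[float, "ScanTrajectory"]:
    """(tilt_deg, trajectory) for the n^2-frame 1-D scan preset.

    When ``step_nm`` is omitted, the exact coverage step is used so that
    the summed excitation is uniform over the field.
    """
    tilt = tilt_for_uniform_coverage(n)
    step = coverage_step_nm(pitch_nm, n) if step_nm is None else step_nm
    return tilt, ScanTrajectory(n_frames=n * n, step_nm=step)


def scan_positions(
    geom: PinholeArrayGeometry,
    traj: ScanTrajectory,
    field_size_nm: tuple[float, float],
    margin_nm: float = 0.0,
    origin_nm: tuple[float, float] = (0.0, 0.0),
    center_scan: bool = True,
) -> list[np.ndarray]:
    """Per-frame illumination-spot centres (x, y) in nm inside the field.

    Frame ``k`` contains the lattice translated by ``k * step`` along the
    fast axis.  ``center_scan`` shifts the lattice origin by half the total
    scan travel so the sweep is symmetric about the field centre.
    ``margin_nm`` enlarges the inclusion window (spots just outside the
    field still illuminate it).
    """
    wx, wy = field_size_nm
    half = np.array([wx / 2.0 + margin_nm, wy / 2.0 + margin_nm])
    vecs = geom.lattice_vectors()  # rows a1, a2 (x, y)
    disp = traj.positions
    origin = np.asarray(origin_nm, dtype=float)
    if center_scan and traj.n_frames > 1:
        origin = origin - disp[-1] / 2.0

    # integer index ranges covering the field for every frame
    corners = []
    for dx in (-half[0], half[0]):
        for dy in (-half[1], half[1]):
            for d in (disp[0], disp[-1]):
                corners.append(np.array([dx, dy]) - origin - d)
    inv = np.linalg.inv(vecs.T)
    idx = np.array([inv @ c for c in corners])
    i_lo, j_lo = np.floor(idx.min(axis=0)).astype(int) - 1
    i_hi, j_hi = np.ceil(idx.max(axis=0)).astype(int) + 1
    ii, jj = np.meshgrid(np.arange(i_lo, i_hi + 1), np.arange(j_lo, j_hi + 1), indexing="ij")
    base = origin[None, :] + ii.ravel()[:, None] * vecs[0] + jj.ravel()[:, None] * vecs[1]

    frames = []
    for d in disp:
        pts = base + d[None, :]
        keep = (np.abs(pts[:, 0]) <= half[0]) & (np.abs(pts[:, 1]) <= half[1])
        frames.append(pts[keep])
    return frames


def slow_axis_projections(geom: PinholeArrayGeometry, traj: ScanTrajectory) -> np.ndarray:
    """Projection of the per-frame scan displacement onto the lattice slow axis.

    For a fast-axis scan at tilt theta these are ``k * step * sin(theta)``:
    the slow-axis sampling comb each pinhole lays down inside its unit cell.
    """
    c, s = math.cos(geom.tilt_rad), math.sin(geom.tilt_rad)
    slow_unit = np.array([-s, c])  # perpendicular to lattice fast vector
    return traj.positions @ slow_unit


def check_uniform_coverage(
    geom: PinholeArrayGeometry, traj: ScanTrajectory, tol: float = 1e-9
) -> dict:
    """Report slow-axis coverage uniformity of the scan inside one unit cell.

    Wraps the slow-axis projections modulo the pitch and inspects the gaps;
    a commensurate preset (``tilt = arctan(1/n)``, ``n^2`` frames, coverage
    step) yields exactly equal gaps.  A warning lists the max/min gap when
    coverage is non-uniform.
    """
    proj = np.sort(np.mod(np.abs(slow_axis_projections(geom, traj)), geom.pitch_nm))
    gaps = np.diff(np.concatenate([proj, [proj[0] + geom.pitch_nm]]))
    report = {
        "slow_projections_nm": proj,
        "max_gap_nm": float(gaps.max()),
        "min_gap_nm": float(gaps.min()),
        "uniform": bool(gaps.max() - gaps.min() < tol),
    }
    if not report["uniform"]:
        warnings.warn(
            "non-uniform slow-axis coverage: gaps range "
            f"{report['min_gap_nm']:.3g}..{report['max_gap_nm']:.3g} nm"
        )
    return report
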