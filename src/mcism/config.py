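"""Run configuration and the end-to-end pipeline.

A :class:`RunConfig` (YAML or JSON) describes one reconstruction run:
optics, pinhole-array geometry, scan trajectory, the optional simulated
phantom and noise, OLID settings, the reconstruction method and the
metrics to report.  Unknown keys are rejected; every default the method
leaves open (lambda, dc_attenuation, sigma_rel, thresholds) is logged to
the run's parameter record so runs are auditable and, given a seed,
deterministic.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import deconv, geometry, localize, metrics, olid, optics, reassign, simulate, stackio

_log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OpticsBlock(_Block):
    lambda_ex: float = 640.0
    lambda_em: float = 680.0
    na: float = 1.49
    pixel_nm: float = 32.5
    pinhole_magnification: Optional[float] = None


class GeometryBlock(_Block):
    pitch_um: Optional[float] = None  # physical, mapped via pinhole magnification
    diameter_um: Optional[float] = None
    pitch_au: Optional[float] = 1.5  # sample-plane, in Airy units
    diameter_au: Optional[float] = 0.5
    tilt_deg: Optional[float] = None  # default: arctan(1/n) for the frame preset


class TrajectoryBlock(_Block):
    n_frames: int = 49
    step_au: Optional[float] = 0.25
    step_nm: Optional[float] = None


class PhantomBlock(_Block):
    kind: str = "line_pairs"
    params: dict = Field(default_factory=dict)
    shape: tuple[int, int] = (64, 64)
    background: float = 0.0


class NoiseBlock(_Block):
    # None = noise-free (infinite SNR); inf does not survive YAML/JSON
    snr_db: Optional[float] = None
    kind: Literal["gaussian", "poisson", "mixed"] = "gaussian"


class OlidBlock(_Block):
    enabled: bool = True
    dc_attenuation: float = 0.0
    clamp_negative: bool = True


class LocateBlock(_Block):
    method: Literal["geometry", "fit"] = "geometry"
    upsample: Literal[1, 2, 4] = 2


class ReconstructionBlock(_Block):
    method: Literal["pr", "jrl", "fista"] = "pr"
    sigma_rel: Optional[float] = None  # None = no digital pinhole
    n_iter: int = 100
    lambda_rel: float = 1e-3  # FISTA-GS lambda as a fraction of max(measured)
    rl_iters: int = 0  # extra RL deconvolution of the PR canvas (MC-ISM)


class MetricsBlock(_Block):
    enabled: bool = True
    nominal_spacing_nm: Optional[float] = None


class RunConfig(_Block):
    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    optics: OpticsBlock = Field(default_factory=OpticsBlock)
    geometry: GeometryBlock = Field(default_factory=GeometryBlock)
    trajectory: TrajectoryBlock = Field(default_factory=TrajectoryBlock)
    phantom: Optional[PhantomBlock] = None
    noise: NoiseBlock = Field(default_factory=NoiseBlock)
    olid: OlidBlock = Field(default_factory=OlidBlock)
    locate: LocateBlock = Field(default_factory=LocateBlock)
    reconstruction: ReconstructionBlock = Field(default_factory=ReconstructionBlock)
    metrics: MetricsBlock = Field(default_factory=MetricsBlock)


def load_config(path: str | Path) -> RunConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return RunConfig.model_validate(data)


def build_domain(cfg: RunConfig):
    """Materialize (OpticalConfig, PinholeArrayGeometry, ScanTrajectory)."""
    opt = optics.OpticalConfig(
        lambda_ex=cfg.optics.lambda_ex,
        lambda_em=cfg.optics.lambda_em,
        na=cfg.optics.na,
        pixel_nm=cfg.optics.pixel_nm,
        pinhole_magnification=cfg.optics.pinhole_magnification,
    )
    au = opt.airy_unit_nm
    if cfg.geometry.pitch_um is not None:
        pitch = opt.pinhole_to_sample_nm(cfg.geometry.pitch_um * 1000.0)
    else:
        pitch = cfg.geometry.pitch_au * au
    if cfg.geometry.diameter_um is not None:
        diameter = opt.pinhole_to_sample_nm(cfg.geometry.diameter_um * 1000.0)
    else:
        diameter = cfg.geometry.diameter_au * au
    n_side = math.isqrt(cfg.trajectory.n_frames)
    tilt = cfg.geometry.tilt_deg
    if tilt is None:
        tilt = geometry.tilt_for_uniform_coverage(max(n_side, 2))
    geom = geometry.PinholeArrayGeometry(pitch_nm=pitch, diameter_nm=diameter, tilt_deg=tilt)
    step = cfg.trajectory.step_nm
    if step is None:
        step = cfg.trajectory.step_au * au
    traj = geometry.ScanTrajectory(n_frames=cfg.trajectory.n_frames, step_nm=step)
    return opt, geom, traj


def run_pipeline(cfg: RunConfig, outdir: str | Path, stack_path: str | Path | None = None) -> dict:
    """simulate (optional) -> OLID -> locate -> reconstruct -> metrics.

    Returns a dict of artifact paths; raises with the failing stage name.
    Given the same config and seed, outputs are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    opt, geom, traj = build_domain(cfg)
    record: dict = {"config": json.loads(cfg.model_dump_json()), "stages": {}}

    stage = "simulate"
    try:
        phantom = None
        if stack_path is not None:
            stack = stackio.read_stack(stack_path)
        elif cfg.phantom is not None:
            phantom = simulate.make_phantom(
                cfg.phantom.kind, cfg.phantom.params, tuple(cfg.phantom.shape),
                opt.pixel_nm, seed=cfg.seed,
            )
            stack = simulate.simulate_stack(
                phantom, geom, traj, opt, background=cfg.phantom.background
            )
            if cfg.noise.snr_db is not None:
                stack = simulate.add_noise_to_snr(
                    stack, cfg.noise.snr_db, kind=cfg.noise.kind, seed=cfg.seed
                )
            stackio.write_stack(stack, outdir / "raw.tif")
            artifacts["raw"] = str(outdir / "raw.tif")
        else:
            raise ValueError("neither a phantom nor an input stack was given")

        stage = "olid"
        if cfg.olid.enabled:
            stack = olid.olid_filter(
                stack,
                olid.OlidParams(
                    dc_attenuation=cfg.olid.dc_attenuation,
                    clamp_negative=cfg.olid.clamp_negative,
                ),
            )
            stackio.write_stack(stack, outdir / "olid.tif")
            artifacts["olid"] = str(outdir / "olid.tif")

        stage = "locate"
        factor = cfg.locate.upsample
        up = localize.upsample_stack(stack, factor)
        shape = stack.frames.shape[1:]
        if cfg.locate.method == "geometry":
            spots = localize.SpotGrid.from_geometry(geom, traj, shape, stack.pixel_nm, upsample=factor)
        else:
            psf_ex = optics.gaussian_psf_from_config(opt, "excitation")
            kernel = optics.gaussian_kernel(
                psf_ex.sigma_lateral_nm / up.pixel_nm, max(2, int(4 * psf_ex.sigma_lateral_nm / up.pixel_nm))
            )
            pitch_px = geom.pitch_nm / up.pixel_nm
            cands = [
                localize.detect_spot_candidates(f, kernel, min_separation_px=0.5 * pitch_px)
                for f in up.frames
            ]
            spots = localize.fit_grid_to_frames(
                cands,
                {"pitch_px": pitch_px, "tilt_deg": geom.tilt_deg},
                {"step_px": traj.step_nm / up.pixel_nm},
                shape=up.frames.shape[1:],
            )
        spots_json = {
            str(k): np.asarray(c).tolist() for k, c in enumerate(spots.centers)
        }
        (outdir / "spots.json").write_text(json.dumps(spots_json))
        artifacts["spots"] = str(outdir / "spots.json")

        stage = "reconstruct"
        method = cfg.reconstruction.method
        psf_ex_model = optics.gaussian_psf_from_config(opt, "excitation")
        psf_det_model = optics.gaussian_psf_from_config(opt, "emission")
        sigma_spot_nm = math.hypot(psf_ex_model.sigma_lateral_nm, geom.diameter_nm / 4.0)
        if method == "pr":
            sigma_base_px = (
                math.hypot(sigma_spot_nm, psf_det_model.sigma_lateral_nm) / up.pixel_nm
            )
            pr = reassign.pr_pipeline(
                up,
                spots,
                sigma_base_px=sigma_base_px,
                sigma_rel=(math.inf if cfg.reconstruction.sigma_rel is None
                           else cfg.reconstruction.sigma_rel),
                pitch_px=geom.pitch_nm / up.pixel_nm,
            )
            recon = pr.image
            recon_pixel_nm = pr.canvas_pixel_nm
            if cfg.reconstruction.rl_iters > 0:
                sigma_canvas = reassign.pr_psf_sigma_canvas_px(
                    sigma_spot_nm, psf_det_model.sigma_lateral_nm, up.pixel_nm
                )
                kernel = optics.gaussian_kernel(sigma_canvas, int(math.ceil(4 * sigma_canvas)))
                recon = reassign.mcism_reconstruct(pr, kernel, n_iter=cfg.reconstruction.rl_iters)
        else:
            if phantom is None:
                obj_shape = shape
            else:
                obj_shape = phantom.image.shape
            patterns = simulate.illumination_stack(
                geom, traj, psf_ex_model, obj_shape, stack.pixel_nm
            )
            measured = np.maximum(stack.frames, 0.0)
            problem = deconv.DeconvProblem(
                measured=measured,
                patterns=patterns,
                psf=psf_det_model.kernel(),
                lambda_reg=cfg.reconstruction.lambda_rel * float(measured.max()),
            )
            params = deconv.DeconvParams(n_iter=cfg.reconstruction.n_iter, seed=cfg.seed)
            if method == "jrl":
                recon = deconv.jrl_deconvolve(problem, params)
            else:
                recon = deconv.fista_gs(problem, params).image
            recon_pixel_nm = stack.pixel_nm
        recon_stack = stackio.RawStack(
            frames=recon[None],
            pixel_nm=recon_pixel_nm or stack.pixel_nm,
            meta={"method": method, "params": record["config"]["reconstruction"]},
        )
        stackio.write_stack(recon_stack, outdir / "recon.tif")
        artifacts["recon"] = str(outdir / "recon.tif")

        stage = "metrics"
        if cfg.metrics.enabled:
            report = {"method": method}
            if cfg.metrics.nominal_spacing_nm and recon_pixel_nm:
                profile = recon.mean(axis=0)
                fit = metrics.bigaussian_fit(
                    profile, cfg.metrics.nominal_spacing_nm / recon_pixel_nm
                )
                report["line_pair"] = {
                    "nominal_spacing_nm": cfg.metrics.nominal_spacing_nm,
                    "separation_nm": fit.separation_px * recon_pixel_nm,
                    "dip_contrast": fit.dip_contrast,
                    "resolved": fit.resolved,
                }
            (outdir / "metrics.json").write_text(json.dumps(report, indent=1, sort_keys=True))
            artifacts["metrics"] = str(outdir / "metrics.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    record["artifacts"] = artifacts
    (outdir / "run.json").write_text(json.dumps(record, indent=1, sort_keys=True))
    artifacts["run"] = str(outdir / "run.json")
    return artifacts
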