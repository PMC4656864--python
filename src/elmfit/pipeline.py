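"""End-to-end analysis pipeline and model-feedback reconstruction.

``run_pipeline`` orchestrates detect -> anticollision -> extract -> fit ->
quality control -> summarise over a list of frames, deterministically given
the configured seeds.  ``reconstruct`` renders accepted fits back through
the image model at an arbitrarily small PSF radius, producing a
superresolved *model-based* visualisation of the fitted structure (it is an
inference under the ellipsoidal-shell assumption, not raw data).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import ellipsoid_mc as emc
from .fitting import (EllipsoidShellModel, ExperimentSummary,
                      SphericalShellModel, summarize_experiment,
                      summarize_frame)
from .io import PipelineConfig
from .segmentation import anticollision_filter, detect_candidates
from .shell_models import PSFModel, PixelGrid, SphericalShell, render_shell_image

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "ReconstructionSpec",
           "reconstruct"]


@dataclass
class PipelineResult:
    """Everything the pipeline produced: per-candidate fits, per-frame
    summaries, and the across-field experiment summary (None when fewer
    than 3 frames were supplied)."""

    results: list = field(default_factory=list)
    frame_summaries: list = field(default_factory=list)
    experiment: ExperimentSummary = None


def _fit_one(region, psf, config: PipelineConfig, seed):
    if config.model_kind == "sphere_algebraic":
        return SphericalShellModel(region, psf).fit()
    return EllipsoidShellModel(
        region, psf, model_kind=config.model_kind, seed=seed,
        n_fluorophores=config.n_fluorophores,
        schedule=config.schedule()).fit()


def run_pipeline(config: PipelineConfig, frames: list) -> PipelineResult:
    """Run the full analysis on one or more frames.

    A failure on one candidate is logged and skips that candidate only;
    a frame with no candidates yields an empty FrameSummary.  All
    randomness (MC fitting) derives from ``config.seed``, so a rerun with
    the same config is bit-identical.
    """
    if not frames:
        raise ValueError("run_pipeline requires at least one frame")
    psf = PSFModel(sigma=config.sigma_known, sigma_known=config.sigma_known)
    out = PipelineResult()
    ss = np.random.SeedSequence(config.seed)
    frame_seeds = ss.generate_state(len(frames)) % (2 ** 31)
    for fi, frame in enumerate(frames):
        t0 = time.perf_counter()
        frame_id = frame.metadata.get("frame_id", fi)
        candidates = detect_candidates(
            frame, min_radius_px=config.hough_min_radius_px,
            max_radius_px=config.hough_max_radius_px,
            peak_threshold=config.hough_peak_threshold,
            smoothing_sigma=config.hough_smoothing_sigma)
        candidates = anticollision_filter(
            candidates, collision_distance=config.collision_distance_px)
        cand_ss = np.random.SeedSequence(int(frame_seeds[fi]))
        cand_seeds = cand_ss.generate_state(max(len(candidates), 1)) % (2 ** 31)
        frame_results = []
        for ci, region in enumerate(candidates):
            try:
                result = _fit_one(region, psf, config, int(cand_seeds[ci]))
            except Exception:
                log.warning("frame %s candidate %d: fit failed; skipped",
                            frame_id, region.index, exc_info=True)
                continue
            result.frame_id = frame_id
            w = frame.pixel_width
            # crop-local -> absolute frame coordinates (nm)
            half = (config.region_size // 2) * w
            result.x0 += region.center_pixel[1] * w + 0.5 * w - half - 0.5 * w
            result.y0 += region.center_pixel[0] * w + 0.5 * w - half - 0.5 * w
            frame_results.append(result)
        summary = summarize_frame(frame_results, frame_id=frame_id)
        n_rej = summary.n_candidates - summary.n_accepted
        log.info("frame %s: %d candidates, %d accepted, %d rejected "
                 "(%.2f s)", frame_id, summary.n_candidates,
                 summary.n_accepted, n_rej, time.perf_counter() - t0)
        out.results.extend(frame_results)
        out.frame_summaries.append(summary)
    if len(out.frame_summaries) >= 3:
        out.experiment = summarize_experiment(out.frame_summaries)
    else:
        log.info("fewer than 3 fields: across-field summary not computed")
    return out


# ---------------------------------------------------------------------------
# model-feedback superresolved reconstruction


@dataclass(frozen=True)
class ReconstructionSpec:
    """How to render fitted parameters back through the image model.

    ``render_psf_sigma`` defaults to 25 nm — half the estimated fluorescent
    layer thickness — so the reconstruction visualises fluorescence density
    rather than instrument blur; ``pixel_width`` of 10 nm resolves it.
    ``average`` renders one shell with the population-mean parameters
    instead of each spore individually.
    """

    render_psf_sigma: float = 25.0
    pixel_width: float = 10.0
    average: bool = False
    n_fluorophores: int = 20000
    margin: float = 200.0  # nm of empty border around the structure

    def __post_init__(self) -> None:
        if self.render_psf_sigma <= 0 or self.pixel_width <= 0:
            raise ValueError("render PSF radius and pixel width must be "
                             "positive")


def _mean_params(fits):
    return dict(
        a=float(np.mean([f.a for f in fits])),
        b=float(np.mean([f.b for f in fits])),
        phi=float(np.mean([f.phi for f in fits])),
        q=float(np.mean([f.q for f in fits])),
        model_kind=fits[0].model_kind,
    )


def _render_one(params, spec: ReconstructionSpec, grid, center, seed=0):
    psf = PSFModel(spec.render_psf_sigma)
    if params["model_kind"] == "sphere_algebraic":
        shell = SphericalShell(center[0], center[1], params["a"], 1.0)
        img = render_shell_image(shell, psf, grid)
        return img / img.max() if img.max() > 0 else img
    sampler = {
        "sphere_mc": emc.uniform_ellipsoid_points,
        "ellipsoid_stretched": emc.stretched_sphere_points,
        "ellipsoid_uniform": emc.uniform_ellipsoid_points,
        "ellipsoid_polarized": emc.polarized_ellipsoid_points,
    }[params["model_kind"]]
    shell = emc.EllipsoidShell(
        x0=center[0], y0=center[1], a=params["a"], b=params["b"],
        phi=params["phi"], q=params["q"],
        n_fluorophores=spec.n_fluorophores)
    cloud = sampler(shell, np.random.default_rng(seed))
    img = emc.render_point_cloud_image(cloud, 1.0, psf, grid)
    return img / img.max() if img.max() > 0 else img


def reconstruct(spec: ReconstructionSpec, fits: list,
                seed: int = 0) -> np.ndarray:
    """Superresolved reconstruction from accepted fits.

    Each fit (or the population average, with ``spec.average``) is rendered
    with its fitted model at the small render PSF.  Raises if any supplied
    fit was rejected by quality control: rejected parameters are not
    trustworthy structure estimates.  Returns a normalised image (peak 1
    per shell, summed for multiple layers/spores).
    """
    fits = list(fits)
    if not fits:
        raise ValueError("reconstruct requires at least one fit")
    rejected = [f for f in fits if not f.accepted]
    if rejected:
        raise ValueError(
            f"{len(rejected)} rejected fit(s) supplied; reconstruction "
            "accepts quality-controlled fits only")
    if spec.average:
        params_list = [_mean_params(fits)]
    else:
        params_list = [dict(a=f.a, b=f.b, phi=f.phi, q=f.q,
                            model_kind=f.model_kind) for f in fits]
    reach = max(p["b"] for p in params_list) + 4 * spec.render_psf_sigma
    half = reach + spec.margin
    n = int(np.ceil(2 * half / spec.pixel_width))
    grid = PixelGrid(n, n, spec.pixel_width)
    center = grid.center
    img = np.zeros((n, n))
    for k, params in enumerate(params_list):
        img += _render_one(params, spec, grid, center, seed=seed + k)
    return img
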