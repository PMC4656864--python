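"""Model fitting, quality control and summaries for shell images.

The module is organised around two model classes in the statsmodels style:

* :class:`SphericalShellModel` — fits the five-parameter algebraic
  thin-shell image model (centre x0, y0; radius a; brightness per unit area
  I0; PSF radius sigma) to a background-corrected fitting region by
  nonlinear least squares.
* :class:`EllipsoidShellModel` — fits the Monte Carlo sphere / stretched /
  uniform / polarized ellipsoid image models by a least-squares iterative
  random search with common random numbers (one fixed fluorophore sample
  per candidate, so the objective is deterministic given the seed).

Both return a :class:`ShellFitResult` carrying the estimates, the
normalised residual

    epsilon = sum_j (I_j^data - I_j^fit)^2 / sum_j (I_j^data)^2,

the quality-control flag and a ``summary()`` table.  Quality control accepts
a fit iff its PSF radius is plausible: 0 < sigma_fit <= 2 * sigma_known.
Rejected candidates are typically overlapping or fragmented spores, whose
fitted sigma inflates.

Free functions mirror the underlying operations (``fit_sphere_algebraic``,
``fit_ellipsoid_mc``, ``residual_error``, ``quality_control``,
``equal_volume_radius``, ``summarize_frame``, ``summarize_experiment``,
``anisotropy_ratio``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from . import ellipsoid_mc as emc
from .segmentation import CandidateRegion, REGION_SIZE
from .shell_models import (PSFModel, PixelGrid, SphericalShell,
                           render_shell_image)

__all__ = [
    "SphericalShellModel",
    "EllipsoidShellModel",
    "ShellFitResult",
    "FrameSummary",
    "ExperimentSummary",
    "AnisotropyResult",
    "RandomSearchSchedule",
    "fit_sphere_algebraic",
    "fit_ellipsoid_mc",
    "residual_error",
    "quality_control",
    "equal_volume_radius",
    "summarize_frame",
    "summarize_experiment",
    "anisotropy_ratio",
]

MODEL_KINDS = ("sphere_algebraic", "sphere_mc", "ellipsoid_stretched",
               "ellipsoid_uniform", "ellipsoid_polarized")

_SAMPLERS = {
    "ellipsoid_stretched": emc.stretched_sphere_points,
    "ellipsoid_uniform": emc.uniform_ellipsoid_points,
    "ellipsoid_polarized": emc.polarized_ellipsoid_points,
    "sphere_mc": emc.uniform_ellipsoid_points,  # b = a: no rejection occurs
}


def residual_error(data: np.ndarray, fit: np.ndarray) -> float:
    """Normalised residual: sum of squared residuals over sum of squared
    data.  0 for a perfect fit, 1 for an all-zero fit."""
    data = np.asarray(data, dtype=float)
    fit = np.asarray(fit, dtype=float)
    if data.shape != fit.shape:
        raise ValueError("data and fit must have the same shape")
    denom = float(np.sum(data * data))
    if denom == 0.0:
        raise ValueError("residual error undefined for all-zero data")
    return float(np.sum((data - fit) ** 2) / denom)


def equal_volume_radius(a: float, b: float) -> float:
    """Radius of the sphere with the volume of the (a, a, b) ellipsoid:
    (a^2 b)^(1/3); lies between a and b."""
    if not (0 < a <= b):
        raise ValueError(f"require 0 < a <= b, got a={a}, b={b}")
    return float((a * a * b) ** (1.0 / 3.0))


@dataclass(frozen=True)
class AnisotropyResult:
    """Surface-tension anisotropy of a thin-walled pressurised prolate
    shell: gamma_ratio = circumferential / axial tension at the equator."""

    aspect: float
    gamma_ratio: float


def anisotropy_ratio(aspect: float) -> AnisotropyResult:
    """gamma_y / gamma_x at the equator = 4 R^2 / (3 R^2 + 1) for aspect
    ratio R = b/a >= 1.  Equals 1 for a sphere and tends to 4/3 as R grows,
    so an elongated shell is always under larger circumferential tension."""
    if aspect < 1:
        raise ValueError("aspect ratio must be >= 1")
    r2 = aspect * aspect
    return AnisotropyResult(aspect=float(aspect),
                            gamma_ratio=float(4.0 * r2 / (3.0 * r2 + 1.0)))


# ---------------------------------------------------------------------------
# results container


@dataclass
class ShellFitResult:
    """Fitted shell parameters for one candidate region.

    Lengths are object-frame nm; (x0, y0) are crop-local coordinates
    (pixel (0, 0) centre at (pixel_width/2, pixel_width/2)).  For spherical
    models b == a, phi == q == 0.  ``brightness`` is I0 (per unit area) for
    the algebraic model and per-fluorophore intensity for MC models.
    """

    model_kind: str
    x0: float
    y0: float
    a: float
    b: float
    phi: float
    q: float
    brightness: float
    sigma_fit: float
    epsilon: float
    accepted: bool = False
    reject_reason: str = ""
    candidate_index: int = -1
    frame_id: object = None
    param_se: dict = field(default_factory=dict)
    n_pixels: int = REGION_SIZE * REGION_SIZE

    @property
    def aspect_ratio(self) -> float:
        return self.b / self.a

    @property
    def radius(self) -> float:
        """Equal-volume radius (a^2 b)^(1/3); equals a for spheres."""
        return equal_volume_radius(self.a, self.b)

    def summary(self) -> str:
        lines = [
            f"Shell image fit ({self.model_kind})",
            "=" * 44,
            f"{'parameter':<14}{'estimate':>12}{'std err':>12}",
            "-" * 44,
        ]
        rows = [("x0 (nm)", self.x0), ("y0 (nm)", self.y0),
                ("a (nm)", self.a), ("b (nm)", self.b),
                ("phi (rad)", self.phi), ("q", self.q),
                ("brightness", self.brightness),
                ("sigma (nm)", self.sigma_fit)]
        for name, val in rows:
            se = self.param_se.get(name.split(" ")[0], None)
            se_s = f"{se:12.4g}" if se is not None else f"{'--':>12}"
            lines.append(f"{name:<14}{val:12.4g}{se_s}")
        lines += [
            "-" * 44,
            f"equal-volume radius: {self.radius:.2f} nm   "
            f"aspect b/a: {self.aspect_ratio:.4f}",
            f"residual epsilon: {self.epsilon:.4g}",
            f"QC: {'accepted' if self.accepted else 'REJECTED'}"
            + (f" ({self.reject_reason})" if self.reject_reason else ""),
        ]
        return "\n".join(lines)


def quality_control(result: ShellFitResult, psf: PSFModel) -> ShellFitResult:
    """Accept a fit iff its PSF radius is plausible:
    0 < sigma_fit <= 2 * sigma_known.  Overlapping or fragmented spores fit
    poorly and inflate sigma, so this single rule removes most false
    positives.  Returns an updated copy with the decision and reason."""
    if result.reject_reason and result.reject_reason not in (
            "sigma_nonpositive", "sigma_above_2x_known"):
        return replace(result, accepted=False)
    if not (result.sigma_fit > 0):
        return replace(result, accepted=False,
                       reject_reason="sigma_nonpositive")
    if result.sigma_fit > 2.0 * psf.sigma_known:
        return replace(result, accepted=False,
                       reject_reason="sigma_above_2x_known")
    return replace(result, accepted=True, reject_reason="")


# ---------------------------------------------------------------------------
# algebraic spherical model


class SphericalShellModel:
    """Five-parameter algebraic image model of a thin spherical shell,
    fitted to a background-corrected crop by nonlinear least squares.

    Parameters
    ----------
    region : CandidateRegion or ndarray
        Background-corrected fitting region (27 x 27 by default).
    psf : PSFModel
        Carries ``sigma_known`` for quality control and the starting sigma.
    """

    def __init__(self, region, psf: PSFModel, pixel_width: float = None):
        if isinstance(region, CandidateRegion):
            self.data = np.asarray(region.crop, dtype=float)
            self.pixel_width = region.pixel_width
            self.candidate_index = region.index
        else:
            self.data = np.asarray(region, dtype=float)
            self.pixel_width = pixel_width if pixel_width else 74.0
            self.candidate_index = -1
        if self.data.ndim != 2:
            raise ValueError("fitting region must be a 2D array")
        self.psf = psf
        self.grid = PixelGrid(*self.data.shape, pixel_width=self.pixel_width)

    def _render(self, x0, y0, a, i0, sigma):
        shell = SphericalShell(x0, y0, a, i0)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")  # truncation warnings during search
            return render_shell_image(shell, PSFModel(sigma), self.grid)

    def fit(self, a_init: float = None, center_init=None) -> ShellFitResult:
        """Least-squares fit of (x0, y0, a, I0, sigma).

        Initialisation: crop centre (the Hough centre) unless
        ``center_init`` is given; mid-range Hough radius (8 px) unless
        ``a_init``; analytic warm start for I0 from the total crop flux.
        """
        cx, cy = self.grid.center
        if center_init is not None:
            cx, cy = center_init
        a0 = a_init if a_init else 8.0 * self.pixel_width
        total = float(self.data.sum())
        if total <= 0:
            return ShellFitResult(
                model_kind="sphere_algebraic", x0=cx, y0=cy, a=a0, b=a0,
                phi=0.0, q=0.0, brightness=0.0, sigma_fit=0.0, epsilon=1.0,
                accepted=False, reject_reason="empty_data",
                candidate_index=self.candidate_index)
        i0_0 = total / (4.0 * math.pi * a0 * a0)
        s0 = self.psf.sigma
        theta0 = np.array([cx, cy, a0, i0_0, s0])
        w = self.pixel_width
        half_x, half_y = self.grid.extent[0], self.grid.extent[1]
        lower = [0.0, 0.0, 0.1 * w, 0.0, 0.05 * s0]
        upper = [half_x, half_y, max(half_x, half_y),
                 np.inf, 10.0 * self.psf.sigma_known]
        scale = np.array([w, w, w, i0_0 if i0_0 > 0 else 1.0, s0])

        def resid(theta):
            return (self._render(*theta) - self.data).ravel()

        try:
            sol = optimize.least_squares(
                resid, theta0, bounds=(lower, upper), x_scale=scale,
                xtol=1e-10, ftol=1e-10, gtol=1e-10)
        except Exception as exc:  # optimizer failure -> rejected result
            return ShellFitResult(
                model_kind="sphere_algebraic", x0=cx, y0=cy, a=a0, b=a0,
                phi=0.0, q=0.0, brightness=i0_0, sigma_fit=0.0, epsilon=1.0,
                accepted=False, reject_reason=f"optimizer_error:{exc}",
                candidate_index=self.candidate_index)
        x0, y0, a, i0, sigma = sol.x
        fit_img = self._render(*sol.x)
        eps = residual_error(self.data, fit_img)
        se = _standard_errors(sol, self.data.size)
        result = ShellFitResult(
            model_kind="sphere_algebraic", x0=float(x0), y0=float(y0),
            a=float(a), b=float(a), phi=0.0, q=0.0, brightness=float(i0),
            sigma_fit=float(sigma), epsilon=eps,
            candidate_index=self.candidate_index,
            param_se={k: v for k, v in zip(("x0", "y0", "a", "brightness",
                                            "sigma"), se)},
            n_pixels=self.data.size)
        if not sol.success:
            result.reject_reason = "optimizer_nonconvergence"
            return result
        return quality_control(result, self.psf)


def _standard_errors(sol, n_obs):
    """Approximate standard errors from the least-squares Jacobian."""
    try:
        _, s, vt = np.linalg.svd(sol.jac, full_matrices=False)
        s = np.where(s > 1e-12 * s.max(), s, np.inf)
        cov = (vt.T / s ** 2) @ vt
        dof = max(n_obs - sol.x.size, 1)
        sigma2 = 2.0 * sol.cost / dof
        return np.sqrt(np.diag(cov) * sigma2)
    except Exception:
        return [None] * sol.x.size


def fit_sphere_algebraic(region, psf: PSFModel, **kwargs) -> ShellFitResult:
    """Fit the algebraic spherical shell model to a candidate region."""
    return SphericalShellModel(region, psf).fit(**kwargs)


# ---------------------------------------------------------------------------
# Monte Carlo models: common random numbers + random search


class CommonRandomPool:
    """Fixed, lazily grown pool of unit-sphere points and uniform deviates.

    Rejection sampling scans the pool in order and keeps the first n
    accepted points, so the fluorophore sample — and hence the least-squares
    objective — is a deterministic function of the seed for any aspect
    ratio and polarity.
    """

    def __init__(self, seed, n: int):
        self.rng = np.random.default_rng(seed)
        self.n = n
        self.points = emc.sample_unit_sphere(max(4 * n, 256), self.rng)
        self.deviates = self.rng.uniform(size=len(self.points))

    def _grow(self):
        extra = emc.sample_unit_sphere(len(self.points), self.rng)
        self.points = np.vstack([self.points, extra])
        self.deviates = np.concatenate(
            [self.deviates, self.rng.uniform(size=len(extra))])

    def sample(self, a: float, b: float, q: float, kind: str) -> np.ndarray:
        """First n accepted points on the unrotated (a, a, b) ellipsoid."""
        if kind == "ellipsoid_stretched":
            return self.points[: self.n] * np.array([b, a, a])
        while True:
            pts = self.points * np.array([b, a, a])
            if kind in ("ellipsoid_uniform", "sphere_mc"):
                p = emc.retention_probability(pts, a, b)
            elif kind == "ellipsoid_polarized":
                p = emc.polar_bias_probability(pts, a, b, q)
            else:
                raise ValueError(f"unknown MC model kind: {kind}")
            accepted = pts[self.deviates < p]
            if len(accepted) >= self.n:
                return accepted[: self.n]
            self._grow()


@dataclass(frozen=True)
class RandomSearchSchedule:
    """Hyperparameters of the iterative random search.

    Per iteration every free shape parameter receives a Gaussian
    perturbation; a move is kept iff it lowers the pixel sum of squares at
    the analytically optimal brightness.  Step sizes decay geometrically,
    so the search anneals from exploration to refinement.
    """

    n_iterations: int = 300
    step_center: float = 5.0      # nm
    step_axes: float = 20.0       # nm
    step_phi: float = 0.1         # rad
    step_q: float = 0.1
    step_sigma: float = 5.0       # nm
    decay: float = 0.985
    explore_q_probability: float = 0.15  # global polarity moves


class EllipsoidShellModel:
    """Monte Carlo shell image model fitted by iterative random search.

    ``model_kind`` selects the fluorophore distribution: ``sphere_mc``,
    ``ellipsoid_stretched``, ``ellipsoid_uniform`` or
    ``ellipsoid_polarized`` (the only kind with a free polarity q).

    One fluorophore sample (default n = 2500, drawn from ``seed``) is reused
    across the whole search (common random numbers), which removes Monte
    Carlo noise from the objective so simple hill descent converges.
    """

    def __init__(self, region, psf: PSFModel, model_kind: str = "ellipsoid_polarized",
                 seed=0, n_fluorophores: int = 2500,
                 schedule: RandomSearchSchedule = None,
                 pixel_width: float = None):
        if model_kind not in _SAMPLERS:
            raise ValueError(f"unknown model kind {model_kind!r}; "
                             f"choose from {sorted(_SAMPLERS)}")
        if isinstance(region, CandidateRegion):
            self.data = np.asarray(region.crop, dtype=float)
            self.pixel_width = region.pixel_width
            self.candidate_index = region.index
        else:
            self.data = np.asarray(region, dtype=float)
            self.pixel_width = pixel_width if pixel_width else 74.0
            self.candidate_index = -1
        self.psf = psf
        self.model_kind = model_kind
        self.seed = seed
        self.n_fluorophores = n_fluorophores
        self.schedule = schedule or RandomSearchSchedule()
        self.grid = PixelGrid(*self.data.shape, pixel_width=self.pixel_width)
        self._pool = CommonRandomPool(seed, n_fluorophores)

    # parameter vector: (x0, y0, a, b, phi, q, sigma); the per-fluorophore
    # brightness is linear in the model and profiled out analytically

    def _render(self, theta):
        x0, y0, a, b, phi, q, sigma = theta
        pts = self._pool.sample(a, b, q, self.model_kind)
        c, s = math.cos(phi), math.sin(phi)
        placed = np.column_stack((
            c * pts[:, 0] - s * pts[:, 1] + x0,
            s * pts[:, 0] + c * pts[:, 1] + y0,
            pts[:, 2]))
        return emc.render_point_cloud_image(
            placed, 1.0, PSFModel(sigma), self.grid)

    def _objective(self, theta):
        """Sum of squares at the best non-negative brightness scale."""
        model = self._render(theta)
        denom = float(np.sum(model * model))
        scale = max(float(np.sum(self.data * model)) / denom, 0.0) \
            if denom > 0 else 0.0
        return float(np.sum((self.data - scale * model) ** 2)), scale

    def _moment_shape(self) -> tuple[float, float]:
        """(aspect ratio, orientation) warm start from the intensity
        second-moment matrix of the crop."""
        w = self.data
        tot = w.sum()
        if tot <= 0:
            return 1.0, 0.0
        ys, xs = np.mgrid[0: w.shape[0], 0: w.shape[1]]
        mx = (w * xs).sum() / tot
        my = (w * ys).sum() / tot
        mxx = (w * (xs - mx) ** 2).sum() / tot
        myy = (w * (ys - my) ** 2).sum() / tot
        mxy = (w * (xs - mx) * (ys - my)).sum() / tot
        lam = np.linalg.eigvalsh(np.array([[mxx, mxy], [mxy, myy]]))
        aspect = math.sqrt(max(lam[1], 1e-12) / max(lam[0], 1e-12))
        phi = 0.5 * math.atan2(2.0 * mxy, mxx - myy) % math.pi
        return aspect, phi

    def _canonicalize(self, theta):
        x0, y0, a, b, phi, q, sigma = theta
        if a > b:  # enforce b >= a, rotating phi by pi/2
            a, b = b, a
            phi = phi + math.pi / 2.0
        phi = phi % math.pi
        q = min(max(q, -1.0), 1.0)
        a = max(a, 0.1 * self.pixel_width)
        b = max(b, a)
        sigma = min(max(sigma, 0.05 * self.psf.sigma),
                    10.0 * self.psf.sigma_known)
        return np.array([x0, y0, a, b, phi, q, sigma])

    def fit(self, start: ShellFitResult = None) -> ShellFitResult:
        """Run the random search; ``start`` (e.g. a simpler model's optimum)
        overrides the default warm start from the algebraic sphere fit."""
        if start is None:
            start = SphericalShellModel(self.data, self.psf,
                                        pixel_width=self.pixel_width).fit()
        q0 = start.q if self.model_kind == "ellipsoid_polarized" else 0.0
        sigma0 = start.sigma_fit if start.sigma_fit > 0 else self.psf.sigma
        free_q = self.model_kind == "ellipsoid_polarized"
        free_shape = self.model_kind != "sphere_mc"
        if start.b > start.a:       # warm start from an ellipsoid optimum
            a0, b0, phi0 = start.a, start.b, start.phi
        elif free_shape:
            # split the sphere fit's radius into axes along the crop's
            # principal axes, preserving the equal-volume radius
            aspect, phi0 = self._moment_shape()
            a0 = start.a / aspect ** (1.0 / 3.0)
            b0 = start.a * aspect ** (2.0 / 3.0)
        else:
            a0, b0, phi0 = start.a, start.a, 0.0
        theta = self._canonicalize(np.array([
            start.x0, start.y0, a0, b0, phi0, q0, sigma0]))
        best, bright = self._objective(theta)

        sch = self.schedule
        steps = np.array([sch.step_center, sch.step_center, sch.step_axes,
                          sch.step_axes, sch.step_phi, sch.step_q,
                          sch.step_sigma])
        rng = np.random.default_rng(
            np.random.SeedSequence([int(self.seed) & 0x7FFFFFFF, 0xE11]))
        for it in range(sch.n_iterations):
            scale = sch.decay ** it
            prop = theta + rng.normal(size=7) * steps * scale
            if free_q and rng.uniform() < sch.explore_q_probability:
                # polarity changes the retained sample discretely, making
                # the objective rugged in q: mix in global moves
                prop[5] = rng.uniform(-1.0, 1.0)
            if not free_shape:
                prop[3] = prop[2]  # b tracks a for the MC sphere
                prop[4] = theta[4]
            if not free_q:
                prop[5] = theta[5]
            prop = self._canonicalize(prop)
            val, scale_b = self._objective(prop)
            if val < best:
                theta, best, bright = prop, val, scale_b
        x0, y0, a, b, phi, q, sigma = theta
        eps = residual_error(self.data, bright * self._render(theta))
        result = ShellFitResult(
            model_kind=self.model_kind, x0=float(x0), y0=float(y0),
            a=float(a), b=float(b), phi=float(phi), q=float(q),
            brightness=float(bright), sigma_fit=float(sigma),
            epsilon=eps, candidate_index=self.candidate_index,
            n_pixels=self.data.size)
        if abs(b - a) < 1e-3 * a and self.model_kind != "sphere_mc":
            result.reject_reason = ""  # phi unidentifiable; flag below
            result.param_se["phi"] = float("inf")
        return quality_control(result, self.psf)


def fit_ellipsoid_mc(region, psf: PSFModel,
                     model_kind: str = "ellipsoid_polarized", rng=0,
                     **kwargs) -> ShellFitResult:
    """Fit a Monte Carlo shell model to a candidate region by iterative
    random search (``rng`` may be a seed or Generator supplying the seed)."""
    seed = rng if not isinstance(rng, np.random.Generator) else int(
        rng.integers(2 ** 31))
    start = kwargs.pop("start", None)
    return EllipsoidShellModel(region, psf, model_kind=model_kind, seed=seed,
                               **kwargs).fit(start=start)


# ---------------------------------------------------------------------------
# summaries


@dataclass
class FrameSummary:
    """Unweighted means over the accepted fits of one field of view."""

    n_candidates: int = 0
    n_accepted: int = 0
    mean_radius: float = float("nan")
    mean_aspect_ratio: float = float("nan")
    mean_polarity: float = float("nan")
    mean_sigma: float = float("nan")
    mean_epsilon: float = float("nan")
    frame_id: object = None

    @property
    def empty(self) -> bool:
        return self.n_accepted == 0


@dataclass
class ExperimentSummary:
    """Across-field means and standard deviations of the per-field
    summaries.  The field-to-field standard deviation (over fields, not
    spores) estimates the random error of the method."""

    frames: list
    n_fields: int
    mean_radius: float
    std_radius: float
    mean_aspect_ratio: float
    std_aspect_ratio: float
    mean_polarity: float
    std_polarity: float

    def summary(self) -> str:
        lines = [
            "Experiment summary",
            "=" * 50,
            f"fields: {self.n_fields}   accepted spores: "
            f"{sum(f.n_accepted for f in self.frames)}",
            f"radius (nm):       {self.mean_radius:9.2f} +/- "
            f"{self.std_radius:.2f}",
        ]
        if np.isfinite(self.mean_aspect_ratio):
            lines.append(f"aspect ratio b/a:  {self.mean_aspect_ratio:9.4f}"
                         f" +/- {self.std_aspect_ratio:.4f}")
        if np.isfinite(self.mean_polarity):
            lines.append(f"polarity q:        {self.mean_polarity:9.4f}"
                         f" +/- {self.std_polarity:.4f}")
        return "\n".join(lines)


def summarize_frame(results: list, frame_id=None) -> FrameSummary:
    """Unweighted means of accepted fits; radii enter as the equal-volume
    radius (a^2 b)^(1/3), which equals a for spherical models."""
    accepted = [r for r in results if r.accepted]
    s = FrameSummary(n_candidates=len(results), n_accepted=len(accepted),
                     frame_id=frame_id)
    if not accepted:
        return s
    s.mean_radius = float(np.mean([r.radius for r in accepted]))
    s.mean_aspect_ratio = float(np.mean([r.aspect_ratio for r in accepted]))
    s.mean_polarity = float(np.mean([r.q for r in accepted]))
    s.mean_sigma = float(np.mean([r.sigma_fit for r in accepted]))
    s.mean_epsilon = float(np.mean([r.epsilon for r in accepted]))
    return s


def summarize_experiment(frames: list) -> ExperimentSummary:
    """Across-field mean and standard deviation (ddof=1) of each per-field
    mean.  Requires >= 3 fields so the standard deviation is meaningful."""
    populated = [f for f in frames if not f.empty]
    if len(frames) < 3:
        raise ValueError("experiment summary requires >= 3 fields")
    def stats(vals):
        vals = [v for v in vals if np.isfinite(v)]
        if not vals:
            return float("nan"), float("nan")
        return (float(np.mean(vals)),
                float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"))
    mr, sr = stats([f.mean_radius for f in populated])
    ma, sa = stats([f.mean_aspect_ratio for f in populated])
    mq, sq = stats([f.mean_polarity for f in populated])
    return ExperimentSummary(frames=list(frames), n_fields=len(frames),
                             mean_radius=mr, std_radius=sr,
                             mean_aspect_ratio=ma, std_aspect_ratio=sa,
                             mean_polarity=mq, std_polarity=sq)
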