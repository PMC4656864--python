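"""Synthetic calibration data: widefield images of fluorophore-decorated
shells with a defocus-dependent PSF and camera noise.

The simulator validates the fitting pipeline against specimens of exactly
known geometry.  Spherical shells of known radius (default exactly 500 nm)
are decorated with fluorophores (default 10,000 per shell, emulating
homogeneous labelling) and imaged with a PSF that broadens with defocus —
deliberately *more* realistic than the single-sigma analysis model, so
recovering the true radius measures the bias of the analysis, not a
tautology.  Two defocus models are available:

* ``disc`` (default) — geometric-optics defocus: the image of a
  fluorophore at depth z is its in-focus Gaussian (radius
  sigma0 = 0.21 * wavelength / NA) displaced uniformly over the blur disc
  of radius |z| * tan(alpha), alpha = asin(NA / n_imm) the marginal-ray
  angle of the objective (alpha ~ 59 deg at NA 1.3 in oil, n_imm = 1.515).
  Out-of-focus light is flattened into a broad halo, as a high-NA
  widefield image of a 3D object shows.
* ``gaussian`` — each fluorophore rendered as a single flux-conserving
  Gaussian of width ``defocus_psf_sigma(z)``, the RMS-matched equivalent
  of the disc model; smooth and convenient for semi-analytic oracles.

Poisson shot noise, Gaussian read noise and 12-bit quantisation emulate
the CCD camera.  Every simulated frame is paired with a ground-truth
manifest (one row per shell) so tests and the calibration analysis can
compare fit against truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import ellipsoid_mc as emc
from .segmentation import Frame, REGION_SIZE
from .shell_models import PSFModel, PixelGrid

__all__ = [
    "SimulationSpec",
    "defocus_psf_sigma",
    "in_focus_sigma",
    "known_psf_radius",
    "simulate_calibration_frame",
    "simulate_experiment",
    "generate_test_fixtures",
]

N_IMMERSION = 1.515

_CLOUD_SAMPLERS = {
    "sphere": None,
    "stretched": emc.stretched_sphere_points,
    "uniform": emc.uniform_ellipsoid_points,
    "polarized": emc.polarized_ellipsoid_points,
}


def in_focus_sigma(wavelength: float = 500.0, na: float = 1.3) -> float:
    """Gaussian-approximation PSF radius at focus: 0.21 * lambda / NA."""
    return 0.21 * wavelength / na


def known_psf_radius(wavelength: float = 500.0, na: float = 1.3) -> float:
    """Calibrated instrument PSF radius for quality control.

    Half the Rayleigh resolution 0.61 * lambda / NA — the rule of thumb
    used to state a microscope's PSF radius from its resolution (~117 nm
    for 500 nm emission at NA 1.3).  This is the value a user would quote
    for the instrument, deliberately coarser than the in-focus Gaussian
    waist: fitted sigma on real 3D specimens carries specimen structure
    and defocus as well as instrument blur.
    """
    return 0.5 * 0.61 * wavelength / na


def defocus_psf_sigma(z, psf0: PSFModel = None, wavelength: float = 500.0,
                      na: float = 1.3, n_immersion: float = N_IMMERSION):
    """Gaussian-equivalent PSF radius at defocus z (nm).

    sigma(z) = sqrt(sigma0^2 + (kappa z)^2), combining the diffraction
    width at focus (sigma0 from ``psf0`` if given, else 0.21 * wavelength /
    NA) with the geometric defocus blur of the objective's light cone:
    a point at defocus z spreads over a disc of radius z * tan(alpha),
    alpha = asin(NA / n_immersion), whose RMS-matched Gaussian radius is
    kappa * z with kappa = tan(alpha) / 2.  For a 1.3 NA oil objective
    kappa ~ 0.84, so out-of-focus light is strongly flattened — the
    dominant effect a high-NA widefield image of a 3D object shows.  Even
    in z, monotone increasing in |z|, sigma(0) = sigma0, and equal to
    sigma0 * sqrt(2) at the characteristic depth z = sigma0 / kappa.
    """
    sigma0 = psf0.sigma if psf0 is not None else in_focus_sigma(wavelength, na)
    kappa = math.tan(math.asin(na / n_immersion)) / 2.0
    z = np.asarray(z, dtype=float)
    out = np.sqrt(sigma0 ** 2 + (kappa * z) ** 2)
    return out if out.ndim else float(out)


@dataclass
class SimulationSpec:
    """Ground truth and instrument parameters for one simulated experiment.

    Defaults reproduce the calibration conditions: spherical shells of
    radius exactly 500 nm, 10,000 fluorophores each, 1.3 NA oil objective,
    500 nm emission, 74 nm pixels with 100% fill factor, 12-bit camera.
    """

    kind: str = "sphere"           # sphere | stretched | uniform | polarized
    radius: float = 500.0          # sphere radius / semiminor axis a (nm)
    semimajor: float = None        # b (nm); None -> radius (sphere)
    phi: float = 0.0
    q: float = 0.0
    n_fluorophores: int = 10000
    wavelength: float = 500.0      # emission (nm)
    na: float = 1.3
    n_immersion: float = N_IMMERSION
    pixel_width: float = 74.0      # nm on the specimen
    n_shells: int = 49
    frame_shape: tuple = None      # (rows, cols); None -> sized to n_shells
    min_separation_px: int = 27
    photons_per_fluorophore: float = 50.0
    read_noise: float = 2.0        # counts rms
    bit_depth: int = 12
    noise: bool = True
    defocus_model: str = "disc"    # disc | gaussian
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _CLOUD_SAMPLERS:
            raise ValueError(f"unknown shell kind {self.kind!r}")
        if self.defocus_model not in ("disc", "gaussian"):
            raise ValueError("defocus_model must be 'disc' or 'gaussian'")
        for name in ("radius", "wavelength", "na", "pixel_width",
                     "photons_per_fluorophore"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.semimajor is None:
            self.semimajor = float(self.radius)
        if self.semimajor < self.radius:
            raise ValueError("semimajor axis must be >= radius (semiminor)")

    @property
    def sigma0(self) -> float:
        return in_focus_sigma(self.wavelength, self.na)

    @property
    def max_count(self) -> int:
        return 2 ** self.bit_depth - 1


def _place_centers(spec: SimulationSpec, rng, shape):
    """Jittered grid placement guaranteeing >= min_separation_px spacing."""
    n_rows, n_cols = shape
    margin = REGION_SIZE // 2 + 2
    sep = spec.min_separation_px
    cell = sep + 8  # jitter head-room inside each cell
    rows_fit = (n_rows - 2 * margin) // cell
    cols_fit = (n_cols - 2 * margin) // cell
    if rows_fit * cols_fit < spec.n_shells:
        raise ValueError(
            f"frame {shape} too small for {spec.n_shells} shells at "
            f">= {sep} px separation")
    cells = [(i, j) for i in range(rows_fit) for j in range(cols_fit)]
    idx = rng.choice(len(cells), size=spec.n_shells, replace=False)
    jit = (cell - sep) / 2.0
    centers = []
    for k in idx:
        i, j = cells[k]
        r = margin + i * cell + cell / 2 + rng.uniform(-jit, jit)
        c = margin + j * cell + cell / 2 + rng.uniform(-jit, jit)
        centers.append((r, c))
    return centers


def _default_shape(spec: SimulationSpec):
    margin = REGION_SIZE // 2 + 2
    cell = spec.min_separation_px + 8
    side = math.ceil(math.sqrt(spec.n_shells))
    n = 2 * margin + side * cell
    return (n, n)


def _shell_cloud(spec: SimulationSpec, x0, y0, rng):
    shell = emc.EllipsoidShell(
        x0=x0, y0=y0, a=spec.radius, b=spec.semimajor, phi=spec.phi,
        q=spec.q, n_fluorophores=spec.n_fluorophores)
    sampler = _CLOUD_SAMPLERS[spec.kind]
    if sampler is None:  # sphere: plain trig-method sampling
        pts = spec.radius * emc.sample_unit_sphere(spec.n_fluorophores, rng)
        return pts + np.array([x0, y0, 0.0])
    return sampler(shell, rng)


def _render_disc_model(spec: SimulationSpec, clouds, shape, rng, n_sub=3):
    """Geometric-defocus rendering: displace each fluorophore uniformly on
    its blur disc of radius |z| tan(alpha), deposit all fluorophores into a
    sub-pixel histogram and convolve once with the in-focus Gaussian."""
    from scipy.ndimage import gaussian_filter
    w = spec.pixel_width
    tan_alpha = math.tan(math.asin(spec.na / spec.n_immersion))
    pts = np.concatenate(clouds)
    n = len(pts)
    disc_r = np.abs(pts[:, 2]) * tan_alpha * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
    x = pts[:, 0] + disc_r * np.cos(theta)
    y = pts[:, 1] + disc_r * np.sin(theta)
    sub_w = w / n_sub
    hist, _, _ = np.histogram2d(
        y, x, bins=(shape[0] * n_sub, shape[1] * n_sub),
        range=((0, shape[0] * w), (0, shape[1] * w)))
    blurred = gaussian_filter(hist, sigma=spec.sigma0 / sub_w,
                              mode="constant")
    # sum sub-pixels back to camera pixels: counts are conserved
    return blurred.reshape(shape[0], n_sub, shape[1], n_sub).sum(axis=(1, 3))


def _render_gaussian_model(spec: SimulationSpec, clouds, centers, shape):
    """Per-fluorophore Gaussian of width defocus_psf_sigma(z), rendered in
    a local window per shell."""
    w = spec.pixel_width
    image = np.zeros(shape)
    sigma_max = defocus_psf_sigma(spec.radius, wavelength=spec.wavelength,
                                  na=spec.na, n_immersion=spec.n_immersion)
    half = REGION_SIZE // 2 + int(math.ceil(3.0 * sigma_max / w))
    for cloud, (crow, ccol) in zip(clouds, centers):
        sig = defocus_psf_sigma(cloud[:, 2], wavelength=spec.wavelength,
                                na=spec.na, n_immersion=spec.n_immersion)
        r0 = max(int(round(crow)) - half, 0)
        c0 = max(int(round(ccol)) - half, 0)
        r1 = min(int(round(crow)) + half + 1, shape[0])
        c1 = min(int(round(ccol)) + half + 1, shape[1])
        image[r0:r1, c0:c1] += emc.render_point_cloud_image(
            cloud - np.array([c0 * w, r0 * w, 0.0]), 1.0,
            PSFModel(spec.sigma0), PixelGrid(r1 - r0, c1 - c0, w),
            sigma=sig, use_z=False)
    return image


def simulate_calibration_frame(spec: SimulationSpec, rng=None):
    """Simulate one field of well-separated shells.

    Fluorophores are placed on each shell, imaged with the chosen defocus
    model (see module docstring), and the expected photon counts receive
    Poisson shot noise plus Gaussian read noise before quantisation to the
    camera bit depth.  Returns ``(Frame, manifest)`` where the manifest is
    a DataFrame of the true parameters, one row per shell.
    """
    rng = emc.as_rng(spec.seed if rng is None else rng)
    shape = spec.frame_shape or _default_shape(spec)
    centers = _place_centers(spec, rng, shape)
    w = spec.pixel_width
    clouds, rows = [], []
    for k, (crow, ccol) in enumerate(centers):
        x0, y0 = (ccol + 0.5) * w, (crow + 0.5) * w
        clouds.append(_shell_cloud(spec, x0, y0, rng))
        rows.append(dict(shell=k, center_row=crow, center_col=ccol,
                         x0_nm=x0, y0_nm=y0, radius_nm=spec.radius,
                         semimajor_nm=spec.semimajor, phi=spec.phi, q=spec.q,
                         kind=spec.kind, n_fluorophores=spec.n_fluorophores))
    if spec.defocus_model == "disc":
        image = _render_disc_model(spec, clouds, shape, rng)
    else:
        image = _render_gaussian_model(spec, clouds, centers, shape)
    expected = image * spec.photons_per_fluorophore
    if spec.noise:
        counts = rng.poisson(expected).astype(float)
        counts += rng.normal(0.0, spec.read_noise, size=shape)
        counts = np.clip(np.round(counts), 0, spec.max_count)
    else:
        counts = np.clip(expected, 0, None)
    frame = Frame(image=counts, pixel_width=w,
                  metadata={"simulated": True, "seed": spec.seed,
                            "kind": spec.kind})
    manifest = pd.DataFrame(rows)
    return frame, manifest


def simulate_experiment(spec: SimulationSpec, n_fields: int = 3):
    """Simulate several independent fields from one spec; field i uses a
    child seed spawned from ``spec.seed`` so fields are independent but the
    whole experiment is reproducible."""
    frames, manifests = [], []
    ss = np.random.SeedSequence(spec.seed)
    for i, child in enumerate(ss.spawn(n_fields)):
        frame, manifest = simulate_calibration_frame(
            spec, rng=np.random.default_rng(child))
        frame.metadata["frame_id"] = i
        manifest.insert(0, "frame_id", i)
        frames.append(frame)
        manifests.append(manifest)
    return frames, pd.concat(manifests, ignore_index=True)


def generate_test_fixtures(out_dir, seed: int = 0, kinds=None,
                           n_fluorophores: int = 2500):
    """Write one small frame + manifest per shell model kind.

    Fixtures are single-shell 100 x 100-pixel frames used by the test suite
    and the documentation examples; all are synthetic.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from .io import write_frame  # local import to avoid a cycle
    specs = {
        "sphere": dict(kind="sphere", radius=500.0),
        "stretched": dict(kind="stretched", radius=450.0, semimajor=750.0,
                          phi=0.4),
        "uniform": dict(kind="uniform", radius=450.0, semimajor=750.0,
                        phi=0.4),
        "polarized_q0.4": dict(kind="polarized", radius=450.0,
                               semimajor=750.0, phi=0.4, q=0.4),
        "polarized_q0.8": dict(kind="polarized", radius=450.0,
                               semimajor=750.0, phi=0.4, q=0.8),
    }
    if kinds is not None:
        specs = {k: v for k, v in specs.items()
                 if v["kind"] in kinds or k in kinds}
    paths = {}
    for i, (name, kw) in enumerate(sorted(specs.items())):
        spec = SimulationSpec(n_shells=1, frame_shape=(100, 100),
                              n_fluorophores=n_fluorophores,
                              seed=seed + i, **kw)
        frame, manifest = simulate_calibration_frame(spec)
        tif = out_dir / f"fixture_{name}.tif"
        csv = out_dir / f"fixture_{name}.csv"
        write_frame(frame, tif)
        manifest.to_csv(csv, index=False)
        paths[name] = (tif, csv)
    return paths
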