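"""Monte Carlo point-cloud models for spheroidal fluorescent shells.

The image of a shell is simulated by scattering fluorophores on its surface
and summing a Gaussian point-source image per fluorophore (the spherically
symmetric Gaussian PSF of the algebraic model, so a fluorophore's
contribution falls off with its defocus as well as in-plane distance).
Three surface
distributions are provided for a prolate ellipsoid of revolution with its
long axis in the object plane (semiminor a, semimajor b, surface
x^2/b^2 + y^2/a^2 + z^2/a^2 = 1 before rotation):

* stretched sphere — uniform points on the unit sphere linearly stretched
  onto the ellipsoid (x = b x', y = a y', z = a z').  The stretch crowds
  fluorophores toward the poles, giving polar-bright images.
* uniform ellipsoid — stretched-sphere points thinned by rejection with
  retention probability p = g/gmax = a * sqrt(x^2/b^4 + y^2/a^4 + z^2/a^4),
  the local area scale factor of the stretch, yielding uniform density per
  unit surface area.
* polarized ellipsoid — uniform-ellipsoid sampling with an extra bias
  pb = C * p * (1 - q sin t), where sin t = sqrt(y^2+z^2)/|r| vanishes at
  the poles.  Polarity q > 0 enriches the poles, q < 0 the equator
  (C = 1 for q >= 0, 1/(1-q) for q < 0); q <= 1 keeps pb in [0, 1].

Rejection sampling resamples until exactly ``n_fluorophores`` points are
retained, so image brightness stays n * I for every aspect ratio and
polarity.  Point clouds are arrays of shape (n, 3) in object-frame nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .shell_models import PSFModel, PixelGrid

__all__ = [
    "EllipsoidShell",
    "as_rng",
    "sample_unit_sphere",
    "stretched_sphere_points",
    "uniform_ellipsoid_points",
    "polarized_ellipsoid_points",
    "render_point_cloud_image",
    "retention_probability",
    "polar_bias_probability",
]


@dataclass(frozen=True)
class EllipsoidShell:
    """Prolate ellipsoidal shell in the object plane.

    Centre (x0, y0) nm; semiminor axis ``a`` <= semimajor axis ``b`` (nm);
    major-axis orientation ``phi`` (radians in [0, pi)); polarity ``q``
    (<= 1; positive = polar bias, negative = equatorial bias); per-fluorophore
    intensity ``intensity``; ``n_fluorophores`` points per rendering.
    """

    x0: float
    y0: float
    a: float
    b: float
    phi: float = 0.0
    q: float = 0.0
    intensity: float = 1.0
    n_fluorophores: int = 2500

    def __post_init__(self) -> None:
        if not (0 < self.a <= self.b):
            raise ValueError(f"require 0 < a <= b, got a={self.a}, b={self.b}")
        if self.q > 1:
            raise ValueError("polarity q must be <= 1 (retention probability "
                             "would be negative at the equator)")
        if self.n_fluorophores < 1:
            raise ValueError("n_fluorophores must be >= 1")

    @property
    def aspect_ratio(self) -> float:
        return self.b / self.a


def as_rng(rng) -> np.random.Generator:
    """Coerce a seed or Generator into a numpy Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def sample_unit_sphere(n: int, rng) -> np.ndarray:
    """n points uniform on the unit sphere by the trig method: azimuth
    uniform on [0, 2 pi), cos(polar angle) uniform on [-1, 1]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = as_rng(rng)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    u = rng.uniform(-1.0, 1.0, size=n)
    sin_theta = np.sqrt(1.0 - u * u)
    return np.column_stack((sin_theta * np.cos(phi), sin_theta * np.sin(phi), u))


def _stretch(unit_points: np.ndarray, a: float, b: float) -> np.ndarray:
    """Map unit-sphere points onto the unrotated ellipsoid surface."""
    return unit_points * np.array([b, a, a])


def _place(points: np.ndarray, shell: EllipsoidShell) -> np.ndarray:
    """Rotate about z by phi (active) and translate to the shell centre."""
    c, s = math.cos(shell.phi), math.sin(shell.phi)
    x = c * points[:, 0] - s * points[:, 1] + shell.x0
    y = s * points[:, 0] + c * points[:, 1] + shell.y0
    return np.column_stack((x, y, points[:, 2]))


def retention_probability(points: np.ndarray, a: float, b: float) -> np.ndarray:
    """p = g/gmax = a * sqrt(x^2/b^4 + y^2/a^4 + z^2/a^4) for points on the
    unrotated ellipsoid surface: the stretch's local area scale factor,
    normalised to 1 at the equator (a/b at the poles)."""
    x, y, z = points[:, 0], points[:, 1], points[:, 2]
    return a * np.sqrt(x * x / b ** 4 + y * y / a ** 4 + z * z / a ** 4)


def polar_bias_probability(points: np.ndarray, a: float, b: float,
                           q: float) -> np.ndarray:
    """Biased retention pb = C * (g/gmax) * (1 - q sin t) with
    sin t = sqrt(y^2 + z^2) / |r| (0 at the poles, 1 at the equator)."""
    if q > 1:
        raise ValueError("q must be <= 1")
    p = retention_probability(points, a, b)
    x, y, z = points[:, 0], points[:, 1], points[:, 2]
    norm = np.sqrt(x * x + y * y + z * z)
    sin_t = np.sqrt(y * y + z * z) / norm
    c = 1.0 if q >= 0 else 1.0 / (1.0 - q)
    return c * p * (1.0 - q * sin_t)


def stretched_sphere_points(shell: EllipsoidShell, rng) -> np.ndarray:
    """Fluorophore positions for the stretched-sphere model (denser at the
    poles by the anisotropic stretch)."""
    rng = as_rng(rng)
    pts = _stretch(sample_unit_sphere(shell.n_fluorophores, rng),
                   shell.a, shell.b)
    return _place(pts, shell)


def _rejection_sample(shell: EllipsoidShell, rng, prob_fn) -> np.ndarray:
    """Draw stretched-sphere points and thin them by prob_fn, resampling
    until exactly n_fluorophores are retained."""
    rng = as_rng(rng)
    n = shell.n_fluorophores
    kept: list[np.ndarray] = []
    n_kept = 0
    batch = max(4 * n, 256)
    while n_kept < n:
        pts = _stretch(sample_unit_sphere(batch, rng), shell.a, shell.b)
        p = prob_fn(pts)
        sel = pts[rng.uniform(size=batch) < p]
        kept.append(sel)
        n_kept += len(sel)
    return _place(np.concatenate(kept)[:n], shell)


def uniform_ellipsoid_points(shell: EllipsoidShell, rng) -> np.ndarray:
    """Fluorophore positions uniform per unit surface area of the ellipsoid."""
    return _rejection_sample(
        shell, rng, lambda pts: retention_probability(pts, shell.a, shell.b))


def polarized_ellipsoid_points(shell: EllipsoidShell, rng) -> np.ndarray:
    """Fluorophore positions with polar (q > 0) or equatorial (q < 0) bias
    on top of uniform surface density; q = 0 reduces to the uniform model."""
    return _rejection_sample(
        shell, rng,
        lambda pts: polar_bias_probability(pts, shell.a, shell.b, shell.q))


def render_point_cloud_image(cloud: np.ndarray, intensity, psf: PSFModel,
                             grid: PixelGrid, n_sub: int = 3,
                             sigma=None, use_z: bool = True) -> np.ndarray:
    """Sum of Gaussian point-source images over a fluorophore cloud.

    With ``use_z=True`` (default) the PSF is the spherically symmetric
    Gaussian evaluated at the 3D displacement, i.e. each fluorophore
    contributes a 2D Gaussian attenuated by exp(-z^2 / 2 sigma^2) — the
    same PSF under which the algebraic thin-shell model is derived, so the
    Monte Carlo sphere image converges to it exactly as n grows.  With
    ``use_z=False`` the z coordinate is ignored and the image sum
    approaches n * intensity (used by the calibration simulator, which
    encodes defocus in a per-fluorophore ``sigma`` array instead).

    Pixel values are footprint integrals (n_sub x n_sub sub-pixel mean
    times pixel area).  The Gaussian is separable, so the image is
    assembled from per-axis factor matrices with one einsum.
    """
    cloud = np.asarray(cloud, dtype=float)
    if cloud.ndim != 2 or cloud.shape[1] != 3 or len(cloud) == 0:
        raise ValueError("cloud must be a non-empty (n, 3) array")
    n = len(cloud)
    sig = np.full(n, psf.sigma) if sigma is None else np.broadcast_to(
        np.asarray(sigma, dtype=float), (n,))
    if np.any(sig <= 0):
        raise ValueError("sigma must be positive")
    inten = np.broadcast_to(np.asarray(intensity, dtype=float), (n,))

    xs, ys = grid.subpixel_coords(n_sub)
    inv2s2 = 1.0 / (2.0 * sig * sig)
    weight = np.exp(-cloud[:, 2] ** 2 * inv2s2) if use_z else np.ones(n)
    # per-axis Gaussian factors; the 1/(2 pi s^2) normalisation and the
    # defocus attenuation are split between the axes
    norm = np.sqrt(inten * weight) / np.sqrt(2.0 * math.pi * sig * sig)
    gx = norm[:, None] * np.exp(-((xs[None, :] - cloud[:, 0, None]) ** 2)
                                * inv2s2[:, None])
    gy = norm[:, None] * np.exp(-((ys[None, :] - cloud[:, 1, None]) ** 2)
                                * inv2s2[:, None])
    sub = np.einsum("ny,nx->yx", gy, gx)
    img = sub.reshape(grid.n_rows, n_sub, grid.n_cols, n_sub).mean(axis=(1, 3))
    return img * grid.pixel_width ** 2
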