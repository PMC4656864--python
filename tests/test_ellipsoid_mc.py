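"""Monte Carlo shell samplers and renderer: uniformity, rejection rules,
flux and determinism."""

import math

import numpy as np
import pytest
from scipy.interpolate import interp1d
from scipy.stats import chi2

from elmfit import (EllipsoidShell, PixelGrid,
                    point_source_image, render_point_cloud_image,
                    render_shell_image, sample_unit_sphere,
                    stretched_sphere_points, uniform_ellipsoid_points,
                    polarized_ellipsoid_points, SphericalShell)
from elmfit.ellipsoid_mc import polar_bias_probability, retention_probability


def _centered(points, shell):
    """Undo the shell's translation and rotation."""
    pts = points - np.array([shell.x0, shell.y0, 0.0])
    c, s = math.cos(shell.phi), math.sin(shell.phi)
    x = c * pts[:, 0] + s * pts[:, 1]
    y = -s * pts[:, 0] + c * pts[:, 1]
    return np.column_stack((x, y, pts[:, 2]))


class TestUnitSphere:
    def test_unit_norm_by_construction(self):
        pts = sample_unit_sphere(10000, np.random.default_rng(0))
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)

    def test_mean_near_origin(self):
        n = 100000
        pts = sample_unit_sphere(n, np.random.default_rng(1))
        assert np.all(np.abs(pts.mean(axis=0)) < 3 / math.sqrt(n))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_octant_occupancy_uniform(self, seed):
        n = 80000
        pts = sample_unit_sphere(n, np.random.default_rng(seed))
        octant = ((pts[:, 0] > 0).astype(int) * 4
                  + (pts[:, 1] > 0).astype(int) * 2
                  + (pts[:, 2] > 0).astype(int))
        counts = np.bincount(octant, minlength=8)
        stat = np.sum((counts - n / 8) ** 2 / (n / 8))
        assert stat < chi2.ppf(0.999, df=7)


class TestStretchedSphere:
    def test_degenerate_stretch_equals_scaled_sphere(self):
        shell = EllipsoidShell(0, 0, 400.0, 400.0, n_fluorophores=5000)
        pts = stretched_sphere_points(shell, np.random.default_rng(3))
        unit = sample_unit_sphere(5000, np.random.default_rng(3))
        assert np.allclose(pts, 400.0 * unit)

    def test_points_on_ellipsoid_surface(self):
        shell = EllipsoidShell(900.0, 700.0, 450.0, 900.0, phi=0.7,
                               n_fluorophores=5000)
        pts = _centered(stretched_sphere_points(
            shell, np.random.default_rng(4)), shell)
        lhs = (pts[:, 0] ** 2 / shell.b ** 2 + pts[:, 1] ** 2 / shell.a ** 2
               + pts[:, 2] ** 2 / shell.a ** 2)
        assert np.allclose(lhs, 1.0, atol=1e-9)

    def test_polar_density_exceeds_equatorial(self):
        # density per unit surface area, using the area-uniform sampler as
        # the area reference; ratio tends to b/a = 2 at the poles
        a, b, n = 400.0, 800.0, 100000
        sh = EllipsoidShell(0, 0, a, b, n_fluorophores=n)
        rng = np.random.default_rng(5)
        stretched = stretched_sphere_points(sh, rng)
        uniform = uniform_ellipsoid_points(sh, rng)

        def frac(pts, lo, hi):
            ax = np.abs(pts[:, 0]) / b
            return np.mean((ax >= lo) & (ax < hi))

        pole = frac(stretched, 0.9, 1.0) / frac(uniform, 0.9, 1.0)
        equator = frac(stretched, 0.0, 0.1) / frac(uniform, 0.0, 0.1)
        assert pole / equator > 1.2
        assert pole / equator == pytest.approx(b / a, rel=0.25)


class TestRejectionRules:
    def test_retention_is_one_on_sphere(self):
        pts = 300.0 * sample_unit_sphere(1000, np.random.default_rng(0))
        assert np.allclose(retention_probability(pts, 300.0, 300.0), 1.0)

    def test_retention_at_pole_and_equator(self):
        a, b = 400.0, 800.0
        pole = np.array([[b, 0.0, 0.0]])
        equator = np.array([[0.0, a, 0.0]])
        assert retention_probability(pole, a, b)[0] == pytest.approx(a / b)
        assert retention_probability(equator, a, b)[0] == pytest.approx(1.0)

    def test_polar_bias_reduces_to_uniform_at_q0(self):
        a, b = 400.0, 800.0
        pts = np.column_stack([sample_unit_sphere(
            500, np.random.default_rng(1))]) * np.array([b, a, a])
        assert np.allclose(polar_bias_probability(pts, a, b, 0.0),
                           retention_probability(pts, a, b))

    def test_full_polarity_kills_equator(self):
        a, b = 400.0, 800.0
        equator = np.array([[0.0, a, 0.0]])
        assert polar_bias_probability(equator, a, b, 1.0)[0] == pytest.approx(0.0)

    def test_equatorial_bias_on_sphere(self):
        r = 500.0
        equator = np.array([[0.0, r, 0.0]])
        pole = np.array([[r, 0.0, 0.0]])
        assert polar_bias_probability(equator, r, r, -1.0)[0] == pytest.approx(1.0)
        assert polar_bias_probability(pole, r, r, -1.0)[0] == pytest.approx(0.5)

    def test_q_above_one_rejected(self):
        with pytest.raises(ValueError):
            EllipsoidShell(0, 0, 400.0, 800.0, q=1.5)
        with pytest.raises(ValueError):
            polar_bias_probability(np.zeros((1, 3)), 400.0, 800.0, 1.2)


class TestUniformEllipsoid:
    def test_exact_count_after_rejection(self):
        shell = EllipsoidShell(0, 0, 300.0, 900.0, n_fluorophores=4321)
        pts = uniform_ellipsoid_points(shell, np.random.default_rng(6))
        assert pts.shape == (4321, 3)

    def test_surface_density_uniform_over_equal_area_bands(self):
        # band edges in x chosen for equal surface area of the prolate
        # spheroid (surface-of-revolution quadrature), then chi-square
        a, b, n = 400.0, 800.0, 60000
        shell = EllipsoidShell(0, 0, a, b, n_fluorophores=n)
        pts = uniform_ellipsoid_points(shell, np.random.default_rng(7))

        def band_area_density(x):
            rho = a * math.sqrt(max(1.0 - x * x / (b * b), 0.0))
            drho = (-a * x / (b * b)) / max(
                math.sqrt(max(1.0 - x * x / (b * b), 1e-12)), 1e-12)
            return 2 * math.pi * rho * math.sqrt(1 + drho * drho)

        xs = np.linspace(-b, b, 2001)
        dens = np.array([band_area_density(x) for x in xs])
        cum = np.concatenate([[0.0], np.cumsum(
            0.5 * (dens[1:] + dens[:-1]) * np.diff(xs))])
        cum /= cum[-1]
        n_bands = 12
        inv = interp1d(cum, xs)
        edges = inv(np.linspace(0, 1, n_bands + 1))
        counts, _ = np.histogram(pts[:, 0], bins=edges)
        expected = n / n_bands
        stat = np.sum((counts - expected) ** 2 / expected)
        assert stat < chi2.ppf(0.999, df=n_bands - 1)


class TestRenderer:
    def test_single_point_matches_discretised_psf(self, psf130):
        grid = PixelGrid.square(9, 74.0)
        cx, cy = grid.center
        img = render_point_cloud_image(np.array([[cx, cy, 0.0]]), 3.0,
                                       psf130, grid)
        # oracle: fine quadrature of h over the central pixel footprint
        w = grid.pixel_width
        ax = np.linspace(cx - w / 2, cx + w / 2, 61)
        xx, yy = np.meshgrid(ax, ax)
        h = point_source_image(np.hypot(xx - cx, yy - cy), psf130, 3.0)
        oracle = h.mean() * w * w
        # agreement limited by the renderer's 3x3 sub-pixel rule
        assert img[4, 4] == pytest.approx(oracle, rel=1e-2)

    def test_flux_conservation_in_plane_mode(self, psf130, grid27):
        shell = EllipsoidShell(*grid27.center, 300.0, 300.0,
                               n_fluorophores=20000)
        cloud = stretched_sphere_points(shell, np.random.default_rng(8))
        img = render_point_cloud_image(cloud, 2.0, psf130, grid27,
                                       use_z=False)
        assert img.sum() == pytest.approx(20000 * 2.0, rel=5e-3)

    def test_deterministic_given_seed(self, psf130, grid27):
        shell = EllipsoidShell(*grid27.center, 450.0, 750.0, q=0.5,
                               n_fluorophores=3000)
        imgs = []
        for _ in range(2):
            cloud = polarized_ellipsoid_points(shell, np.random.default_rng(9))
            imgs.append(render_point_cloud_image(cloud, 1.0, psf130, grid27))
        assert np.array_equal(imgs[0], imgs[1])

    def test_sphere_cloud_approaches_algebraic_image(self, psf130, grid27):
        # coarse check at n = 2e4; the n^{-1/2} convergence study lives in
        # the acceptance suite
        a, n = 500.0, 20000
        alg = render_shell_image(
            SphericalShell(*grid27.center, a, 1.0), psf130, grid27)
        shell = EllipsoidShell(*grid27.center, a, a, n_fluorophores=n)
        cloud = stretched_sphere_points(shell, np.random.default_rng(10))
        mc = render_point_cloud_image(cloud, 4 * math.pi * a * a / n,
                                      psf130, grid27)
        rel_rms = np.sqrt(np.mean((mc - alg) ** 2) / np.mean(alg ** 2))
        assert rel_rms < 0.05

    def test_empty_cloud_rejected(self, psf130, grid27):
        with pytest.raises(ValueError):
            render_point_cloud_image(np.zeros((0, 3)), 1.0, psf130, grid27)
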