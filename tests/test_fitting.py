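"""Model fitting, quality control, residuals and summaries."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from elmfit import (EllipsoidShell, SphericalShellModel,
                    anisotropy_ratio, equal_volume_radius, fit_ellipsoid_mc,
                    fit_sphere_algebraic, quality_control, residual_error,
                    summarize_experiment, summarize_frame)
from elmfit.ellipsoid_mc import uniform_ellipsoid_points, render_point_cloud_image
from elmfit.fitting import FrameSummary, ShellFitResult


def _result(sigma_fit=130.0, a=500.0, accepted=False, **kw):
    defaults = dict(model_kind="sphere_algebraic", x0=0.0, y0=0.0, a=a, b=a,
                    phi=0.0, q=0.0, brightness=1.0, sigma_fit=sigma_fit,
                    epsilon=0.01, accepted=accepted)
    defaults.update(kw)
    return ShellFitResult(**defaults)


class TestResidualError:
    def test_hand_examples(self):
        assert residual_error([1.0, 2.0], [1.0, 1.0]) == pytest.approx(0.2)
        data = np.arange(1.0, 10.0)
        assert residual_error(data, data) == 0.0
        assert residual_error(data, np.zeros_like(data)) == pytest.approx(1.0)

    def test_all_zero_data_rejected(self):
        with pytest.raises(ValueError):
            residual_error(np.zeros(4), np.ones(4))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            residual_error(np.zeros(4), np.zeros(5))


class TestEqualVolumeRadius:
    def test_values(self):
        assert equal_volume_radius(500.0, 500.0) == pytest.approx(500.0)
        assert equal_volume_radius(500.0, 800.0) == pytest.approx(584.8, abs=0.05)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(100.0, 1000.0), st.floats(1.0, 3.0),
           st.floats(1.001, 1.2))
    def test_bounds_and_monotonicity(self, a, aspect, growth):
        b = a * aspect
        r = equal_volume_radius(a, b)
        assert a * (1 - 1e-12) <= r <= b * (1 + 1e-12)
        assert equal_volume_radius(a, b * growth) > r
        assert equal_volume_radius(a * growth, b * growth) > r

    def test_invalid_axes_rejected(self):
        with pytest.raises(ValueError):
            equal_volume_radius(800.0, 500.0)
        with pytest.raises(ValueError):
            equal_volume_radius(0.0, 500.0)


class TestAnisotropyRatio:
    def test_reference_values(self):
        assert anisotropy_ratio(1.0).gamma_ratio == pytest.approx(1.0)
        assert anisotropy_ratio(np.sqrt(3.0)).gamma_ratio == pytest.approx(1.2)
        assert anisotropy_ratio(1e6).gamma_ratio == pytest.approx(4.0 / 3.0, rel=1e-6)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(1.0, 50.0))
    def test_bounded_and_increasing(self, aspect):
        r = anisotropy_ratio(aspect).gamma_ratio
        assert 1.0 <= r < 4.0 / 3.0
        assert anisotropy_ratio(aspect + 0.5).gamma_ratio > r

    def test_oblate_rejected(self):
        with pytest.raises(ValueError):
            anisotropy_ratio(0.9)


class TestQualityControl:
    def test_boundary_exactness(self, psf130):
        exactly = quality_control(_result(sigma_fit=2 * 130.0), psf130)
        just_over = quality_control(_result(sigma_fit=2 * 130.0 + 1e-9), psf130)
        assert exactly.accepted
        assert not just_over.accepted
        assert just_over.reject_reason == "sigma_above_2x_known"

    def test_plausible_sigma_accepted(self, psf130):
        assert quality_control(_result(sigma_fit=130.0), psf130).accepted

    def test_nonpositive_sigma_rejected(self, psf130):
        for s in (0.0, -5.0):
            r = quality_control(_result(sigma_fit=s), psf130)
            assert not r.accepted
            assert r.reject_reason == "sigma_nonpositive"


class TestSphereFit:
    def test_noise_free_parameter_recovery(self, sphere_crop, psf130):
        crop, truth = sphere_crop
        res = fit_sphere_algebraic(crop, psf130)
        assert res.accepted
        assert res.a == pytest.approx(truth.a, abs=0.5)
        assert res.sigma_fit == pytest.approx(psf130.sigma, abs=1.0)
        assert res.x0 == pytest.approx(truth.x0, abs=0.5)
        assert res.y0 == pytest.approx(truth.y0, abs=0.5)
        assert res.epsilon < 1e-6

    def test_pure_noise_rejected_by_qc(self, psf130):
        n_rejected = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(10):
                rng = np.random.default_rng(seed)
                raw = rng.uniform(0, 100, (27, 27))
                zero = np.median(raw[raw < raw.mean()])
                crop = np.clip(raw - zero, 0, None)
                res = fit_sphere_algebraic(crop, psf130)
                n_rejected += (not res.accepted)
        assert n_rejected >= 9

    def test_empty_crop_flagged(self, psf130):
        res = fit_sphere_algebraic(np.zeros((27, 27)), psf130)
        assert not res.accepted
        assert res.reject_reason == "empty_data"

    def test_summary_is_printable(self, sphere_crop, psf130):
        crop, _ = sphere_crop
        text = SphericalShellModel(crop, psf130).fit().summary()
        assert "sphere_algebraic" in text
        assert "accepted" in text


class TestEllipsoidFit:
    def test_uniform_ellipsoid_recovery(self, psf130, grid27):
        truth = EllipsoidShell(*grid27.center, 450.0, 750.0, phi=0.5,
                               n_fluorophores=10000)
        cloud = uniform_ellipsoid_points(truth, np.random.default_rng(7))
        data = render_point_cloud_image(cloud, 1.0, psf130, grid27)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_ellipsoid_mc(data, psf130,
                                   model_kind="ellipsoid_uniform", rng=3)
        assert res.a == pytest.approx(450.0, rel=0.02)
        assert res.b == pytest.approx(750.0, rel=0.02)
        assert res.phi == pytest.approx(0.5, abs=0.05)

    def test_sphere_input_gives_unit_aspect(self, sphere_crop, psf130):
        crop, _ = sphere_crop
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_ellipsoid_mc(crop, psf130,
                                   model_kind="ellipsoid_uniform", rng=0)
        assert 1.0 <= res.aspect_ratio <= 1.05

    def test_model_nesting_reduces_residual(self, polarized_crop, psf130):
        """Each model extends the previous one, so seeding each search from
        the simpler optimum must not increase the residual."""
        data, _ = polarized_crop
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r_sph = fit_ellipsoid_mc(data, psf130, model_kind="sphere_mc",
                                     rng=11)
            r_uni = fit_ellipsoid_mc(data, psf130,
                                     model_kind="ellipsoid_uniform",
                                     rng=11, start=r_sph)
            r_pol = fit_ellipsoid_mc(data, psf130,
                                     model_kind="ellipsoid_polarized",
                                     rng=11, start=r_uni)
        assert r_pol.epsilon <= r_uni.epsilon <= r_sph.epsilon

    def test_unknown_model_kind_rejected(self, psf130):
        with pytest.raises(ValueError):
            fit_ellipsoid_mc(np.zeros((27, 27)), psf130, model_kind="banana")


class TestSummaries:
    def test_single_accepted_fit(self):
        r = _result(a=480.0, accepted=True)
        s = summarize_frame([r])
        assert s.n_accepted == 1
        assert s.mean_radius == pytest.approx(480.0)
        assert s.mean_aspect_ratio == pytest.approx(1.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        results = [_result(a=float(a), accepted=True)
                   for a in rng.uniform(400, 600, 20)]
        s1 = summarize_frame(results)
        s2 = summarize_frame(list(reversed(results)))
        assert s1.mean_radius == pytest.approx(s2.mean_radius)
        assert s1.mean_sigma == pytest.approx(s2.mean_sigma)

    def test_rejected_fits_excluded(self):
        results = [_result(a=500.0, accepted=True),
                   _result(a=9999.0, accepted=False)]
        assert summarize_frame(results).mean_radius == pytest.approx(500.0)

    def test_empty_frame_summary(self):
        s = summarize_frame([])
        assert s.empty
        assert np.isnan(s.mean_radius)

    def test_experiment_needs_three_fields(self):
        frames = [FrameSummary(n_accepted=1, mean_radius=500.0)
                  for _ in range(2)]
        with pytest.raises(ValueError):
            summarize_experiment(frames)

    def test_across_field_statistics(self):
        radii = [495.0, 500.0, 505.0]
        frames = [FrameSummary(n_candidates=10, n_accepted=10, mean_radius=r,
                               mean_aspect_ratio=1.0, mean_polarity=0.0)
                  for r in radii]
        e = summarize_experiment(frames)
        assert e.mean_radius == pytest.approx(500.0)
        assert e.std_radius == pytest.approx(np.std(radii, ddof=1))
        assert "radius" in e.summary()
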