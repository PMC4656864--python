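import warnings

import numpy as np
import pytest

from elmfit import (PSFModel, PixelGrid, SphericalShell, EllipsoidShell,
                    render_shell_image)
from elmfit.ellipsoid_mc import polarized_ellipsoid_points, render_point_cloud_image


@pytest.fixture(scope="session")
def psf130():
    """A typical GFP widefield PSF radius."""
    return PSFModel(sigma=130.0, sigma_known=130.0)


@pytest.fixture(scope="session")
def grid27():
    """The standard 27 x 27 fitting region at 74 nm pixels."""
    return PixelGrid.square(27, 74.0)


@pytest.fixture(scope="session")
def sphere_crop(psf130, grid27):
    """Noise-free rendered image of a 500 nm shell, off-centre by a known
    amount, with its ground truth."""
    cx, cy = grid27.center
    truth = SphericalShell(cx + 10.0, cy - 15.0, 500.0, 0.5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        crop = render_shell_image(truth, psf130, grid27)
    return crop, truth


@pytest.fixture(scope="session")
def polarized_crop(psf130, grid27):
    """Noise-free image of a polarized ellipsoid (a=450, b=750, phi=0.5,
    q=0.5) rendered from 10,000 fluorophores, with its ground truth."""
    cx, cy = grid27.center
    truth = EllipsoidShell(cx, cy, 450.0, 750.0, phi=0.5, q=0.5,
                           n_fluorophores=10000)
    cloud = polarized_ellipsoid_points(truth, np.random.default_rng(42))
    crop = render_point_cloud_image(cloud, 1.0, psf130, grid27)
    return crop, truth
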