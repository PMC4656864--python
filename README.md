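# elmfit — ellipsoid localization microscopy

`elmfit` infers the size, shape and protein distribution of spheroidal
fluorescent shells — such as the coat layers of *Bacillus* spores carrying
GFP fusion proteins — from ordinary widefield fluorescence micrographs, with
a precision (~10 nm) far below the diffraction limit. It does so not by
sharpening the image but by fitting a physical model of the whole shell
image to the data: because every pixel of a spore's image constrains the
same few geometric parameters, the shell radius can be located far more
precisely than the optical resolution.

## The model

A thin spherical shell of radius *a*, uniformly fluorescent with brightness
*I₀* per unit area, imaged through a Gaussian point-spread function (PSF) of
radius *σ*, produces the radial image intensity

    f(r) = a I₀ ( e^{−(r−a)²/2σ²} − e^{−(r+a)²/2σ²} ) / r,

with the removable singularity at r = 0 replaced by its limit
2a²I₀/σ² · e^{−a²/2σ²}. Fitting the five parameters (x₀, y₀, a, I₀, σ) to a
background-corrected 27 × 27-pixel region recovers the shell radius; the
fitted σ doubles as a quality-control statistic (fits with σ above twice the
instrument's known PSF radius are overlapping or fragmented spores and are
rejected).

Elongated spores are handled by Monte Carlo image models of a prolate
ellipsoid (semiminor *a*, semimajor *b*, orientation φ) decorated with
fluorophores: a **stretched sphere** (pole-crowded density), a **uniform
ellipsoid** (rejection-sampled uniform surface density, retention
p = a·(x²/b⁴ + y²/a⁴ + z²/a⁴)^{1/2}), and a **polarized ellipsoid** whose
retention is further biased by the polarity q toward the poles (q > 0) or
equator (q < 0). These are fitted by a least-squares iterative random
search with common random numbers. Ellipsoid results are summarised as the
equal-volume radius (a²b)^{1/3} and the aspect ratio b/a, from which the
surface-tension anisotropy of a pressurised shell,
γ_y/γ_x = 4(b/a)²/(3(b/a)²+1), follows.

Fitted parameters can be fed back through the image model at an arbitrarily
small render PSF (default 25 nm) to produce a superresolved, model-based
reconstruction of a single spore or of a population average.

## Worked example

Simulate three fields of spherical shells with radius exactly 500 nm
(10,000 fluorophores each, 1.3 NA oil objective, 500 nm emission, 74 nm
pixels, 12-bit camera noise), then run the full pipeline — Hough
segmentation, anticollision filtering, background zeroing, algebraic-model
fitting and σ-based quality control:

```
elmfit simulate --out-dir sim --n-shells 49 --n-fields 3 --seed 1
elmfit run sim/field_*.tif --out summary.json --results-csv results.csv \
    --sigma-known 117.3 --seed 1
```

which prints

```
Experiment summary
==================================================
fields: 3   accepted spores: 147
radius (nm):          501.41 +/- 0.15
aspect ratio b/a:     1.0000 +/- 0.0000
polarity q:           0.0000 +/- 0.0000
```

All 147 simulated spores were accepted and the mean fitted radius is
501.4 nm against a ground truth of 500 nm — a bias of 1.4 nm, with a
field-to-field standard deviation of 0.15 nm, i.e. well inside the 10 nm
error bound that makes layer-order assignment possible. `results.csv` holds
one row per candidate (centre, radius, axes, orientation, polarity,
brightness, fitted σ, residual ε and the accept/reject decision);
`summary.json` holds the per-field and across-field statistics. A
superresolved reconstruction of the accepted fits is produced by

```
elmfit reconstruct --results results.csv --out recon.tif
```

The same library surface is available in Python
(`SphericalShellModel(region, psf).fit()`,
`EllipsoidShellModel(region, psf, model_kind="ellipsoid_polarized").fit()`,
`run_pipeline`, `reconstruct`, ...), returning result objects with a
`summary()` table.

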