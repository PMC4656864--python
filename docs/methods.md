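# Methods

This note records the models implemented in `elmfit`, the assumptions they
make, the defaults that matter, and the design decisions taken where the
method left room.

## Image model of a thin fluorescent shell

The algebraic model treats the specimen as an infinitesimally thin,
uniformly fluorescent spherical surface of radius `a` centred at
(x0, y0) in the focal plane, and the microscope as a *spherically
symmetric* Gaussian PSF of radius `sigma` (all lengths object-frame nm).
Integrating the PSF over the sphere gives the closed-form radial intensity
`f(r)` (see README). Two consequences of the spherically symmetric PSF are
worth stating explicitly because they differ from a pure-2D blur:

* fluorescence from parts of the shell away from the focal plane is
  attenuated by `exp(−z²/2σ²)`, so the in-plane image flux is
  `(2π)^{3/2} a σ I₀ erf(a/√2σ)` (exposed as `shell_image_flux`), not the
  emitted `4πa²I₀`;
* the Monte Carlo renderer evaluates each fluorophore's Gaussian at the 3D
  displacement by default (`use_z=True`), which is what makes the MC sphere
  image converge to the algebraic one as the fluorophore count grows
  (relative RMS ∝ n^{−1/2}; the test suite fits this slope). With
  `use_z=False` the renderer is a flux-preserving 2D blur, used by the
  calibration simulator.

The thick-shell profile `f₂(r)` integrates `f` over shell radius in closed
form (error-function antiderivative, validated against numeric quadrature).
It is provided for analysis but not fitted: thickness and PSF radius are
nearly degenerate in the image unless `sigma ≪ d`.

The contour of maximum brightness of a shell image lies *inside* the true
radius by an offset that grows with `sigma/a` (`peak_brightness_radius`).
This reproduces quantitatively why cross-section peak-finding infers
different layer diameters for the same structure imaged in different
colours, and is the bias that model fitting avoids.

### Rendering convention

Pixel (i, j) has its centre at ((j+0.5)w, (i+0.5)w), w = 74 nm by default.
A pixel value is the integral of the intensity over the pixel footprint,
approximated by a 3×3 sub-pixel mean times the pixel area — at w ≈ 0.5–0.9
sigma, centre-point sampling measurably biases fitted parameters. The same
rule is used for the algebraic renderer, the MC renderer and the simulator,
so fits and synthetic data share one discretisation.

## Monte Carlo ellipsoid models

Only a prolate ellipsoid of revolution lying flat in the object plane is
modelled (surface x²/b² + y²/a² + z²/a² = 1 before rotation by φ about z),
matching how elongated spores settle on a coverslip. Uniform sphere points
come from the trig method (azimuth uniform, cos(polar angle) uniform).
Three surface distributions:

* **stretched sphere** — linear stretch (x = bx′, y = ay′, z = az′); the
  stretch compresses surface area near the poles, so fluorophore density
  (per unit area) is higher there by up to b/a;
* **uniform ellipsoid** — stretched points thinned by rejection with
  retention equal to the stretch's local area scale factor (a/b at the
  poles, 1 at the equator), giving uniform surface density;
* **polarized ellipsoid** — retention further multiplied by
  C(1 − q·sin t), sin t = √(y²+z²)/‖r‖, C = 1 for q ≥ 0 and (1−q)⁻¹ for
  q < 0. q ∈ [−1, 1] keeps the probability in [0, 1]; q = 0 reduces
  exactly to the uniform model.

Rejection sampling resamples until exactly `n_fluorophores` points are
retained, so total image brightness n·I is independent of aspect ratio and
polarity — the alternative (thinning a fixed batch) would couple brightness
to shape and destabilise fitting. Default counts: 2,500 fluorophores for
fitting, 10⁵ for convergence checks.

## Fitting

`SphericalShellModel` fits (x0, y0, a, I0, sigma) by bounded nonlinear
least squares (trust-region reflective), initialised from the Hough centre,
the mid-range Hough radius (8 px) and the total crop flux. Approximate
standard errors come from the Jacobian at the optimum. On noise-free
self-rendered inputs all parameters are recovered to well under 0.5 nm.

`EllipsoidShellModel` fits the MC models by an iterative random search:

* **common random numbers** — one lazily grown pool of unit-sphere points
  and uniform deviates per candidate; rejection scans the pool in order and
  keeps the first n accepted, so the objective is a deterministic function
  of the seed at any (b/a, q), which is what lets simple descent converge;
* **profiled brightness** — per-fluorophore intensity is linear in the
  model, so each evaluation uses its analytically optimal (non-negative)
  value rather than searching over it;
* **warm starts** — centre, radius and σ from the algebraic sphere fit;
  the sphere radius is split into axes using the aspect ratio and
  orientation of the crop's intensity second-moment matrix, preserving the
  equal-volume radius;
* **proposals** — 300 iterations; every free parameter receives a Gaussian
  perturbation (5 nm centre, 20 nm axes, 0.1 rad, 0.1 q, 5 nm σ) scaled by
  0.985 per iteration; a move is accepted iff it lowers the objective.
  Because changing q alters the retained sample discretely, the objective
  is rugged in q, and with probability 0.15 a proposal draws q uniformly
  from [−1, 1] instead of locally. Axes are canonicalised to b ≥ a (with a
  π/2 rotation of φ); φ is reported modulo π and is unidentifiable when
  b ≈ a (flagged via an infinite standard error).

On noise-free polarized-ellipsoid images (a = 450, b = 750, q = 0.5,
10⁴ fluorophores) the search recovers the axes to ≈1% and q to within 0.1
when averaged over five seeds; the acceptance suite measures this.

Model choice between sphere and ellipsoid is reported via the residual
ε = Σ(data−fit)²/Σdata² side by side, not automated: for near-spherical
species the spherical model is preferred on parsimony even when the
ellipsoid fits equally well. ε is computed on background-subtracted pixel
values — the values actually fitted.

## Segmentation and quality control

A circular Hough transform over radii 4–12 px runs on the Sobel gradient
magnitude of the lightly smoothed frame, binarised at the Otsu threshold
(the accumulator counts votes from edge pixels). Peaks above 0.8× the
maximum accumulator response become candidates: closed rings score ≈1 in
the normalised accumulator (even for aspect ratios up to ~1.7 and dim
spores), while arc fragments of a ring — the dominant false positive —
score ≤0.75. Detected circles that geometrically overlap are one feature
(strongest response wins). The anticollision filter then suppresses any
candidate within 13 px (half the fitting region) of a stronger one, which
removes the two-circles-on-one-elongated-spore duplication. Candidates
nearer than 13 px to a frame edge are dropped rather than zero-padded,
because padding biases the fitted σ.

Background is removed per 27×27 region by subtracting the median of all
pixels darker than the region mean (for a constant region, the minimum),
then clipping at zero; adding a constant to a frame shifts the zero level
by exactly that constant and leaves corrected crops unchanged.

Quality control accepts a fit iff 0 < σ_fit ≤ 2·σ_known. σ_known is the
instrument's quoted PSF radius — half the Rayleigh resolution,
0.305·λ/NA (≈117 nm for the simulated 1.3 NA / 500 nm instrument; 130 nm
is a typical configured value for real GFP data). Fitted σ on real shells
runs well above the in-focus Gaussian waist because it absorbs specimen
structure and defocus; the in-focus waist is therefore *not* a valid
σ_known.

## Calibration simulator

The simulator produces the validation conditions: fields of well-separated
(≥27 px) spherical shells of radius exactly 500 nm, 10,000 fluorophores
per shell, 1.3 NA oil objective (n_imm = 1.515), 500 nm emission, 74 nm
pixels with 100% fill factor, Poisson shot noise (50 photons per
fluorophore by default), 2-count RMS Gaussian read noise, 12-bit
quantisation. Desk-scale default: 3 fields × 49 shells (a 7×7 jittered
grid), against the original experiment's scale of 5 fields × ~200 spores;
the acceptance script states the sizes it used.

The defocus model is the deliberate fidelity gap between simulator and
analysis model, and the dominant systematic choice:

* **disc (default)** — geometric-optics defocus: a fluorophore at depth z
  is rendered as its in-focus Gaussian (σ₀ = 0.21λ/NA ≈ 81 nm) displaced
  uniformly over the blur disc of radius |z|·tan α, α = asin(NA/n_imm) ≈
  59°. Out-of-focus light is flattened into a broad halo, most of which is
  removed by background zeroing — the behaviour a high-NA widefield image
  of a 1 µm object shows. Rendering uses a sub-pixel histogram and a
  single Gaussian convolution, so whole fields are fast.
* **gaussian** — each fluorophore rendered as one flux-conserving Gaussian
  of width σ(z) = √(σ₀² + (z·tanα/2)²), the RMS-matched equivalent of the
  disc (`defocus_psf_sigma`); smooth, and convenient for the semi-analytic
  radial-profile oracle in the tests.

Under the disc model the full pipeline recovers the 500 nm ground truth
with a bias of order 1–2 nm and sub-nm field-to-field scatter (the
acceptance script computes the exact values). Models whose defocused PSF
keeps a compact central lobe (a paraxial Gaussian-beam law, or an
aberration-free scalar diffraction PSF) leave substantial central
intensity that the attenuating analysis model cannot represent, and were
measured here to bias the fitted radius inward by tens of nm; they do not
reproduce the documented behaviour of realistic simulators of this
instrument class, and the Gaussian mode is retained for oracle tests
rather than calibration claims.

What passing the calibration tests does **not** show about real data: real
spores are aspherical, inhomogeneously labelled, and of finite layer
thickness; real PSFs carry aberrations; and batch-to-batch biological
variation (~6 nm at best in repeatability) exceeds the simulator's noise
floor. The calibration bounds the *method's* bias, not the biological
scatter.

## Reconstruction

Accepted fits (never rejected ones) can be rendered back through their
image model with a small PSF — default 25 nm, half the estimated
fluorescent layer thickness — on a 10 nm grid, either per spore or from
population-mean parameters. The output is a visualisation of the fitted
parametric model, not data: it inherits every assumption above, and is
labelled as model-based inference throughout.

## Numerical choices and degenerate inputs

* `f(r)` switches to its r→0 limit below r = 10⁻⁶·a (two-sided relative
  difference at the switch < 10⁻⁹).
* Peak finding uses bounded scalar maximisation on (0, a), tolerance
  10⁻³ nm; `f` is unimodal there.
* The thick-shell closed form was re-derived and is tested against
  quadrature of `f` over the shell radius; the quadrature is authoritative.
* All-zero crops, optimizer failures and non-convergence yield rejected
  `ShellFitResult`s with a reason, never exceptions; one bad candidate
  never aborts a frame.
* Every random draw descends from explicit integer seeds (per-candidate
  seeds are spawned from the pipeline seed), so reruns are byte-identical.
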