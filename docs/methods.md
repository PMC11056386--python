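# Methods

This note documents the physical models, numerical choices and defaults
behind the toolkit, and what its synthetic validation does and does not
establish about real instruments.

## Specimen model

Phantoms are pure-phase objects on a regular object-space grid (micrometers,
x = shear axis = fastest array axis, origin at pixel (0,0)).  A sphere of
diameter d and index n_p in a medium n_m delays the wavefront by

    φ(ρ) = (2π/λ) · (n_p − n_m) · 2·sqrt((d/2)² − ρ²),

the chord length through the sphere at lateral radius ρ.  Phase is evaluated
at pixel centers with no area-weighted anti-aliasing; the peak converges to
(2π/λ)·Δn·d quadratically in pixel size, and the integrated phase converges
to (2π/λ)·Δn·(πd³/6).  Overlapping spheres sum (with a warning); spheres
crossing the grid boundary are rejected.

Package-wide index constants at 650 nm: polystyrene 1.588, immersion oil
1.518, water 1.333.  Published dispersion fits put polystyrene at 1.586–1.589
near 650 nm; 1.588 gives a 1 µm bead in oil a peak delay of 0.677 rad,
consistent with the commonly quoted ≈0.68 rad check value.

Random phantoms are Gaussian white noise smoothed to a chosen correlation
length (periodic boundaries), recentered to zero mean and rescaled so
max|φ| equals the requested amplitude; they are reproducible by seed and are
used for round-trip property tests.

## Image formation

The e- and o-waves sample the specimen phase at ±s/2 along the shear axis:
θ_e(x) = Φ(x+s/2), θ_o(x) = Φ(x−s/2), applied by band-limited (Fourier)
interpolation so sub-pixel shears are exact for band-limited fields.  The
default shear is half the incoherent PSF FWHM (0.514·λ/NA), in keeping with
shear interferometers whose beam separation stays below the PSF width; it is
a free parameter of `OpticalConfig`, since real prism shears are rarely
documented.

Frames follow the two-beam interference law

    I(α) = J_o² + J_e² + 2 J_o J_e cos(θ_e − θ_o − α),

with J_e = J_o = 1 for pure-phase specimens (amplitude maps are supported
but not validated).  Bias schedules are arbitrary; the uniform open schedule
α_i = 2πi/N, Δα_i = 2π/N is the default.

**Diffraction.**  Two blur models are provided.  The pipeline default is the
*near-coherent* model: the complex fields J·e^{iθ} of both waves are
convolved with the amplitude Airy PSF 2J₁(v)/v before interference.  This is
the appropriate regime when the condenser NA (0.30 here) is well below the
objective NA, and it reproduces the bead-calibration behaviour of such
instruments: the reconstructed peak of a 1 µm bead stays within a few
percent of its true delay, and a 200 nm bead images at ≈0.55 µm FWHM through
an NA 0.75 system.  An *incoherent* intensity-domain Airy blur
(`psf_blur`, flux-conserving, reflect boundary) is also available; applied
to the same scenario it attenuates the 1 µm bead peak by ~25%, far more than
real systems show, which is why it is not the pipeline default.  A rigorous
partially coherent (Abbe/Hopkins) treatment is out of scope; its main
omitted effect is damping of coherent edge ringing, which in the coherent
model overshoots a hard-edged bead's peak by a few percent.  The 20 nm
illumination bandwidth is likewise ignored (monochromatic model).

Shot noise replaces each pixel with a Poisson draw at a stated photon budget
per intensity unit per frame, seeded and reproducible.

## Demodulation

Every pixel of a bias series traces A + B·cos(Δθ − α).  The 4-bucket
estimator uses atan2(I_{π/2} − I_{3π/2}, I_0 − I_π); the N-step estimator
uses the sine/cosine-weighted sums over the schedule.  Both are fixed to the
same sign convention (positive output when θ_e leads θ_o); as printed in the
standard references the two formulas differ by a leading minus sign, which
cannot be right on identical data, so the N-step sum is sign-reconciled to
the 4-bucket form (they are then algebraically identical on the uniform
4-level schedule).  A quadrant-aware two-argument arctangent is used
throughout — the printed tan⁻¹ of a ratio is quadrant-ambiguous — giving
outputs wrapped to (−π, π].  Pixels with no modulation (both sums ≈ 0,
relative threshold 10⁻¹²) are set to 0 and flagged in a validity mask
rather than NaN so Fourier integration stays finite.  No phase unwrapping
is applied; all supported scenarios keep |∇ₓΦ| < π.

At a fixed per-frame photon budget the demodulation variance falls as 1/N,
so the background noise std scales as 1/√N — the quantitative content of
the observation that 16 bias levels resolve weak scatterers that 4 levels
bury in noise (`sensitivity_experiment` reproduces both the strict ordering
and the scaling within a few percent).

## Gradient-to-phase integration

The demodulated map is the finite difference of Φ over the shear s, whose
row-wise transfer function is H(k) = 2i·sin(k·s/2).  The default integrator
divides each row's spectrum by H with Tikhonov regularization
(H/(H²+δ²), δ = 2·10⁻³ relative) — the Hilbert-kernel realization of the
integration ∫∇ₓΦ dx′ + c — and zeroes the DC term, fixing c = 0.  The exact
sin kernel is used at every shear (it reduces to i·k·s for small s, so one
code path covers both limits).  Rows are mirror-extended before the FFT
with a sign flip: the phase is even-extended at the boundary, hence its
shear difference is odd; this is the correct boundary model for specimens
in a zero background.  A `periodic` option skips the extension for fields
that are themselves periodic (used in closed-form tests).  The row DC is a
genuine gauge freedom of gradient data; comparisons against ground truth
are made in the row-mean-free gauge or after background correction.
Whether to invert row-wise (1-D) or over the half-plane (2-D) is an open
implementation choice for this family of methods; row-wise is implemented,
as the shear is axis-aligned.

Baselines: a literal per-row running sum (exhibits the classic random-walk
row streaks under noise, kept as a didactic reference) and Wiener
deconvolution Φ̂ = conj(H)·G/(|H|² + 1/snr).  At large snr the Wiener route
coincides with the Hilbert one; at practical snr (default 100) its uniform
regularization damps the low frequencies that carry the specimen body, and
under shot noise its error against ground truth exceeds the Hilbert
route's — the qualitative ranking that motivates preferring the Hilbert
integration.

**Background correction** mirrors the usual ImageJ flattening: a rolling
ball rolled under a lightly smoothed copy (Gaussian σ = 1 px, so the ball
rides the noise mean rather than its lower envelope) estimates the
background, which is subtracted; the result is recentered on its median
(the specimen occupies a small area, so the median is background).  The
ball is an ellipsoid whose intensity semi-axis is 2% of the image range —
phase maps are in radians, not pixel units, so a literal sphere would sag
into narrow peaks.  The radius must exceed the largest specimen feature;
3 µm is used for single-bead fields.

## Metrics

* `peak_phase`: maximum of the neighborhood-mean-filtered image.  At
  Nyquist sampling the neighborhood is kept at 1 px — any wider window
  spans a whole resolution element and biases a diffraction-limited peak
  down; at finer sampling 3–5 px suppresses single-pixel outliers.
* `average_particle_trace`: cubic-interpolated traces along the shear axis
  through each detected center, resampled to common coordinates and
  averaged; near-edge detections are skipped with a warning.  Traces are
  taken along the shear axis by default (the perpendicular is an option).
* `fwhm_gaussian_fit`: 4-parameter least-squares Gaussian (amplitude,
  center, σ, offset — the pedestal term is kept even after background
  correction, for robustness); FWHM = 2√(2 ln 2)·σ with its standard error
  from the fit covariance.  The estimator is unbiased on noiseless
  Gaussians and obeys the convolution quadrature rule
  FWHM² = F₁² + F₂², the accounting used when a finite particle is imaged
  through a PSF.
* `find_particles`: local maxima above 50% of the global peak, separated by
  at least 3 PSF FWHM (detection is not standardized in this literature;
  this rule is simple and adequate for sparse bead fields).
* `radial_profile`: mean phase over a transverse band along a segment.

## Validation scenarios and their sizes

The acceptance harness uses desk-scale problem sizes chosen to keep every
quantity converged: 96² grids at 20 nm pixels for analytic phantom checks,
128² Nyquist-sampled fields for the single-bead pipeline, and 256² fields
with 20 replicate beads (sub-pixel position jitter, 10⁴ photons per unit)
for the resolution measurements.  Doubling any of these changes the
reported values by well under a percent.

Two known model–experiment gaps, both traceable to optics outside the
model's scope, are documented rather than patched:

* the coherent model's edge ringing puts the reconstructed 1 µm bead peak
  at 0.70–0.71 rad, a couple of percent above the 0.65–0.70 typically read
  off real instruments whose partial coherence damps the ringing;
* measured low-magnification resolutions of such systems (≈1.34 µm at
  NA 0.4 for a 1 µm bead) exceed every diffraction-limited prediction —
  the simulation gives ≈1.09 µm — indicating experimental broadening
  (aberrations, larger prism shear at low magnification) that cannot be
  derived from first principles here.

## What the synthetic tests do not show

The generator emulates monochromatic, aberration-free, axially thin imaging
of index-matched-mounted specimens with ideal bias steps.  Real data add
retarder calibration error, partial coherence, defocus and thick-specimen
scattering, camera read noise and fixed-pattern nonuniformity; none of
these are modeled, so passing tests validate the mathematics of the
demodulation/integration chain and its noise scaling, not instrument
performance.  Axial sectioning is likewise out of scope: z-stacks are
processed plane by plane with no cross-plane coupling.
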