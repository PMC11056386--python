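# grom

Simulation and reconstruction toolkit for quantitative phase imaging (QPI)
on a differential interference contrast (DIC) microscope with phase-shifting
— the *gradient retardance* approach, in which a liquid-crystal retarder
steps the bias between the microscope's sheared e- and o-waves.

A DIC microscope records the interference of two laterally sheared,
orthogonally polarized beams. With a controllable retardance bias α between
them, each frame is

    I(α) = J_o² + J_e² + 2 J_o J_e cos(θ_e − θ_o − α),

so a series of frames at known biases encodes the sheared phase difference
θ_e − θ_o ≈ s·∂Φ/∂x (s the shear distance, Φ the specimen phase).  The
toolkit implements the full desk-scale chain for this kind of instrument,
without any hardware:

1. **phantom** — ground-truth phase maps: spheres with chord-length phase
   delay (2π/λ)·Δn·t(x,y), flats, band-limited random fields;
2. **forward** — shear splitting, near-coherent Airy-PSF image formation,
   the interference law above, Poisson shot noise, bias-series acquisition;
3. **demodulation** — 4-step arctangent and general N-step phase-shifting
   estimators, `∇ₓΦ = atan2(Σᵢ I(αᵢ) sin αᵢ Δαᵢ, Σᵢ I(αᵢ) cos αᵢ Δαᵢ)`;
4. **reconstruction** — integration of the gradient into quantitative phase
   Φ(x,y) = ∫₀ˣ ∇ₓΦ dx′ + c by row-wise Fourier (Hilbert-kernel) inversion
   of the shear-difference transfer function 2i·sin(k·s/2), with cumulative
   summation and Wiener deconvolution as baselines, plus rolling-ball
   background correction;
5. **metrics** — robust peak phase, averaged particle traces, Gaussian-fit
   FWHM resolution, radially averaged profiles;
6. **io / cli** — float32 multi-page TIFF stacks with YAML sidecars, CSV
   metrics, and a `grom` command line.

It is aimed at microscope builders and image-analysis developers who want a
reference implementation of the demodulation/integration mathematics and a
synthetic testbed with exact ground truth.

## Worked example

Simulate a 1 µm polystyrene bead (n = 1.588) in immersion oil (n = 1.518)
at λ = 650 nm through an NA 0.75 system, 16 uniform bias levels, and
reconstruct its phase:

```python
import grom

optics = grom.OpticalConfig.nyquist(0.75)           # pixel = λ/(4·NA)
grid = grom.ImageGrid(128, 128, optics.pixel_size)
phantom, _ = grom.bead_field_phantom(grid, diameter=1.0,
                                     n_particle=grom.N_POLYSTYRENE,
                                     n_medium=grom.N_IMMERSION_OIL,
                                     wavelength=0.65)
print(f"ground-truth peak: {phantom.peak:.4f} rad")

stack, grad, phase = grom.simulate_and_reconstruct(
    phantom, optics, nsteps=16, photons_per_unit=1e4, seed=1,
    background_radius=3.0)
print(f"reconstructed peak: {grom.peak_phase(phase, neighborhood=1):.4f} rad")
```

This prints

```
ground-truth peak: 0.6767 rad
reconstructed peak: 0.7012 rad
```

The ground-truth peak is the analytic chord-length delay
(2π/0.65)·0.070·1.0 ≈ 0.68 rad; the reconstructed value recovers it to a
few percent, the residual coming from coherent diffraction ringing at the
bead edge and shot noise (see `docs/methods.md`).  The same chain from the shell, given a config like

```yaml
# config.yaml
optics:
  wavelength: 0.65        # um
  na_objective: 0.75
  na_condenser: 0.30
  magnification: 1.0
  camera_pixel: 0.2167    # object pixel = camera_pixel / magnification
nsteps: 16
grid_ny: 128
grid_nx: 128
sphere_diameter: 1.0      # um
sphere_n_particle: 1.588
sphere_n_medium: 1.518
photons_per_unit: 10000.0
seed: 1
```

```sh
grom simulate --config config.yaml --seed 1 --out sim/
grom reconstruct sim/stack.tif --background-radius 3.0 --out rec/
grom evaluate rec/phase.tif sim/ground_truth.tif
```

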