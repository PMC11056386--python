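"""Forward model of DIC shear interferometry under a retarder bias schedule.

A Wollaston prism splits the illumination into orthogonally polarized e- and
o-waves that are laterally sheared by a distance ``s`` smaller than the PSF
width.  With a pre-sample retardance bias ``alpha`` between the two waves,

    U_e = J_e * exp(i * theta_e),
    U_o = J_o * exp(i * (theta_o + alpha)),

their interference gives the recorded intensity

    I = J_o**2 + J_e**2 + 2 * J_o * J_e * cos(theta_e - theta_o - alpha),

so the image encodes the sheared phase difference theta_e - theta_o, which
approximates ``s * dPhi/dx`` for a smooth specimen phase ``Phi``.

Diffraction is modeled in the near-coherent regime appropriate for a
condenser NA well below the objective NA: the complex e- and o-fields are
convolved with the amplitude Airy point-spread function before interference
(``coherent_blur``).  An incoherent intensity-domain Airy blur (``psf_blur``)
is also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal, special

from .grids import ImageGrid
from .phantom import PhasePhantom

__all__ = [
    "OpticalConfig",
    "BiasSchedule",
    "WavePair",
    "Interferogram",
    "InterferogramStack",
    "airy_intensity_psf",
    "airy_amplitude_psf",
    "shear_phase_pair",
    "coherent_blur",
    "interferogram",
    "psf_blur",
    "add_shot_noise",
    "acquire_bias_series",
]

#: FWHM of the incoherent Airy intensity PSF in units of lambda/NA.
AIRY_INTENSITY_FWHM = 0.514
#: FWHM of the coherent Airy amplitude PSF in units of lambda/NA.
AIRY_AMPLITUDE_FWHM = 0.705


@dataclass(frozen=True)
class OpticalConfig:
    """Microscope parameters: wavelength and NAs set the PSF, magnification
    and camera pixel set the object-space sampling, and the shear vector
    sets the gradient axis.

    Lengths are micrometers; ``shear_distance`` is in object space.
    """

    wavelength: float = 0.65
    na_objective: float = 0.75
    na_condenser: float = 0.30
    magnification: float = 40.0
    camera_pixel: float = 6.5
    shear_distance: float | None = None
    shear_axis: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if not 0 < self.na_objective <= 1.5:
            raise ValueError(f"na_objective must be in (0, 1.5], got {self.na_objective}")
        if not self.wavelength > 0:
            raise ValueError("wavelength must be positive")
        if self.shear_distance is None:
            # default: half the PSF FWHM ("less than the PSF width")
            object.__setattr__(self, "shear_distance", self.psf_fwhm / 2.0)
        if not self.shear_distance > 0:
            raise ValueError("shear_distance must be positive")
        norm = float(np.hypot(*self.shear_axis))
        if not np.isclose(norm, 1.0, atol=1e-9):
            raise ValueError(f"shear_axis must be a unit vector, |v| = {norm}")
        if self.pixel_size > self.psf_fwhm / 2.0:
            warnings.warn(
                f"object pixel {self.pixel_size:.3g} um violates Nyquist for the "
                f"PSF (FWHM {self.psf_fwhm:.3g} um)",
                stacklevel=2,
            )

    @property
    def pixel_size(self) -> float:
        """Object-space pixel, camera_pixel / magnification (um)."""
        return self.camera_pixel / self.magnification

    @property
    def psf_fwhm(self) -> float:
        """FWHM of the incoherent Airy intensity PSF (um)."""
        return AIRY_INTENSITY_FWHM * self.wavelength / self.na_objective

    @classmethod
    def nyquist(cls, na_objective: float, wavelength: float = 0.65, **kwargs) -> "OpticalConfig":
        """Config sampled exactly at Nyquist: pixel = lambda / (4 NA)."""
        kwargs.setdefault("magnification", 1.0)
        kwargs.setdefault("camera_pixel", wavelength / (4.0 * na_objective))
        return cls(wavelength=wavelength, na_objective=na_objective, **kwargs)


@dataclass(frozen=True)
class BiasSchedule:
    """Ordered retardance bias levels alpha_i with spacing weights dalpha_i."""

    biases: tuple[float, ...]
    deltas: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.biases) < 3:
            raise ValueError("need at least 3 bias levels for demodulation")
        if len(self.deltas) != len(self.biases):
            raise ValueError("deltas must match biases in length")
        if np.ptp(self.biases) < 1e-12:
            raise ValueError("degenerate schedule: all bias levels equal")

    def __len__(self) -> int:
        return len(self.biases)

    @classmethod
    def uniform(cls, nsteps: int) -> "BiasSchedule":
        """Uniform open schedule alpha_i = 2*pi*i/N, dalpha = 2*pi/N."""
        if nsteps < 3:
            raise ValueError("uniform schedule needs at least 3 steps")
        alphas = 2.0 * np.pi * np.arange(nsteps) / nsteps
        return cls(biases=tuple(alphas), deltas=(2.0 * np.pi / nsteps,) * nsteps)


@dataclass
class WavePair:
    """Amplitude and phase maps of the sheared e- and o-waves."""

    grid: ImageGrid
    amplitude_e: np.ndarray
    amplitude_o: np.ndarray
    phase_e: np.ndarray
    phase_o: np.ndarray

    def __post_init__(self) -> None:
        for name in ("amplitude_e", "amplitude_o", "phase_e", "phase_o"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape {arr.shape} != grid {self.grid.shape}")
        if np.any(self.amplitude_e < 0) or np.any(self.amplitude_o < 0):
            raise ValueError("wave amplitudes must be non-negative")

    @property
    def phase_difference(self) -> np.ndarray:
        """theta_e - theta_o, the sheared phase difference."""
        return self.phase_e - self.phase_o


@dataclass
class Interferogram:
    """One recorded intensity frame at a fixed retarder bias."""

    grid: ImageGrid
    intensity: np.ndarray
    bias: float

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.grid.shape:
            raise ValueError("intensity shape does not match grid")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")


@dataclass
class InterferogramStack:
    """Bias series: one frame per schedule entry, sharing one grid."""

    frames: list[Interferogram]
    schedule: BiasSchedule
    optics: OpticalConfig

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.schedule):
            raise ValueError(
                f"{len(self.frames)} frames for a {len(self.schedule)}-level schedule"
            )
        grid = self.frames[0].grid
        for fr in self.frames[1:]:
            if not fr.grid.same_geometry(grid):
                raise ValueError("all frames must share one grid")

    @property
    def grid(self) -> ImageGrid:
        return self.frames[0].grid

    def intensities(self) -> np.ndarray:
        """Stacked intensities, shape ``(nframes, ny, nx)``."""
        return np.stack([fr.intensity for fr in self.frames])


# ---------------------------------------------------------------------------
# point-spread functions


def _airy_kernel(pixel_size: float, wavelength: float, na: float, amplitude: bool,
                 radius_factor: float = 10.0) -> np.ndarray:
    """Sampled Airy kernel out to ``radius_factor`` first-zero radii."""
    first_zero = 0.61 * wavelength / na
    half = max(int(np.ceil(radius_factor * first_zero / pixel_size)), 2)
    coords = np.arange(-half, half + 1) * pixel_size
    X, Y = np.meshgrid(coords, coords)
    v = 2.0 * np.pi * na * np.hypot(X, Y) / wavelength
    with np.errstate(invalid="ignore"):
        amp = np.where(v == 0, 1.0, 2.0 * special.j1(np.maximum(v, 1e-300)) / np.maximum(v, 1e-300))
    kern = amp if amplitude else amp**2
    return kern / kern.sum()


def airy_intensity_psf(pixel_size: float, wavelength: float, na: float) -> np.ndarray:
    """Normalized incoherent Airy intensity PSF (first zero at 0.61 lambda/NA)."""
    return _airy_kernel(pixel_size, wavelength, na, amplitude=False)


def airy_amplitude_psf(pixel_size: float, wavelength: float, na: float) -> np.ndarray:
    """Amplitude Airy PSF 2*J1(v)/v, normalized to unit sum so a flat field
    passes unchanged."""
    return _airy_kernel(pixel_size, wavelength, na, amplitude=True)


# ---------------------------------------------------------------------------
# forward operations


def _fourier_shift(arr: np.ndarray, shift_px: tuple[float, float]) -> np.ndarray:
    """Band-limited sub-pixel shift (periodic boundaries)."""
    return np.real(np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(arr), shift_px)))


def shear_phase_pair(phantom: PhasePhantom, optics: OpticalConfig) -> WavePair:
    """Split a pure-phase specimen into its e-/o-wave pair.

    The e-wave samples the phase at +s/2 along the shear axis and the o-wave
    at -s/2, so ``theta_e - theta_o`` approximates ``s * dPhi/dx``.
    Sub-pixel shears use band-limited (Fourier) interpolation.
    """
    s = optics.shear_distance
    ux, uy = optics.shear_axis
    px = phantom.grid.pixel_size
    # theta_e(x) = Phi(x + s/2): content moves by -s/2 along the axis
    half = (s / 2.0) / px
    theta_e = _fourier_shift(phantom.phase, (-half * uy, -half * ux))
    theta_o = _fourier_shift(phantom.phase, (half * uy, half * ux))
    ones = np.ones(phantom.grid.shape)
    return WavePair(grid=phantom.grid, amplitude_e=ones, amplitude_o=ones.copy(),
                    phase_e=theta_e, phase_o=theta_o)


def coherent_blur(pair: WavePair, optics: OpticalConfig) -> WavePair:
    """Convolve the complex e- and o-fields with the amplitude Airy PSF.

    This is the near-coherent image-formation model (condenser NA below the
    objective NA): the fields, not the intensities, are band-limited by the
    objective, and the recorded frames then interfere the blurred fields.
    """
    h = airy_amplitude_psf(pair.grid.pixel_size, optics.wavelength, optics.na_objective)
    out = {}
    for tag in ("e", "o"):
        field_c = getattr(pair, f"amplitude_{tag}") * np.exp(1j * getattr(pair, f"phase_{tag}"))
        blurred = signal.fftconvolve(field_c, h, mode="same")
        out[f"amplitude_{tag}"] = np.abs(blurred)
        out[f"phase_{tag}"] = np.angle(blurred)
    return WavePair(grid=pair.grid, **out)


def interferogram(pair: WavePair, bias: float) -> Interferogram:
    """Record one frame: I = Jo^2 + Je^2 + 2 Jo Je cos(theta_e - theta_o - alpha)."""
    je, jo = pair.amplitude_e, pair.amplitude_o
    intensity = jo**2 + je**2 + 2.0 * jo * je * np.cos(pair.phase_difference - bias)
    return Interferogram(grid=pair.grid, intensity=np.maximum(intensity, 0.0), bias=bias)


def psf_blur(image: Interferogram, optics: OpticalConfig) -> Interferogram:
    """Incoherent blur: convolve the intensity with the Airy intensity PSF.

    The kernel is normalized and the boundary reflected, so total intensity
    is conserved and a constant frame passes unchanged.
    """
    h = airy_intensity_psf(image.grid.pixel_size, optics.wavelength, optics.na_objective)
    half = h.shape[0] // 2
    padded = np.pad(image.intensity, half, mode="reflect")
    blurred = signal.fftconvolve(padded, h, mode="same")[half:-half, half:-half]
    return Interferogram(grid=image.grid, intensity=np.maximum(blurred, 0.0), bias=image.bias)


def add_shot_noise(stack: InterferogramStack, photons_per_unit: float, seed: int) -> InterferogramStack:
    """Poisson shot noise: each pixel becomes a draw with mean
    ``intensity * photons_per_unit``, rescaled back to intensity units."""
    if not photons_per_unit > 0:
        raise ValueError("photons_per_unit must be positive")
    rng = np.random.default_rng(seed)
    frames = [
        Interferogram(
            grid=fr.grid,
            intensity=rng.poisson(fr.intensity * photons_per_unit) / photons_per_unit,
            bias=fr.bias,
        )
        for fr in stack.frames
    ]
    return InterferogramStack(frames=frames, schedule=stack.schedule, optics=stack.optics)


def acquire_bias_series(
    phantom: PhasePhantom,
    optics: OpticalConfig,
    schedule: BiasSchedule,
    blur: bool | str = True,
    photons_per_unit: float | None = None,
    seed: int = 0,
) -> InterferogramStack:
    """Simulate a full phase-shifted acquisition.

    Parameters
    ----------
    blur : bool or {"coherent", "intensity", "none"}
        ``True``/``"coherent"`` blurs the complex fields with the amplitude
        PSF before interference (default); ``"intensity"`` blurs each
        recorded frame with the incoherent Airy PSF; ``False``/``"none"``
        skips diffraction.
    photons_per_unit : float, optional
        If given, Poisson shot noise at this photon budget per intensity
        unit per frame.
    """
    if len(schedule) == 0:
        raise ValueError("empty bias schedule")
    mode = {True: "coherent", False: "none"}.get(blur, blur)
    if mode not in ("coherent", "intensity", "none"):
        raise ValueError(f"unknown blur mode {blur!r}")
    pair = shear_phase_pair(phantom, optics)
    if mode == "coherent":
        pair = coherent_blur(pair, optics)
    frames = [interferogram(pair, alpha) for alpha in schedule.biases]
    if mode == "intensity":
        frames = [psf_blur(fr, optics) for fr in frames]
    stack = InterferogramStack(frames=frames, schedule=schedule, optics=optics)
    if photons_per_unit is not None:
        stack = add_shot_noise(stack, photons_per_unit, seed)
    return stack
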