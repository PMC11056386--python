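"""Ground-truth phase phantoms: spheres, flats and smooth random fields.

A transparent specimen delays the illuminating wavefront by

    phi(x, y) = (2*pi / lambda) * delta_n * t(x, y)

where ``delta_n`` is the refractive-index difference between specimen and
immersion medium and ``t`` the geometric thickness traversed.  For a sphere
of radius ``r`` the thickness is the chord length ``2*sqrt(r**2 - rho**2)``
at lateral distance ``rho`` from the center, so the peak delay of a bead of
diameter ``d`` is ``(2*pi/lambda) * delta_n * d``.  A 1 um polystyrene bead
(n = 1.588) in immersion oil (n = 1.518) at 650 nm therefore delays the
wavefront by about 0.68 rad at its center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import ImageGrid

__all__ = [
    "N_POLYSTYRENE",
    "N_IMMERSION_OIL",
    "N_WATER",
    "SphereSpec",
    "PhasePhantom",
    "make_sphere_phantom",
    "make_flat_phantom",
    "make_random_phantom",
]

# Refractive indices near 650 nm. Polystyrene dispersion fits give
# 1.586-1.589 at this wavelength; 1.588 is adopted package-wide.
N_POLYSTYRENE = 1.588
N_IMMERSION_OIL = 1.518
N_WATER = 1.333


@dataclass(frozen=True)
class SphereSpec:
    """A spherical bead: center (x, y) in um, diameter in um, and the
    refractive indices of particle and immersion medium."""

    center: tuple[float, float]
    diameter: float
    n_particle: float
    n_medium: float

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError(f"diameter must be positive, got {self.diameter}")
        for name, n in (("n_particle", self.n_particle), ("n_medium", self.n_medium)):
            if not 1.0 <= n <= 2.5:
                raise ValueError(f"{name} must lie in [1.0, 2.5], got {n}")

    @property
    def delta_n(self) -> float:
        return self.n_particle - self.n_medium


@dataclass
class PhasePhantom:
    """Ground-truth optical phase map (radians) on a calibrated grid."""

    grid: ImageGrid
    phase: np.ndarray
    wavelength: float

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.shape != self.grid.shape:
            raise ValueError(
                f"phase shape {self.phase.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phantom phase must be finite everywhere")
        if not self.wavelength > 0:
            raise ValueError("wavelength must be positive")

    @property
    def peak(self) -> float:
        return float(self.phase.max())


def make_sphere_phantom(
    grid: ImageGrid, spheres: list[SphereSpec], wavelength: float
) -> PhasePhantom:
    """Phase map of one or more beads, evaluated at pixel centers.

    Phases of overlapping spheres add (with a warning); a sphere whose
    projected disc extends past the grid is rejected.
    """
    if not wavelength > 0:
        raise ValueError("wavelength must be positive")
    height, width = grid.extent
    X, Y = grid.mesh()
    phase = np.zeros(grid.shape)
    support = np.zeros(grid.shape, dtype=bool)
    overlap_warned = False
    for sph in spheres:
        cx, cy = sph.center
        r = sph.diameter / 2.0
        if cx - r < 0 or cy - r < 0 or cx + r > width - grid.pixel_size or cy + r > height - grid.pixel_size:
            raise ValueError(
                f"sphere at ({cx}, {cy}) um with diameter {sph.diameter} um "
                f"extends past the {width:.3g} x {height:.3g} um grid"
            )
        rho2 = (X - cx) ** 2 + (Y - cy) ** 2
        inside = rho2 < r**2
        if not overlap_warned and np.any(inside & support):
            warnings.warn("overlapping spheres: phases are summed", stacklevel=2)
            overlap_warned = True
        chord = np.where(inside, 2.0 * np.sqrt(np.maximum(r**2 - rho2, 0.0)), 0.0)
        phase += (2.0 * np.pi / wavelength) * sph.delta_n * chord
        support |= inside
    return PhasePhantom(grid=grid, phase=phase, wavelength=wavelength)


def make_flat_phantom(
    grid: ImageGrid, phase_value: float = 0.0, wavelength: float = 0.65
) -> PhasePhantom:
    """Constant-phase specimen (null target for calibration tests)."""
    return PhasePhantom(
        grid=grid, phase=np.full(grid.shape, float(phase_value)), wavelength=wavelength
    )


def make_random_phantom(
    grid: ImageGrid,
    amplitude: float,
    correlation_length: float,
    seed: int,
    wavelength: float = 0.65,
) -> PhasePhantom:
    """Band-limited zero-mean random phase field.

    White Gaussian noise is smoothed with a Gaussian kernel of standard
    deviation ``correlation_length`` (in object space), re-centered to zero
    mean and rescaled so that ``max |phase| <= amplitude``.  The same seed
    always yields the same field.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if not correlation_length > 2 * grid.pixel_size:
        raise ValueError(
            "correlation_length must exceed 2 pixels "
            f"({2 * grid.pixel_size:.4g} um), got {correlation_length}"
        )
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(grid.shape)
    sigma_px = correlation_length / grid.pixel_size
    smooth = ndimage.gaussian_filter(white, sigma_px, mode="wrap")
    smooth -= smooth.mean()
    peak = np.abs(smooth).max()
    if peak > 0 and amplitude > 0:
        smooth *= amplitude / peak
    else:
        smooth = np.zeros(grid.shape)
    return PhasePhantom(grid=grid, phase=smooth, wavelength=wavelength)
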