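"""Validation metrics: robust peak phase, averaged particle traces,
Gaussian-fit FWHM and radially averaged profiles.

These reproduce the standard calibration measurements for a phase
microscope: the peak optical delay of a bead of known size and index checks
the phase scale, and the full width at half maximum of a Gaussian fitted to
the averaged trace of n identical beads measures the planar resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.feature import peak_local_max

from .reconstruction import PhaseImage

__all__ = [
    "ProfileFit",
    "Trace",
    "FitError",
    "peak_phase",
    "find_particles",
    "average_particle_trace",
    "fwhm_gaussian_fit",
    "radial_profile",
]

GAUSSIAN_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


class FitError(RuntimeError):
    """Raised when a profile fit fails to converge; carries the residual norm."""

    def __init__(self, message: str, residual_norm: float | None = None):
        super().__init__(message)
        self.residual_norm = residual_norm


@dataclass(frozen=True)
class ProfileFit:
    """Result of a Gaussian fit to a particle trace."""

    fwhm: float
    fwhm_se: float
    amplitude: float
    center: float
    offset: float
    n_particles: int

    def __post_init__(self) -> None:
        if not self.fwhm > 0:
            raise ValueError("fwhm must be positive")
        if self.fwhm_se < 0:
            raise ValueError("fwhm_se must be non-negative")


@dataclass(frozen=True)
class Trace:
    """A 1-D profile with object-space coordinates (micrometers)."""

    coords: np.ndarray
    values: np.ndarray
    n_averaged: int = 1


def peak_phase(phase: PhaseImage, neighborhood: int = 3) -> float:
    """Robust peak: maximum of the neighborhood-mean-filtered image.

    ``neighborhood`` is the side of the averaging square in pixels; keep it
    below half the PSF FWHM in pixels or the peak of a diffraction-limited
    particle is averaged down.
    """
    if phase.phase.size == 0:
        raise ValueError("empty phase image")
    if neighborhood <= 1:
        return float(phase.phase.max())
    smoothed = ndimage.uniform_filter(phase.phase, size=int(neighborhood))
    return float(smoothed.max())


def find_particles(
    phase: PhaseImage, min_separation: float, threshold_rel: float = 0.5
) -> list[tuple[float, float]]:
    """Detect particle centers: local maxima above ``threshold_rel`` of the
    global peak, separated by at least ``min_separation`` micrometers.
    Returns (x, y) centers in object space."""
    sep_px = max(int(round(min_separation / phase.grid.pixel_size)), 1)
    coords = peak_local_max(phase.phase, min_distance=sep_px, threshold_rel=threshold_rel)
    px = phase.grid.pixel_size
    return [(float(c * px), float(r * px)) for r, c in coords]


def average_particle_trace(
    phase: PhaseImage,
    detections: list[tuple[float, float]],
    half_window: float,
    axis: str = "x",
) -> Trace:
    """Mean 1-D profile through the detected particle centers.

    Traces are extracted along the shear axis (``axis="x"``, the default)
    or perpendicular to it, sampled at sub-pixel positions with cubic
    interpolation, and resampled onto a common coordinate grid centered on
    each detection.  Detections within half a window of the image edge are
    skipped with a warning.
    """
    if not detections:
        raise ValueError("empty detection list")
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    px = phase.grid.pixel_size
    height, width = phase.grid.extent
    n_half = int(round(half_window / px))
    offsets = np.arange(-n_half, n_half + 1) * px
    profiles = []
    for cx, cy in detections:
        if axis == "x":
            ok = half_window <= cx <= width - px - half_window and 0 <= cy <= height - px
            sample_x, sample_y = cx + offsets, np.full_like(offsets, cy)
        else:
            ok = half_window <= cy <= height - px - half_window and 0 <= cx <= width - px
            sample_x, sample_y = np.full_like(offsets, cx), cy + offsets
        if not ok:
            warnings.warn(
                f"detection at ({cx:.3g}, {cy:.3g}) um is within half a window of "
                "the edge; skipped",
                stacklevel=2,
            )
            continue
        prof = ndimage.map_coordinates(
            phase.phase, [sample_y / px, sample_x / px], order=3, mode="nearest"
        )
        profiles.append(prof)
    if not profiles:
        raise ValueError("all detections fell too close to the image edge")
    return Trace(coords=offsets, values=np.mean(profiles, axis=0), n_averaged=len(profiles))


def _gaussian(x: np.ndarray, amplitude: float, center: float, sigma: float, offset: float) -> np.ndarray:
    return amplitude * np.exp(-((x - center) ** 2) / (2.0 * sigma**2)) + offset


def fwhm_gaussian_fit(trace: Trace) -> ProfileFit:
    """Least-squares Gaussian fit (amplitude, center, sigma, offset) of a
    single-peaked trace; FWHM = 2*sqrt(2*ln 2)*sigma with its standard
    error propagated from the fit covariance."""
    x, y = np.asarray(trace.coords, float), np.asarray(trace.values, float)
    if x.size < 5:
        raise ValueError("trace too short for a 4-parameter fit")
    offset0 = float(np.min(y))
    amp0 = float(np.max(y) - offset0)
    center0 = float(x[np.argmax(y)])
    weights = np.clip(y - offset0, 0, None)
    if weights.sum() > 0:
        sigma0 = float(np.sqrt(np.sum(weights * (x - center0) ** 2) / weights.sum()))
    else:
        sigma0 = float(np.ptp(x)) / 4.0
    sigma0 = max(sigma0, float(np.min(np.diff(x))) / 2.0)
    try:
        popt, pcov = optimize.curve_fit(
            _gaussian, x, y, p0=[amp0, center0, sigma0, offset0], maxfev=20000
        )
    except RuntimeError as exc:
        resid = float(np.linalg.norm(y - _gaussian(x, amp0, center0, sigma0, offset0)))
        raise FitError(f"Gaussian fit did not converge: {exc}", resid) from exc
    amp, center, sigma, offset = popt
    sigma = abs(float(sigma))
    sigma_se = float(np.sqrt(pcov[2, 2])) if np.all(np.isfinite(pcov)) else 0.0
    return ProfileFit(
        fwhm=GAUSSIAN_FWHM_FACTOR * sigma,
        fwhm_se=GAUSSIAN_FWHM_FACTOR * sigma_se,
        amplitude=float(amp),
        center=float(center),
        offset=float(offset),
        n_particles=trace.n_averaged,
    )


def radial_profile(
    phase: PhaseImage,
    start: tuple[float, float],
    end: tuple[float, float],
    width: float,
    n_samples: int | None = None,
) -> Trace:
    """Phase averaged over a transverse band along a line segment.

    At each position along the segment from ``start`` to ``end`` (um), the
    phase is averaged over ``width`` micrometers perpendicular to it.
    """
    px = phase.grid.pixel_size
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    length = float(np.linalg.norm(end - start))
    if length == 0:
        raise ValueError("segment has zero length")
    height, wid = phase.grid.extent
    for pt in (start, end):
        if not (0 <= pt[0] <= wid - px and 0 <= pt[1] <= height - px):
            raise ValueError(f"segment endpoint {tuple(pt)} outside the image")
    if n_samples is None:
        n_samples = max(int(round(length / px)) + 1, 2)
    direction = (end - start) / length
    normal = np.array([-direction[1], direction[0]])
    along = np.linspace(0.0, length, n_samples)
    n_trans = max(int(round(width / px)) + 1, 1)
    trans = np.linspace(-width / 2.0, width / 2.0, n_trans) if n_trans > 1 else np.array([0.0])
    pts = (start[None, None, :]
           + along[:, None, None] * direction[None, None, :]
           + trans[None, :, None] * normal[None, None, :])
    values = ndimage.map_coordinates(
        phase.phase, [pts[..., 1].ravel() / px, pts[..., 0].ravel() / px],
        order=1, mode="nearest",
    ).reshape(n_samples, n_trans)
    return Trace(coords=along, values=values.mean(axis=1), n_averaged=n_trans)


def metrics_table(entries: list[dict]) -> pd.DataFrame:
    """Assemble a plain metrics table (metric, value, se, n, units)."""
    return pd.DataFrame(entries, columns=["metric", "value", "se", "n", "units"])
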