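"""Object-space pixel grids shared by phantoms, interferograms and phase maps.

All physical lengths in this package are object-space micrometers; the
gradient (shear) axis is ``x``, the second (fastest-varying) array axis.
The grid origin sits at array element ``(0, 0)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ImageGrid"]


@dataclass(frozen=True)
class ImageGrid:
    """A regular 2-D pixel grid in object space.

    Parameters
    ----------
    ny, nx : int
        Pixel counts along the slow (y) and fast (x) axes; at least 8 each.
    pixel_size : float
        Object-space size of one pixel, micrometers.
    """

    ny: int
    nx: int
    pixel_size: float

    def __post_init__(self) -> None:
        if self.ny < 8 or self.nx < 8:
            raise ValueError(f"grid must be at least 8x8, got {self.ny}x{self.nx}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def extent(self) -> tuple[float, float]:
        """(height, width) of the field of view in micrometers."""
        return (self.ny * self.pixel_size, self.nx * self.pixel_size)

    def x_coords(self) -> np.ndarray:
        """Pixel-center x coordinates (micrometers), shape ``(nx,)``."""
        return np.arange(self.nx) * self.pixel_size

    def y_coords(self) -> np.ndarray:
        """Pixel-center y coordinates (micrometers), shape ``(ny,)``."""
        return np.arange(self.ny) * self.pixel_size

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid ``(X, Y)`` of pixel-center coordinates, each ``(ny, nx)``."""
        return np.meshgrid(self.x_coords(), self.y_coords())

    def same_geometry(self, other: "ImageGrid", rtol: float = 1e-9) -> bool:
        return (
            self.ny == other.ny
            and self.nx == other.nx
            and np.isclose(self.pixel_size, other.pixel_size, rtol=rtol)
        )
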