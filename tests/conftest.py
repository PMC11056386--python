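import numpy as np
import pytest

from grom import (
    ImageGrid,
    OpticalConfig,
    SphereSpec,
    make_sphere_phantom,
)

WAVELENGTH = 0.65


@pytest.fixture
def nyquist_optics():
    """NA 0.75 system sampled at lambda/(4 NA)."""
    return OpticalConfig.nyquist(0.75, WAVELENGTH)


@pytest.fixture
def fine_grid():
    """Fine grid (20 nm pixels) resolving a 1 um bead well."""
    return ImageGrid(ny=96, nx=96, pixel_size=0.02)


@pytest.fixture
def bead_phantom(nyquist_optics):
    """Single 1 um polystyrene-in-oil bead at Nyquist sampling."""
    grid = ImageGrid(ny=64, nx=64, pixel_size=nyquist_optics.pixel_size)
    h, w = grid.extent
    sphere = SphereSpec(center=(w / 2, h / 2), diameter=1.0,
                        n_particle=1.588, n_medium=1.518)
    return make_sphere_phantom(grid, [sphere], WAVELENGTH)


def constant_pair_stack(value, nsteps, grid=None, amplitude=1.0):
    """Noiseless stack whose sheared phase difference is `value` everywhere."""
    from grom import BiasSchedule, Interferogram, InterferogramStack, OpticalConfig

    if grid is None:
        grid = ImageGrid(ny=8, nx=8, pixel_size=0.2)
    schedule = BiasSchedule.uniform(nsteps)
    optics = OpticalConfig.nyquist(0.75, WAVELENGTH)
    frames = [
        Interferogram(
            grid=grid,
            intensity=np.full(grid.shape,
                              2 * amplitude**2 * (1 + np.cos(value - a))),
            bias=a,
        )
        for a in schedule.biases
    ]
    return InterferogramStack(frames=frames, schedule=schedule, optics=optics)
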