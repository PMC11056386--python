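"""File formats: multi-page float32 TIFF for image stacks, YAML sidecar
configs carrying the physical metadata (wavelength, pixel size, bias
schedule, shear), and CSV metrics tables.

TIFF page order defines bias order; the schedule lives in the sidecar, not
in per-page tags.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .grids import ImageGrid
from .forward import BiasSchedule, Interferogram, InterferogramStack, OpticalConfig
from .phantom import PhasePhantom
from .reconstruction import PhaseImage

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "save_phantom",
    "load_phantom",
    "save_stack",
    "load_stack",
    "save_image",
    "load_image",
]


@dataclass
class RunConfig:
    """Everything needed to rerun a simulation or reconstruction."""

    optics: OpticalConfig = field(default_factory=OpticalConfig)
    nsteps: int = 16
    grid_ny: int = 128
    grid_nx: int = 128
    sphere_diameter: float = 1.0
    sphere_n_particle: float = 1.588
    sphere_n_medium: float = 1.518
    blur: str = "coherent"
    photons_per_unit: float | None = None
    seed: int = 0
    method: str = "hilbert"
    background_radius: float | None = None
    snr_parameter: float = 100.0

    def __post_init__(self) -> None:
        # YAML 1.1 reads "1.0e4" as a string; coerce numeric fields
        for name in ("sphere_diameter", "sphere_n_particle", "sphere_n_medium",
                     "snr_parameter"):
            setattr(self, name, float(getattr(self, name)))
        for name in ("photons_per_unit", "background_radius"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, float(value))
        self.nsteps = int(self.nsteps)
        self.seed = int(self.seed)

    def schedule(self) -> BiasSchedule:
        return BiasSchedule.uniform(self.nsteps)

    def grid(self) -> ImageGrid:
        return ImageGrid(ny=self.grid_ny, nx=self.grid_nx,
                         pixel_size=self.optics.pixel_size)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["optics"]["shear_axis"] = list(self.optics.shear_axis)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        opt = dict(d.pop("optics", {}))
        if "shear_axis" in opt:
            opt["shear_axis"] = tuple(opt["shear_axis"])
        known = {f for f in cls.__dataclass_fields__ if f != "optics"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {', '.join(sorted(unknown))}")
        return cls(optics=OpticalConfig(**opt), **d)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def _write_tiff(path: Path, data: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(data, dtype=np.float32),
                     photometric="minisblack")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def save_phantom(phantom: PhasePhantom, path: str | Path) -> None:
    """Single-plane float32 TIFF plus a key-value sidecar with the
    wavelength and pixel size."""
    path = Path(path)
    _write_tiff(path, phantom.phase)
    meta = {"pixel_size_um": phantom.grid.pixel_size,
            "wavelength_um": phantom.wavelength,
            "kind": "phase_phantom"}
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def load_phantom(path: str | Path) -> PhasePhantom:
    path = Path(path)
    phase = tifffile.imread(path).astype(float)
    with open(_sidecar(path)) as fh:
        meta = yaml.safe_load(fh)
    grid = ImageGrid(ny=phase.shape[0], nx=phase.shape[1],
                     pixel_size=float(meta["pixel_size_um"]))
    return PhasePhantom(grid=grid, phase=phase, wavelength=float(meta["wavelength_um"]))


def save_stack(stack: InterferogramStack, path: str | Path) -> None:
    """Multi-page float32 TIFF, page order = bias order, plus sidecar."""
    path = Path(path)
    _write_tiff(path, stack.intensities())
    meta = {
        "pixel_size_um": stack.grid.pixel_size,
        "wavelength_um": stack.optics.wavelength,
        "biases_rad": [float(b) for b in stack.schedule.biases],
        "deltas_rad": [float(d) for d in stack.schedule.deltas],
        "na_objective": stack.optics.na_objective,
        "na_condenser": stack.optics.na_condenser,
        "magnification": stack.optics.magnification,
        "camera_pixel_um": stack.optics.camera_pixel,
        "shear_distance_um": stack.optics.shear_distance,
        "shear_axis": list(stack.optics.shear_axis),
        "kind": "interferogram_stack",
    }
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def load_stack(path: str | Path) -> InterferogramStack:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    if data.ndim == 2:
        data = data[None]
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"stack {path} is missing its metadata sidecar {sidecar.name} "
            "(pixel size and bias schedule are required)"
        )
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    optics = OpticalConfig(
        wavelength=float(meta["wavelength_um"]),
        na_objective=float(meta.get("na_objective", 0.75)),
        na_condenser=float(meta.get("na_condenser", 0.30)),
        magnification=float(meta.get("magnification", 1.0)),
        camera_pixel=float(meta["pixel_size_um"]) * float(meta.get("magnification", 1.0)),
        shear_distance=float(meta["shear_distance_um"]),
        shear_axis=tuple(meta.get("shear_axis", (1.0, 0.0))),
    )
    schedule = BiasSchedule(
        biases=tuple(float(b) for b in meta["biases_rad"]),
        deltas=tuple(float(d) for d in meta["deltas_rad"]),
    )
    if data.shape[0] != len(schedule):
        raise ValueError(
            f"stack has {data.shape[0]} pages but the schedule lists "
            f"{len(schedule)} bias levels"
        )
    grid = ImageGrid(ny=data.shape[1], nx=data.shape[2],
                     pixel_size=float(meta["pixel_size_um"]))
    frames = [Interferogram(grid=grid, intensity=np.maximum(data[i], 0.0),
                            bias=schedule.biases[i]) for i in range(data.shape[0])]
    return InterferogramStack(frames=frames, schedule=schedule, optics=optics)


def save_image(image: PhaseImage, path: str | Path, wavelength: float | None = None) -> None:
    path = Path(path)
    _write_tiff(path, image.phase)
    meta = {"pixel_size_um": image.grid.pixel_size, "method": image.method,
            "kind": "phase_image"}
    if wavelength is not None:
        meta["wavelength_um"] = wavelength
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def load_image(path: str | Path) -> PhaseImage:
    path = Path(path)
    phase = tifffile.imread(path).astype(float)
    with open(_sidecar(path)) as fh:
        meta = yaml.safe_load(fh)
    grid = ImageGrid(ny=phase.shape[0], nx=phase.shape[1],
                     pixel_size=float(meta["pixel_size_um"]))
    return PhaseImage(grid=grid, phase=phase, method=str(meta.get("method", "unknown")))
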