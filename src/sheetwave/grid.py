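"""Core computational-grid and field containers.

Conventions used throughout the package:

* All lengths are in micrometers; ``wavelength`` is always the *vacuum*
  wavelength, and the vacuum wavenumber is ``k0 = 2 pi / wavelength``.
* Volumes are stored z-major, shape ``(nz, ny, nx)``, matching multi-page
  (ImageJ-style) TIFF page order.  The propagator always advances along
  axis 0; imaging geometries with an orthogonal detection/illumination
  axis are handled by the explicit reorientation helpers below, never by
  a second propagator.
* Transverse fields are stored as 2D complex arrays of shape ``(ny, nx)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "Grid3D",
    "ComplexField",
    "RefractiveVolume",
    "FluorophoreVolume",
    "reorient_for_detection",
    "reorient_for_illumination",
    "restore_from_illumination",
]


@dataclass(frozen=True)
class Grid3D:
    """Regular 3D voxel grid.

    Parameters
    ----------
    nx, ny, nz
        Voxel counts along x (fastest axis), y, and z (page axis).
    dx, dy, dz
        Voxel pitch in micrometers.
    origin
        Marker for the coordinate convention.  ``"corner"`` puts the
        coordinate origin at the center of voxel ``[0, 0, 0]``;
        ``"center"`` at the grid center.  Only a label — helpers that
        need coordinates compute them explicitly.
    """

    nx: int
    ny: int
    nz: int
    dx: float
    dy: float
    dz: float
    origin: Literal["corner", "center"] = "center"

    def __post_init__(self) -> None:
        for name in ("nx", "ny", "nz"):
            if getattr(self, name) < 8:
                raise ValueError(f"{name} must be >= 8, got {getattr(self, name)}")
        for name in ("dx", "dy", "dz"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape ``(nz, ny, nx)``."""
        return (self.nz, self.ny, self.nx)

    @property
    def transverse_shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size (Lx, Ly, Lz) in micrometers."""
        return (self.nx * self.dx, self.ny * self.dy, self.nz * self.dz)

    def x_coords(self) -> np.ndarray:
        return (np.arange(self.nx) - self.nx / 2) * self.dx

    def y_coords(self) -> np.ndarray:
        return (np.arange(self.ny) - self.ny / 2) * self.dy

    def z_coords(self) -> np.ndarray:
        """Axial slice coordinates; z=0 is the entrance face plus dz/2."""
        return (np.arange(self.nz) + 0.5) * self.dz


@dataclass
class ComplexField:
    """A 2D transverse complex scalar field u(x, y) at one axial plane."""

    values: np.ndarray
    dx: float
    dy: float
    wavelength: float
    z_position: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2:
            raise ValueError("field values must be 2D (ny, nx)")
        if not (self.dx > 0 and self.dy > 0 and self.wavelength > 0):
            raise ValueError("dx, dy and wavelength must be positive")

    @property
    def k0(self) -> float:
        """Vacuum wavenumber 2*pi/lambda in rad/um."""
        return 2.0 * np.pi / self.wavelength

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def power(self) -> float:
        """Total power  sum |u|^2 dx dy."""
        return float(np.sum(np.abs(self.values) ** 2) * self.dx * self.dy)

    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2

    def copy(self) -> "ComplexField":
        return replace(self, values=self.values.copy())

    def assert_finite(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")


@dataclass
class RefractiveVolume:
    """Complex refractive-index map n(z, y, x) on a regular grid.

    The real part is the refractive index (bounded to [1, 2] for
    biological plausibility), the non-negative imaginary part encodes
    absorption (Beer-Lambert attenuation exp(-k0*Im(n)*dz) per step).
    """

    grid: Grid3D
    n: np.ndarray
    n_ambient: float = 1.33

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n)
        if not np.iscomplexobj(self.n):
            self.n = self.n.astype(np.complex128)
        if self.n.shape != self.grid.shape:
            raise ValueError(
                f"index array shape {self.n.shape} != grid shape {self.grid.shape}"
            )
        self.validate()

    def validate(self) -> None:
        if not np.all(np.isfinite(self.n)):
            raise ValueError("refractive index contains non-finite values")
        re = self.n.real
        if re.min() < 1.0 - 1e-9 or re.max() > 2.0 + 1e-9:
            raise ValueError(
                f"real index outside [1, 2]: range [{re.min()}, {re.max()}]"
            )
        if self.n.imag.min() < -1e-12:
            raise ValueError("negative absorption (Im(n) < 0)")

    @property
    def is_lossless(self) -> bool:
        return bool(np.all(self.n.imag == 0))

    def slice_mean_index(self) -> np.ndarray:
        """Per-slice mean real index, the per-slice diffraction reference."""
        return self.n.real.mean(axis=(1, 2))


@dataclass
class FluorophoreVolume:
    """Non-negative fluorophore density (arbitrary units) on a grid."""

    grid: Grid3D
    density: np.ndarray

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=np.float64)
        if self.density.shape != self.grid.shape:
            raise ValueError("density shape does not match grid")
        if not np.all(np.isfinite(self.density)):
            raise ValueError("density contains non-finite values")
        if self.density.min() < 0:
            raise ValueError("density must be non-negative")


def _reoriented_grid(grid: Grid3D, axes: tuple[int, int, int]) -> Grid3D:
    # sizes/pitches indexed in (z, y, x) order
    counts = (grid.nz, grid.ny, grid.nx)
    pitch = (grid.dz, grid.dy, grid.dx)
    nz, ny, nx = (counts[a] for a in axes)
    dz, dy, dx = (pitch[a] for a in axes)
    return Grid3D(nx=nx, ny=ny, nz=nz, dx=dx, dy=dy, dz=dz, origin=grid.origin)


def reorient_for_detection(arr: np.ndarray, grid: Grid3D) -> tuple[np.ndarray, Grid3D]:
    """Identity reorientation: detection is the stored z (page) axis.

    Kept as an explicit, tested no-op so call sites document their axis
    choice.
    """
    return arr, grid


def reorient_for_illumination(
    arr: np.ndarray, grid: Grid3D
) -> tuple[np.ndarray, Grid3D]:
    """Reorient a (z, y, x) volume so the lab x axis becomes the
    propagation (page) axis.

    The returned array has shape (nx, ny, nz): propagation along lab x,
    transverse axes (row, col) = (lab y, lab z).
    """
    out = np.ascontiguousarray(np.transpose(arr, (2, 1, 0)))
    return out, _reoriented_grid(grid, (2, 1, 0))


def restore_from_illumination(
    arr: np.ndarray, grid: Grid3D
) -> tuple[np.ndarray, Grid3D]:
    """Inverse of :func:`reorient_for_illumination`."""
    out = np.ascontiguousarray(np.transpose(arr, (2, 1, 0)))
    return out, _reoriented_grid(grid, (2, 1, 0))
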