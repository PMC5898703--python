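"""Split-step beam propagation through inhomogeneous refractive media.

The scheme alternates exact (non-paraxial) angular-spectrum diffraction
steps through a homogeneous reference index ``n0`` with thin refractive
phase screens carrying the local index contrast ``n - n0``:

* diffraction:   U(kx,ky) <- U * exp(i dz sqrt((n0 k0)^2 - kx^2 - ky^2))
* phase screen:  u(x,y)   <- u * exp(i k0 (n(x,y) - n0) dz)

A symmetric (Strang) splitting — half diffraction step, full phase
screen, half diffraction step — gives second-order accuracy in dz.  The
reference index may be held global (the ambient immersion index) or be
locally re-expanded per slice as the slice-mean real index, which
minimizes the phase-screen residual and keeps the scheme accurate beyond
the strictly paraxial regime.

Transverse spatial frequencies beyond the propagating band
(kx^2 + ky^2 > (n0 k0)^2) are evanescent; they are either zeroed
(default, keeps power bookkeeping exact) or physically damped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field
from typing import Literal

import numpy as np
from scipy import fft as sp_fft

from .grid import ComplexField, Grid3D, RefractiveVolume

__all__ = [
    "PropagatorConfig",
    "BPMResult",
    "free_space_step",
    "phase_screen_step",
    "propagate",
    "absorbing_frame",
]


@dataclass(frozen=True)
class PropagatorConfig:
    """Knobs of the split-step propagator.

    n_ref_mode
        ``"global"`` uses the volume's ambient index as diffraction
        reference for every step; ``"per_slice_mean"`` re-expands around
        the mean real index of each slice.
    evanescent_policy
        ``"zero"`` removes evanescent modes; ``"decay"`` damps them with
        their physical exponential decay.
    boundary
        ``"periodic"`` (the raw FFT behaviour) or ``"absorbing"``, which
        applies a super-Gaussian absorbing frame of ``absorb_width``
        pixels each step to suppress wrap-around.
    store
        ``"none"``, ``"field"`` (per-plane complex field) or
        ``"intensity"`` (per-plane |u|^2).
    """

    n_ref_mode: Literal["global", "per_slice_mean"] = "global"
    evanescent_policy: Literal["zero", "decay"] = "zero"
    boundary: Literal["periodic", "absorbing"] = "periodic"
    absorb_width: int = 16
    absorb_strength: float = 4.0
    store: Literal["none", "field", "intensity"] = "none"

    def validate_for(self, grid: Grid3D) -> None:
        if self.boundary == "absorbing" and self.absorb_width >= min(grid.nx, grid.ny) // 2:
            raise ValueError("absorbing frame width must be < min(nx, ny)/2")


@dataclass
class BPMResult:
    """Output of :func:`propagate`."""

    final: ComplexField
    record: np.ndarray | None = None  # (nz, ny, nx) complex or float
    plane_power: np.ndarray | None = None  # (nz,) power after each slice
    n_ref_used: np.ndarray | None = None  # (nz,) reference index per step


def _k_transverse_sq(shape: tuple[int, int], dx: float, dy: float) -> np.ndarray:
    ky = 2.0 * np.pi * sp_fft.fftfreq(shape[0], d=dy)
    kx = 2.0 * np.pi * sp_fft.fftfreq(shape[1], d=dx)
    return ky[:, None] ** 2 + kx[None, :] ** 2


def _transfer_function(
    shape: tuple[int, int],
    dx: float,
    dy: float,
    wavelength: float,
    dz: float,
    n0: float,
    policy: str,
) -> np.ndarray:
    """Angular-spectrum kernel exp(i dz kz) with the chosen evanescent policy."""
    k0 = 2.0 * np.pi / wavelength
    k2 = (n0 * k0) ** 2
    krsq = _k_transverse_sq(shape, dx, dy)
    arg = k2 - krsq
    prop = arg >= 0.0
    kz = np.sqrt(np.abs(arg))
    H = np.empty(shape, dtype=np.complex128)
    H[prop] = np.exp(1j * dz * kz[prop])
    if policy == "zero":
        H[~prop] = 0.0
    elif policy == "decay":
        # physical decay exp(-dz*sqrt(krsq - k^2)); |dz| guards reverse steps
        H[~prop] = np.exp(-abs(dz) * kz[~prop])
    else:
        raise ValueError(f"unknown evanescent policy {policy!r}")
    return H


def _apply_transfer(values: np.ndarray, H: np.ndarray) -> np.ndarray:
    return sp_fft.ifft2(H * sp_fft.fft2(values))


def free_space_step(
    field: ComplexField,
    dz: float,
    n0: float,
    evanescent_policy: str = "zero",
) -> ComplexField:
    """Advance a field by ``dz`` through homogeneous index ``n0``.

    Uses the exact scalar propagator; propagating modes acquire the
    phase ``dz*sqrt((n0 k0)^2 - kr^2)``, evanescent modes are zeroed or
    exponentially damped according to the policy.  Power in the
    propagating band is conserved exactly (the kernel is unimodular
    there).
    """
    if not n0 > 0:
        raise ValueError(f"reference index must be positive, got {n0}")
    field.assert_finite()
    if dz < 0:
        raise ValueError("dz must be non-negative; conjugate the field to go back")
    _sampling_warning(field, n0)
    if dz == 0:
        return field.copy()
    H = _transfer_function(
        field.shape, field.dx, field.dy, field.wavelength, dz, n0, evanescent_policy
    )
    out = field.copy()
    out.values = _apply_transfer(field.values, H)
    out.z_position = field.z_position + dz
    return out


def _free_space_signed(
    field: ComplexField, dz: float, n0: float, policy: str
) -> ComplexField:
    """Internal helper allowing signed dz (used by ideal-lens refocus)."""
    H = _transfer_function(
        field.shape, field.dx, field.dy, field.wavelength, dz, n0, policy
    )
    out = field.copy()
    out.values = _apply_transfer(field.values, H)
    out.z_position = field.z_position + dz
    return out


def phase_screen_step(
    field: ComplexField,
    n_slice: np.ndarray,
    n0: float,
    dz: float,
) -> ComplexField:
    """Apply the thin phase screen of one slice: u *= exp(i k0 (n - n0) dz).

    A positive imaginary index part attenuates pointwise
    (Beer-Lambert, amplitude factor exp(-k0 Im(n) dz)).
    """
    n_slice = np.asarray(n_slice)
    if n_slice.shape != field.shape:
        raise ValueError(
            f"slice shape {n_slice.shape} does not match field shape {field.shape}"
        )
    out = field.copy()
    out.values = field.values * np.exp(1j * field.k0 * (n_slice - n0) * dz)
    return out


def absorbing_frame(
    shape: tuple[int, int], width: int, strength: float = 4.0
) -> np.ndarray:
    """Super-Gaussian absorbing frame, 1 in the interior, ->exp(-strength)
    at the outermost pixel; suppresses periodic wrap-around."""
    def profile(n: int) -> np.ndarray:
        p = np.ones(n)
        if width > 0:
            edge = np.arange(width)
            ramp = np.exp(-strength * ((width - edge) / width) ** 4)
            p[:width] = ramp
            p[n - width:] = ramp[::-1]
        return p

    return profile(shape[0])[:, None] * profile(shape[1])[None, :]


def _sampling_warning(field: ComplexField, n_max: float) -> None:
    limit = field.wavelength / (2.0 * n_max)
    if field.dx > limit or field.dy > limit:
        warnings.warn(
            f"transverse pitch {max(field.dx, field.dy):.3g} um exceeds lambda/(2 n) "
            f"= {limit:.3g} um; high-angle content is undersampled",
            stacklevel=3,
        )


def propagate(
    initial: ComplexField,
    volume: RefractiveVolume,
    config: PropagatorConfig | None = None,
    z_start: int = 0,
    z_stop: int | None = None,
) -> BPMResult:
    """Propagate a field through slices ``z_start .. z_stop`` of a volume.

    Symmetric split step per slice: half diffraction step, phase screen,
    half diffraction step.  ``z_stop`` is exclusive; defaults to the
    full depth.  The optional per-plane record stores the field (or
    intensity) *after* each slice.
    """
    if config is None:
        config = PropagatorConfig()
    grid = volume.grid
    config.validate_for(grid)
    if not (
        np.isclose(initial.dx, grid.dx, rtol=1e-9)
        and np.isclose(initial.dy, grid.dy, rtol=1e-9)
    ):
        raise ValueError(
            f"field pitch ({initial.dx}, {initial.dy}) does not match volume "
            f"transverse pitch ({grid.dx}, {grid.dy})"
        )
    if initial.shape != grid.transverse_shape:
        raise ValueError("field shape does not match volume transverse shape")
    initial.assert_finite()
    if grid.dz > grid.dx:
        warnings.warn(
            f"axial step dz={grid.dz} exceeds transverse pitch dx={grid.dx}; "
            "split-step accuracy degrades",
            stacklevel=2,
        )

    if z_stop is None:
        z_stop = grid.nz
    n_steps = z_stop - z_start
    if n_steps < 0:
        raise ValueError("z_stop must be >= z_start")

    dz = grid.dz
    policy = config.evanescent_policy
    slice_means = (
        volume.slice_mean_index() if config.n_ref_mode == "per_slice_mean" else None
    )
    frame = (
        absorbing_frame(grid.transverse_shape, config.absorb_width, config.absorb_strength)
        if config.boundary == "absorbing"
        else None
    )

    u = initial.copy()
    record: np.ndarray | None = None
    if config.store == "field":
        record = np.empty((n_steps,) + grid.transverse_shape, dtype=np.complex128)
    elif config.store == "intensity":
        record = np.empty((n_steps,) + grid.transverse_shape, dtype=np.float64)
    plane_power = np.empty(n_steps)
    n_ref_used = np.empty(n_steps)

    half_cache: dict[float, np.ndarray] = {}
    for i, j in enumerate(range(z_start, z_stop)):
        n0 = float(slice_means[j]) if slice_means is not None else volume.n_ambient
        if n0 not in half_cache:
            half_cache[n0] = _transfer_function(
                u.shape, u.dx, u.dy, u.wavelength, dz / 2.0, n0, policy
            )
        H = half_cache[n0]
        u.values = _apply_transfer(u.values, H)
        u = phase_screen_step(u, volume.n[j], n0, dz)
        if frame is not None:
            u.values = u.values * frame
        u.values = _apply_transfer(u.values, H)
        u.z_position += dz
        plane_power[i] = u.power()
        n_ref_used[i] = n0
        if config.store == "field":
            record[i] = u.values
        elif config.store == "intensity":
            record[i] = np.abs(u.values) ** 2

    return BPMResult(final=u, record=record, plane_power=plane_power, n_ref_used=n_ref_used)
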