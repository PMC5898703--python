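"""Adaptive optics in silico: guide-star phase conjugation, focus
metrics, the shift-shift memory effect, and mean-free-path estimation.

The central physics is reciprocity of the lossless split-step scheme:
light emitted by a point source (guide star) inside the tissue and
recorded at the surface can be conjugated and sent back, and it
refocuses onto the guide star essentially perfectly.  Translating the
conjugated wavefront laterally degrades the focus over a scale set by
the medium's speckle statistics — the shift-shift memory effect; the
focus-survival curve C(dx) is compared against the autocorrelation of
the speckle a plane wave produces at the same depth.

Depth is naturally measured in scattering mean free paths l_s, the
1/e decay length of the *ballistic* (coherent) power
|<u(z)>|^2 ~ exp(-z/l_s); the estimator below uses the transverse/
ensemble mean field, which applies to continuous media where no
per-scatterer cross-section exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np
from scipy import fft as sp_fft

from .bpm import PropagatorConfig, propagate
from .fields import PupilSpec, SourceSpec, make_field
from .grid import ComplexField, Grid3D, RefractiveVolume

__all__ = [
    "FocusReport",
    "MemoryEffectCurve",
    "guidestar_exit_wavefront",
    "conjugate_and_focus",
    "memory_effect_curve",
    "estimate_mean_free_path",
]


@dataclass
class FocusReport:
    """Quality metrics of a (corrected) focus."""

    peak_intensity: float
    strehl: float
    fwhm_lateral: float  # um
    fwhm_axial: float  # um
    position_error: float  # um, |found peak - requested focus|
    peak_position: tuple[float, float, float]  # (x, y, z) um

    def __post_init__(self) -> None:
        if not -1e-6 <= self.strehl <= 1.05:
            raise ValueError(f"unphysical Strehl ratio {self.strehl}")


@dataclass
class MemoryEffectCurve:
    """Focus survival C(dx) and the reference speckle autocorrelation."""

    shifts: np.ndarray  # um
    C: np.ndarray
    reference: np.ndarray
    depth_um: float
    depth_mfp: float | None = None
    mode: str = "peak_ratio"


def _source_slice_index(grid: Grid3D, z: float) -> int:
    j = int(round(z / grid.dz))
    return min(max(j, 1), grid.nz)


def _reversed_subvolume(volume: RefractiveVolume, j_src: int) -> RefractiveVolume:
    """Slices 0..j_src-1 flipped so propagation runs source -> entry face."""
    sub = volume.n[:j_src][::-1].copy()
    g = volume.grid
    grid = Grid3D(nx=g.nx, ny=g.ny, nz=j_src, dx=g.dx, dy=g.dy, dz=g.dz, origin=g.origin)
    return RefractiveVolume(grid=grid, n=sub, n_ambient=volume.n_ambient)


def guidestar_exit_wavefront(
    volume: RefractiveVolume,
    source_pos: tuple[float, float, float],
    na: float,
    wavelength: float,
    config: PropagatorConfig | None = None,
) -> ComplexField:
    """Field of an embedded point emitter recorded at the entry (z=0) face.

    The guide star is an ideal NA-capped point source at ``source_pos``;
    its emission toward the entry surface is obtained by propagating
    through the flipped slice stack between the source plane and z=0.
    """
    if config is None:
        config = PropagatorConfig()
    grid = volume.grid
    j_src = _source_slice_index(grid, source_pos[2])
    pupil = PupilSpec(na=na, wavelength=wavelength, n0=volume.n_ambient)
    src = make_field(
        SourceSpec(
            kind="point_source",
            pupil=pupil,
            focus_position=(source_pos[0], source_pos[1], 0.0),
        ),
        grid,
    )
    rev = _reversed_subvolume(volume, j_src)
    res = propagate(src, rev, config)
    out = res.final
    out.z_position = 0.0
    return out


def _focus_metrics(record: np.ndarray, grid: Grid3D, target: tuple[float, float, float]):
    """Peak intensity, peak position, lateral and axial FWHM near target."""
    iz, iy, ix = np.unravel_index(np.argmax(record), record.shape)
    peak = float(record[iz, iy, ix])
    x = grid.x_coords()[ix]
    y = grid.y_coords()[iy]
    z = grid.z_coords()[iz]

    def fwhm_1d(profile: np.ndarray, pitch: float) -> float:
        p = profile - profile.max() / 2.0
        i0 = int(np.argmax(profile))
        left = right = None
        for i in range(i0, 0, -1):
            if p[i - 1] < 0 <= p[i]:
                left = (i - 1) + (0 - p[i - 1]) / (p[i] - p[i - 1])
                break
        for i in range(i0, len(p) - 1):
            if p[i] >= 0 > p[i + 1]:
                right = i + (p[i] - 0) / (p[i] - p[i + 1])
                break
        if left is None or right is None:
            return float("nan")
        return float((right - left) * pitch)

    lat = fwhm_1d(record[iz, iy, :], grid.dx)
    ax = fwhm_1d(record[:, iy, ix], grid.dz)
    err = float(np.sqrt((x - target[0]) ** 2 + (y - target[1]) ** 2 + (z - target[2]) ** 2))
    return peak, (float(x), float(y), float(z)), lat, ax, err


def _ideal_peak(
    grid: Grid3D,
    na: float,
    wavelength: float,
    n_ambient: float,
    power: float,
    depth: float,
) -> float:
    """Diffraction-limited focal peak of an NA-capped source of given power."""
    pupil = PupilSpec(na=na, wavelength=wavelength, n0=n_ambient)
    f = make_field(
        SourceSpec(kind="point_source", pupil=pupil, focus_position=(0.0, 0.0, depth)),
        grid,
    )
    f.values *= np.sqrt(power)
    vac = RefractiveVolume(
        grid=grid, n=np.full(grid.shape, n_ambient, dtype=np.complex128), n_ambient=n_ambient
    )
    res = propagate(f, vac, PropagatorConfig(store="intensity"))
    return float(res.record.max())


def conjugate_and_focus(
    exit_wavefront: ComplexField,
    volume: RefractiveVolume,
    source_pos: tuple[float, float, float],
    na: float,
    mode: str = "phase_and_amplitude",
    config: PropagatorConfig | None = None,
) -> tuple[FocusReport, np.ndarray]:
    """Send the conjugated surface wavefront back into the tissue.

    ``phase_and_amplitude`` conjugates the full complex field;
    ``phase_only`` keeps the conjugate phase at uniform amplitude (what
    a phase-only spatial light modulator can do), renormalized to the
    same total power.  Returns the focus report at the guide-star
    position and the recorded intensity volume.
    """
    if mode not in ("phase_and_amplitude", "phase_only"):
        raise ValueError(f"invalid conjugation mode {mode!r}")
    if config is None:
        config = PropagatorConfig(store="intensity")
    elif config.store != "intensity":
        raise ValueError("conjugate_and_focus needs config.store='intensity'")
    grid = volume.grid
    power = exit_wavefront.power()
    u = np.conj(exit_wavefront.values)
    if mode == "phase_only":
        amp = np.sqrt(power / (grid.nx * grid.ny * grid.dx * grid.dy))
        u = amp * np.exp(1j * np.angle(u))
    field = ComplexField(
        values=u,
        dx=exit_wavefront.dx,
        dy=exit_wavefront.dy,
        wavelength=exit_wavefront.wavelength,
        z_position=0.0,
    )
    res = propagate(field, volume, config)
    record = res.record
    peak, pos, lat, ax, err = _focus_metrics(record, grid, source_pos)
    ideal = _ideal_peak(
        grid, na, exit_wavefront.wavelength, volume.n_ambient, power, source_pos[2]
    )
    report = FocusReport(
        peak_intensity=peak,
        strehl=min(peak / ideal, 1.05),
        fwhm_lateral=lat,
        fwhm_axial=ax,
        position_error=err,
        peak_position=pos,
    )
    return report, record


def _lateral_shift(field: ComplexField, dx_shift: float) -> ComplexField:
    """Shift u(x, y) -> u(x - dx_shift, y) via Fourier translation."""
    kx = 2.0 * np.pi * sp_fft.fftfreq(field.shape[1], d=field.dx)[None, :]
    out = field.copy()
    out.values = sp_fft.ifft2(sp_fft.fft2(field.values) * np.exp(-1j * kx * dx_shift))
    return out


def memory_effect_curve(
    volume: RefractiveVolume,
    source_pos: tuple[float, float, float],
    shifts: Sequence[float],
    na: float,
    wavelength: float,
    ell_s: float | None = None,
    config: PropagatorConfig | None = None,
) -> MemoryEffectCurve:
    """Shift-shift memory effect: focus survival vs lateral shift.

    The conjugated guide-star wavefront is translated laterally by each
    shift, propagated back to the guide-star plane, and the focal
    intensity at the translated target position recorded;
    C(dx) = I(dx)/I(0).  The reference curve is the normalized spatial
    autocorrelation (along x) of the speckle intensity a plane wave
    produces on the same plane.
    """
    if config is None:
        config = PropagatorConfig()
    grid = volume.grid
    j_src = _source_slice_index(grid, source_pos[2])
    exit_wf = guidestar_exit_wavefront(volume, source_pos, na, wavelength, config)
    conj = ComplexField(
        values=np.conj(exit_wf.values),
        dx=exit_wf.dx,
        dy=exit_wf.dy,
        wavelength=wavelength,
        z_position=0.0,
    )
    x_coords = grid.x_coords()
    y_idx = int(np.argmin(np.abs(grid.y_coords() - source_pos[1])))

    shifts = np.asarray(list(shifts), dtype=float)
    intens = np.empty(len(shifts))
    for i, s in enumerate(shifts):
        f = _lateral_shift(conj, s) if s != 0.0 else conj
        res = propagate(f, volume, config, z_start=0, z_stop=j_src)
        plane = np.abs(res.final.values) ** 2
        x_idx = int(np.argmin(np.abs(x_coords - (source_pos[0] + s))))
        win = plane[
            max(y_idx - 1, 0) : y_idx + 2, max(x_idx - 1, 0) : x_idx + 2
        ]
        intens[i] = float(win.max())
    i0 = intens[shifts == 0.0]
    norm = float(i0[0]) if len(i0) else float(intens.max())
    C = intens / norm

    # reference: plane-wave speckle intensity autocorrelation along x
    pw = make_field(
        SourceSpec(
            kind="plane_wave",
            pupil=PupilSpec(na=1e-6, wavelength=wavelength, n0=volume.n_ambient),
        ),
        grid,
    )
    res = propagate(pw, volume, config, z_start=0, z_stop=j_src)
    I = np.abs(res.final.values) ** 2
    dI = I - I.mean()
    # FFT-based autocorrelation over x, averaged over y (periodic lags)
    F = np.fft.fft(dI, axis=1)
    ac = np.fft.ifft(np.abs(F) ** 2, axis=1).real.mean(axis=0)
    ac /= ac[0]
    lag_px = np.abs(shifts) / grid.dx
    lag0 = np.floor(lag_px).astype(int) % grid.nx
    frac = lag_px - np.floor(lag_px)
    reference = (1 - frac) * ac[lag0] + frac * ac[(lag0 + 1) % grid.nx]

    depth_um = j_src * grid.dz
    return MemoryEffectCurve(
        shifts=shifts,
        C=C,
        reference=reference,
        depth_um=depth_um,
        depth_mfp=None if ell_s is None else depth_um / ell_s,
    )


def estimate_mean_free_path(
    volume: RefractiveVolume | Callable[[int], RefractiveVolume],
    wavelength: float,
    n_realizations: int = 1,
    seed: int = 0,
    config: PropagatorConfig | None = None,
) -> tuple[float, dict]:
    """Scattering mean free path from ballistic (coherent) power decay.

    A unit plane wave is propagated through each realization of the
    medium (``volume`` may be a factory ``seed -> RefractiveVolume``);
    the ballistic amplitude per depth is the realization-averaged
    transverse mean field, and l_s is the 1/e length of its power from
    the log-linear fit |<u>(z)|^2 ~ exp(-z/l_s).

    Returns (ell_s, diagnostics); ell_s is inf with ``no_decay`` set for
    homogeneous lossless media.
    """
    if config is None:
        config = PropagatorConfig(store="field")
    elif config.store != "field":
        raise ValueError("mean-free-path estimate needs config.store='field'")
    volumes: list[RefractiveVolume]
    if callable(volume):
        volumes = [volume(seed + i) for i in range(n_realizations)]
    else:
        volumes = [volume]
    mean_amp = None
    for vol in volumes:
        pw = make_field(
            SourceSpec(
                kind="plane_wave",
                pupil=PupilSpec(na=1e-6, wavelength=wavelength, n0=vol.n_ambient),
            ),
            vol.grid,
        )
        res = propagate(pw, vol, config)
        amp = res.record.mean(axis=(1, 2))  # coherent (k_perp = 0) component
        mean_amp = amp if mean_amp is None else mean_amp + amp
    mean_amp /= len(volumes)
    z = volumes[0].grid.z_coords()
    ballistic = np.abs(mean_amp) ** 2 * (
        volumes[0].grid.nx * volumes[0].grid.ny * volumes[0].grid.dx * volumes[0].grid.dy
    )
    logp = np.log(np.maximum(ballistic, 1e-300))
    A = np.column_stack([z, np.ones_like(z)])
    slope, intercept = np.linalg.lstsq(A, logp, rcond=None)[0]
    resid = logp - A @ np.array([slope, intercept])
    ss_tot = np.sum((logp - logp.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
    diagnostics = {
        "slope": float(slope),
        "r_squared": float(r2),
        "ballistic_power": ballistic,
        "z": z,
        "no_decay": bool(slope > -1e-6),
    }
    if slope > -1e-6:
        return float("inf"), diagnostics
    return float(-1.0 / slope), diagnostics
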