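"""Light-sheet image formation: excitation, spatially varying
convolution with the tiled PSF set, and stack simulation.

Lab-frame conventions: the detection axis is the stored z (page) axis;
illumination propagates along lab x, orthogonal to detection.  Emission
is treated fully incoherently — every fluorophore voxel radiates an
intensity proportional to (excitation x density) and is blurred by the
volumetric PSF of its tile (nearest) or the bilinear blend of the four
surrounding tiles.  Detection-path attenuation is carried by the raw
(un-normalized) PSF integrals, so no separate absorption bookkeeping is
needed on the camera side.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Any, Literal, Sequence

import numpy as np
from scipy import fft as sp_fft

from .bpm import PropagatorConfig, propagate
from .fields import PupilSpec, SourceSpec, make_field
from .grid import (
    ComplexField,
    FluorophoreVolume,
    Grid3D,
    RefractiveVolume,
    reorient_for_illumination,
)
from .phantoms import Phantom
from .psf import PSFSet, TileLayout, compute_psf_set

logger = logging.getLogger("sheetwave")

__all__ = [
    "CameraImage",
    "ImageStack",
    "NoiseModel",
    "excitation_volume",
    "render_camera_image",
    "simulate_stack",
]


@dataclass
class CameraImage:
    """A single simulated camera frame."""

    values: np.ndarray  # (ny, nx) non-negative
    dx: float
    dy: float
    plane_z: float
    provenance: dict[str, Any] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("camera image contains non-finite values")


@dataclass
class ImageStack:
    """Ordered camera frames over scanned focal planes."""

    frames: list[CameraImage]
    scan_step: float

    def as_array(self) -> np.ndarray:
        return np.stack([f.values for f in self.frames])


@dataclass(frozen=True)
class NoiseModel:
    """Optional camera noise: Poisson shot noise at a stated photon
    scale plus additive Gaussian read noise."""

    photons_per_unit: float = 100.0
    gaussian_sigma: float = 0.0
    poisson: bool = True

    def apply(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = image
        if self.poisson:
            out = rng.poisson(np.maximum(out, 0.0) * self.photons_per_unit) / self.photons_per_unit
        if self.gaussian_sigma > 0:
            out = out + rng.normal(scale=self.gaussian_sigma, size=out.shape)
        return out


def _lab_focus_to_illum_frame(
    focus_lab: tuple[float, float, float], grid: Grid3D, sheet_z: float
) -> tuple[float, float, float]:
    """Map a lab-frame (x, y, z) focus to the illumination propagation
    frame (cols = lab z, rows = lab y, propagation = lab x)."""
    Lx, Ly, Lz = grid.extent
    x_lab, y_lab, _z_lab = focus_lab
    return (sheet_z - Lz / 2.0, y_lab, x_lab + Lx / 2.0)


def excitation_volume(
    volume: RefractiveVolume,
    illum: SourceSpec | Sequence[SourceSpec],
    sheet_z: float,
    config: PropagatorConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Excitation intensity in the lab frame for a sheet at ``sheet_z``.

    A single SourceSpec is propagated coherently (|u|^2 of the field); a
    sequence is treated as an incoherent set whose member intensities
    are averaged (e.g. a scanned-beam sheet).  The illumination
    propagates along lab x; ``illum.focus_position`` is read in lab
    coordinates with its z replaced by ``sheet_z``.

    Returns (excitation[(z, y, x)], per_plane_power[n_illum_planes]).
    """
    if config is None:
        config = PropagatorConfig(store="intensity")
    elif config.store != "intensity":
        raise ValueError("excitation_volume requires config.store='intensity'")
    specs = [illum] if isinstance(illum, SourceSpec) else list(illum)
    if not specs:
        raise ValueError("no illumination source given")

    vol_arr, ill_grid = reorient_for_illumination(volume.n, volume.grid)
    ill_volume = RefractiveVolume(grid=ill_grid, n=vol_arr, n_ambient=volume.n_ambient)

    acc: np.ndarray | None = None
    power = None
    for spec in specs:
        focus = _lab_focus_to_illum_frame(spec.focus_position, volume.grid, sheet_z)
        spec_p = SourceSpec(
            kind=spec.kind,
            pupil=spec.pupil,
            focus_position=focus,
            normalization=spec.normalization,
            gaussian_waist=spec.gaussian_waist,
        )
        field = make_field(spec_p, ill_grid)
        result = propagate(field, ill_volume, config)
        rec = result.record  # (nx, ny, nz_lab) intensity
        acc = rec if acc is None else acc + rec
        power = result.plane_power if power is None else power + result.plane_power
    acc /= len(specs)
    power = power / len(specs)
    # back to lab frame (z, y, x)
    exc = np.ascontiguousarray(np.transpose(acc, (2, 1, 0)))
    return exc, power


def _blend_weights_1d(
    centers: np.ndarray, n: int, blend: str
) -> np.ndarray:
    """Per-tile 1D blending weights over pixel indices 0..n-1.

    Bilinear: hat functions between adjacent tile centers, clamped to
    the nearest tile outside the center range; nearest: indicators.
    Rows sum to 1 for every pixel.
    """
    px = np.arange(n) + 0.0
    ntiles = len(centers)
    w = np.zeros((ntiles, n))
    if ntiles == 1:
        w[0] = 1.0
        return w
    if blend == "nearest":
        idx = np.argmin(np.abs(px[None, :] - centers[:, None]), axis=0)
        for t in range(ntiles):
            w[t] = idx == t
        return w
    if blend != "bilinear":
        raise ValueError(f"unknown blend {blend!r}")
    for t in range(ntiles):
        c = centers[t]
        left = centers[t - 1] if t > 0 else None
        right = centers[t + 1] if t < ntiles - 1 else None
        wt = np.zeros(n)
        if left is None:
            wt[px <= c] = 1.0
        else:
            sel = (px > left) & (px <= c)
            wt[sel] = (px[sel] - left) / (c - left)
        if right is None:
            wt[px > c] = 1.0
        else:
            sel = (px > c) & (px < right)
            wt[sel] = (right - px[sel]) / (right - c)
        w[t] = wt
    return w


def render_camera_image(
    excitation: np.ndarray,
    fluor: FluorophoreVolume,
    psf_set: PSFSet,
    blend: Literal["nearest", "bilinear"] = "bilinear",
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
) -> CameraImage:
    """Spatially varying convolution of the emitted light with the PSF set.

    image(x, y) = sum over emitter voxels of
    emitted * PSF_tile(x - x', y - y', z' - plane_z), with the emitting
    voxel's PSF the nearest tile's stack or the bilinear blend of the
    four surrounding tiles.  Raw (transmission-scaled) PSFs are used, so
    detection-path attenuation shows in the image.
    """
    grid = psf_set.grid
    if excitation.shape != grid.shape or fluor.density.shape != grid.shape:
        raise ValueError("excitation/fluorophore shape does not match the PSF grid")
    emitted = excitation * fluor.density
    layout = psf_set.layout
    ts = layout.tile_size
    dz = grid.dz

    # map emitted planes to PSF refocus planes
    z_emit = grid.z_coords() - psf_set.plane_z
    zmax = psf_set.z_offsets.max() + dz / 2.0
    zmin = psf_set.z_offsets.min() - dz / 2.0
    usable = (z_emit >= zmin) & (z_emit <= zmax)
    lost = emitted[~usable].sum()
    total = emitted.sum()
    if lost > 0 and total > 0:
        warnings.warn(
            f"PSF axial support smaller than the emitting volume: "
            f"{lost / total:.1%} of emitted energy outside the refocus band is dropped",
            stacklevel=2,
        )
    plane_idx = np.round((z_emit - psf_set.z_offsets[0]) / dz).astype(int)

    cx, cy = layout.center_pixels(grid)
    wx = _blend_weights_1d(cx, grid.nx, blend)
    wy = _blend_weights_1d(cy, grid.ny, blend)

    pad_y = sp_fft.next_fast_len(grid.ny + ts)
    pad_x = sp_fft.next_fast_len(grid.nx + ts)
    image_f = np.zeros((pad_y, pad_x), dtype=np.complex128)
    cyc = ts // 2
    for iy in range(layout.tile_ny):
        for ix in range(layout.tile_nx):
            weight = wy[iy][:, None] * wx[ix][None, :]
            if not weight.any():
                continue
            psf_raw = psf_set.raw(iy, ix)
            tile_fft_cache: dict[int, np.ndarray] = {}
            for z in np.nonzero(usable)[0]:
                sl = emitted[z] * weight
                if not sl.any():
                    continue
                pi = int(np.clip(plane_idx[z], 0, len(psf_set.z_offsets) - 1))
                if pi not in tile_fft_cache:
                    kern = np.zeros((pad_y, pad_x))
                    kern[:ts, :ts] = psf_raw[pi]
                    kern = np.roll(kern, (-cyc, -cyc), axis=(0, 1))
                    tile_fft_cache[pi] = sp_fft.fft2(kern)
                src = np.zeros((pad_y, pad_x))
                src[: grid.ny, : grid.nx] = sl
                image_f += sp_fft.fft2(src) * tile_fft_cache[pi]
    image = sp_fft.ifft2(image_f).real[: grid.ny, : grid.nx]
    image = np.maximum(image, 0.0)
    if noise is not None:
        if rng is None:
            rng = np.random.default_rng(0)
        image = np.maximum(noise.apply(image, rng), 0.0)
    return CameraImage(
        values=image,
        dx=grid.dx,
        dy=grid.dy,
        plane_z=psf_set.plane_z,
        provenance={"blend": blend, "tiles": (layout.tile_ny, layout.tile_nx)},
    )


def simulate_stack(
    phantom: Phantom,
    illum: SourceSpec | Sequence[SourceSpec],
    detect_pupil: PupilSpec,
    layout: TileLayout,
    z_positions: Sequence[float],
    blend: Literal["nearest", "bilinear"] = "bilinear",
    config: PropagatorConfig | None = None,
    psf_nz: int | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> ImageStack:
    """Scan the light sheet and focal plane together through the sample.

    For each z: propagate the illumination, compute the tiled PSF set of
    that focal plane, and render the camera frame.  Deterministic for a
    fixed seed (the seed only feeds the optional noise model).
    """
    z_positions = list(z_positions)
    if len(z_positions) > 1:
        steps = np.diff(z_positions)
        if not np.allclose(steps, steps[0]):
            raise ValueError("z positions must be uniformly spaced")
        scan_step = float(steps[0])
    else:
        scan_step = phantom.refractive.grid.dz
    rng = np.random.default_rng(seed)
    frames = []
    bpm_cfg = config or PropagatorConfig()
    for z in z_positions:
        t0 = time.perf_counter()
        exc, _power = excitation_volume(
            phantom.refractive,
            illum,
            sheet_z=z,
            config=PropagatorConfig(
                n_ref_mode=bpm_cfg.n_ref_mode,
                evanescent_policy=bpm_cfg.evanescent_policy,
                boundary=bpm_cfg.boundary,
                absorb_width=bpm_cfg.absorb_width,
                absorb_strength=bpm_cfg.absorb_strength,
                store="intensity",
            ),
        )
        psf_set = compute_psf_set(
            phantom.refractive, z, layout, detect_pupil, config=bpm_cfg, psf_nz=psf_nz
        )
        frame = render_camera_image(
            exc, phantom.fluor, psf_set, blend=blend, noise=noise, rng=rng
        )
        frame.provenance["sheet_z"] = z
        frames.append(frame)
        logger.info(
            "plane z=%.2f um rendered in %.2f s (grid %s, %dx%d tiles)",
            z,
            time.perf_counter() - t0,
            phantom.refractive.grid.shape,
            layout.tile_ny,
            layout.tile_nx,
        )
    return ImageStack(frames=frames, scan_step=scan_step)
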