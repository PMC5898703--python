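import numpy as np
import pytest

from sheetwave.grid import Grid3D, RefractiveVolume


@pytest.fixture(autouse=True)
def _quiet_sampling_warnings():
    """Grids chosen for speed routinely trip the (intentional) sampling
    advisories; keep test output readable."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*pitch.*")
        warnings.filterwarnings("ignore", message=".*axial step.*")
        yield


def vacuum_volume(grid: Grid3D, n0: float = 1.33) -> RefractiveVolume:
    return RefractiveVolume(
        grid=grid, n=np.full(grid.shape, n0, dtype=np.complex128), n_ambient=n0
    )


def fwhm_1d(profile: np.ndarray, pitch: float) -> float:
    """Interpolated full width at half maximum of a 1D profile."""
    p = np.asarray(profile, dtype=float)
    half = p.max() / 2.0
    i0 = int(np.argmax(p))
    left = right = None
    for i in range(i0, 0, -1):
        if p[i - 1] < half <= p[i]:
            left = (i - 1) + (half - p[i - 1]) / (p[i] - p[i - 1])
            break
    for i in range(i0, len(p) - 1):
        if p[i] >= half > p[i + 1]:
            right = i + (p[i] - half) / (p[i] - p[i + 1])
            break
    assert left is not None and right is not None, "no half-max crossing found"
    return (right - left) * pitch


def brute_force_render(emitted, psf_set, blend="nearest"):
    """Direct triple-loop spatially varying superposition; shares no
    summation code with imaging.render_camera_image."""
    grid = psf_set.grid
    layout = psf_set.layout
    ts = layout.tile_size
    c = ts // 2
    cx, cy = layout.center_pixels(grid)
    z_emit = grid.z_coords() - psf_set.plane_z
    if blend != "nearest":
        raise NotImplementedError
    # padded accumulator so per-emitter kernel placement is a plain slice add
    out = np.zeros((grid.ny + 2 * ts, grid.nx + 2 * ts))
    nzp = len(psf_set.z_offsets)
    for z in range(grid.nz):
        pi = int(round((z_emit[z] - psf_set.z_offsets[0]) / grid.dz))
        if pi < 0 or pi >= nzp:
            continue
        for yy in range(grid.ny):
            for xx in range(grid.nx):
                w = emitted[z, yy, xx]
                if w == 0.0:
                    continue
                iy = int(np.argmin(np.abs(cy - yy)))
                ix = int(np.argmin(np.abs(cx - xx)))
                kern = psf_set.raw(iy, ix)[pi]
                oy = ts + yy - c
                ox = ts + xx - c
                out[oy : oy + ts, ox : ox + ts] += w * kern
    return out[ts : ts + grid.ny, ts : ts + grid.nx]
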