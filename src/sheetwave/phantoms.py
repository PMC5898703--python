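"""Synthetic refractive-index / fluorophore phantoms with ground truth.

Every generator is deterministic under its seed and keeps a ``truth``
record of the geometry it rendered, so simulated images can be compared
against a known object.  Index values are kept inside the biologically
plausible band (ambient water 1.33 up to ~1.43 for eggshell/yolk-like
structures).

The pseudorandom tissue texture is classic lattice gradient ("Perlin")
noise with optional octaves, written here because no gradient-noise
dependency is available; the base lattice spacing controls the
autocorrelation length of the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Any, Literal, Sequence

import numpy as np

from .grid import FluorophoreVolume, Grid3D, RefractiveVolume

__all__ = [
    "Phantom",
    "SphereSpec",
    "make_spheres",
    "make_perlin_tissue",
    "make_embryo",
    "make_test_chart",
    "gradient_noise_3d",
]

# One-time calibration of the lattice-spacing -> autocorrelation-FWHM map
# of the single-octave gradient noise (measured on 96^3 realizations).
PERLIN_FWHM_PER_CELL = 0.85


@dataclass
class Phantom:
    """Paired refractive and fluorophore volumes plus ground truth."""

    refractive: RefractiveVolume
    fluor: FluorophoreVolume
    truth: dict[str, Any] = dc_field(default_factory=dict)


@dataclass(frozen=True)
class SphereSpec:
    """A (possibly coated) sphere: center in micrometers, radii, indices.

    For a coated sphere give ``n_shell`` and ``r_core < radius``; the
    shell occupies r_core < r <= radius.
    """

    center: tuple[float, float, float]  # (x, y, z) um
    radius: float
    n: float
    n_shell: float | None = None
    r_core: float | None = None
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if (self.n_shell is None) != (self.r_core is None):
            raise ValueError("coated sphere needs both n_shell and r_core")
        if self.r_core is not None and not 0 < self.r_core < self.radius:
            raise ValueError("need 0 < r_core < radius")


def _coords(grid: Grid3D) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    z = grid.z_coords()[:, None, None]
    y = grid.y_coords()[None, :, None]
    x = grid.x_coords()[None, None, :]
    return z, y, x


def _sphere_occupancy(
    grid: Grid3D, center: tuple[float, float, float], radius: float, antialias: bool
) -> tuple[np.ndarray, tuple[slice, slice, slice]]:
    """Occupancy fraction of a sphere within each voxel of its bounding box."""
    cx, cy, cz = center
    pad = radius + max(grid.dx, grid.dy, grid.dz)
    z_all = grid.z_coords()
    y_all = grid.y_coords()
    x_all = grid.x_coords()
    zi = np.where(np.abs(z_all - cz) <= pad)[0]
    yi = np.where(np.abs(y_all - cy) <= pad)[0]
    xi = np.where(np.abs(x_all - cx) <= pad)[0]
    if len(zi) == 0 or len(yi) == 0 or len(xi) == 0:
        raise ValueError(f"sphere at {center} lies outside the grid")
    box = (
        slice(zi[0], zi[-1] + 1),
        slice(yi[0], yi[-1] + 1),
        slice(xi[0], xi[-1] + 1),
    )
    z = z_all[box[0]][:, None, None] - cz
    y = y_all[box[1]][None, :, None] - cy
    x = x_all[box[2]][None, None, :] - cx
    if not antialias:
        occ = (z**2 + y**2 + x**2 <= radius**2).astype(np.float64)
        return occ, box
    # 3^3 subvoxel supersampling of the boundary shell
    occ = np.zeros(z.shape[:1] + y.shape[1:2] + x.shape[2:], dtype=np.float64)
    offsets = (np.arange(3) - 1.0) / 3.0
    for oz in offsets:
        for oy in offsets:
            for ox in offsets:
                occ += (
                    (z + oz * grid.dz) ** 2
                    + (y + oy * grid.dy) ** 2
                    + (x + ox * grid.dx) ** 2
                    <= radius**2
                )
    occ /= 27.0
    return occ, box


def make_spheres(
    grid: Grid3D,
    spheres: Sequence[SphereSpec],
    n_ambient: float = 1.33,
    antialias: bool = True,
    label_spheres: bool = True,
) -> Phantom:
    """Voxelize solid or coated spheres into a phantom.

    Overlapping spheres are allowed (last wins in the overlap region)
    but flagged in the truth record.
    """
    n = np.full(grid.shape, n_ambient, dtype=np.complex128)
    fluor = np.zeros(grid.shape)
    overlap = False
    for i, a in enumerate(spheres):
        for b in spheres[i + 1 :]:
            d = np.linalg.norm(np.subtract(a.center, b.center))
            if d < a.radius + b.radius:
                overlap = True
    for s in spheres:
        occ, box = _sphere_occupancy(grid, s.center, s.radius, antialias)
        outer_n = s.n_shell if s.n_shell is not None else s.n
        n[box] = n[box] + occ * (outer_n - n[box].real) + 1j * occ * s.kappa
        if s.r_core is not None:
            occ_c, box_c = _sphere_occupancy(grid, s.center, s.r_core, antialias)
            n[box_c] = n[box_c] + occ_c * (s.n - n[box_c].real)
        if label_spheres:
            fluor[box] = np.maximum(fluor[box], occ)
    truth = {
        "kind": "spheres",
        "spheres": [
            {
                "center": s.center,
                "radius": s.radius,
                "n": s.n,
                "n_shell": s.n_shell,
                "r_core": s.r_core,
            }
            for s in spheres
        ],
        "overlapping": overlap,
    }
    return Phantom(
        refractive=RefractiveVolume(grid=grid, n=n, n_ambient=n_ambient),
        fluor=FluorophoreVolume(grid=grid, density=fluor),
        truth=truth,
    )


def _perlin_octave(
    shape: tuple[int, int, int],
    cell_vox: tuple[float, float, float],
    rng: np.random.Generator,
    chunk: int = 32,
) -> np.ndarray:
    """Single-octave 3D lattice gradient noise on a voxel grid."""
    n_grad = 1024
    grads = rng.normal(size=(n_grad, 3))
    grads /= np.linalg.norm(grads, axis=1, keepdims=True)
    perm = rng.permutation(n_grad)

    def hash_idx(iz: np.ndarray, iy: np.ndarray, ix: np.ndarray) -> np.ndarray:
        return perm[(perm[(perm[iz % n_grad] + iy) % n_grad] + ix) % n_grad]

    def fade(t: np.ndarray) -> np.ndarray:
        return t * t * t * (t * (6.0 * t - 15.0) + 10.0)

    nz, ny, nx = shape
    out = np.empty(shape, dtype=np.float32)
    for z0 in range(0, nz, chunk):
        z1 = min(z0 + chunk, nz)
        fz = np.arange(z0, z1)[:, None, None] / cell_vox[0]
        fy = (np.arange(ny)[None, :, None]) / cell_vox[1]
        fx = (np.arange(nx)[None, None, :]) / cell_vox[2]
        iz0 = np.floor(fz).astype(np.int64)
        iy0 = np.floor(fy).astype(np.int64)
        ix0 = np.floor(fx).astype(np.int64)
        tz = (fz - iz0).astype(np.float32)
        ty = (fy - iy0).astype(np.float32)
        tx = (fx - ix0).astype(np.float32)
        wz, wy, wx = fade(tz), fade(ty), fade(tx)
        acc = np.zeros((z1 - z0, ny, nx), dtype=np.float32)
        for cz in (0, 1):
            for cy in (0, 1):
                for cx in (0, 1):
                    g = grads[hash_idx(iz0 + cz, iy0 + cy, ix0 + cx)]
                    dot = (
                        g[..., 0] * (tz - cz)
                        + g[..., 1] * (ty - cy)
                        + g[..., 2] * (tx - cx)
                    )
                    w = (
                        (wz if cz else 1.0 - wz)
                        * (wy if cy else 1.0 - wy)
                        * (wx if cx else 1.0 - wx)
                    )
                    acc += w * dot
        out[z0:z1] = acc
    return out


def gradient_noise_3d(
    grid: Grid3D,
    correlation_length: float,
    seed: int,
    octaves: int = 1,
    persistence: float = 0.5,
) -> np.ndarray:
    """Zero-mean, unit-std smooth random field on the grid.

    ``correlation_length`` (um) sets the autocorrelation FWHM of the
    base octave; further octaves add finer detail at half the scale and
    ``persistence`` times the amplitude each.
    """
    if correlation_length <= 0:
        raise ValueError("correlation_length must be positive")
    cell_um = correlation_length / PERLIN_FWHM_PER_CELL
    rng = np.random.default_rng(seed)
    total = np.zeros(grid.shape, dtype=np.float32)
    amp = 1.0
    for o in range(octaves):
        cell_vox = (
            cell_um / (2**o) / grid.dz,
            cell_um / (2**o) / grid.dy,
            cell_um / (2**o) / grid.dx,
        )
        total += amp * _perlin_octave(grid.shape, cell_vox, rng)
        amp *= persistence
    total = total.astype(np.float64)
    total -= total.mean()
    std = total.std()
    if std == 0:
        return total
    return total / std


def make_perlin_tissue(
    grid: Grid3D,
    mean_n: float = 1.36,
    amplitude: float = 0.03,
    correlation_length: float = 1.0,
    seed: int = 0,
    octaves: int = 1,
    n_ambient: float = 1.33,
    kappa: float = 0.0,
    fluor_mode: Literal["uniform", "none"] = "uniform",
) -> Phantom:
    """Continuous scattering tissue: smooth pseudorandom index field
    n = mean_n + amplitude * g with g zero-mean, unit-std gradient noise.

    Defaults reproduce the n = 1.36 +/- 0.03 tissue used for the
    adaptive-optics experiments.
    """
    if amplitude == 0.0:
        n = np.full(grid.shape, mean_n, dtype=np.complex128)
    else:
        g = gradient_noise_3d(grid, correlation_length, seed, octaves=octaves)
        n = (mean_n + amplitude * g).astype(np.complex128)
        n = np.clip(n.real, 1.0, 2.0).astype(np.complex128)
    if kappa > 0:
        n = n + 1j * kappa
    fluor = np.ones(grid.shape) if fluor_mode == "uniform" else np.zeros(grid.shape)
    truth = {
        "kind": "perlin",
        "mean_n": mean_n,
        "amplitude": amplitude,
        "correlation_length": correlation_length,
        "octaves": octaves,
        "seed": seed,
    }
    return Phantom(
        refractive=RefractiveVolume(grid=grid, n=n, n_ambient=n_ambient),
        fluor=FluorophoreVolume(grid=grid, density=fluor),
        truth=truth,
    )


def _poisson_disk_in_ellipsoid(
    rng: np.random.Generator,
    n_points: int,
    semi_axes: tuple[float, float, float],
    min_gap: float,
    margin: float,
    max_tries: int = 200000,
) -> list[tuple[float, float, float]]:
    """Dart-throwing placement of points inside an ellipsoid (origin-centered)."""
    ax, ay, az = (a - margin for a in semi_axes)
    pts: list[tuple[float, float, float]] = []
    tries = 0
    while len(pts) < n_points and tries < max_tries:
        tries += 1
        p = rng.uniform(-1, 1, size=3)
        if (p**2).sum() > 1.0:
            continue
        cand = (p[0] * ax, p[1] * ay, p[2] * az)
        ok = all(
            (cand[0] - q[0]) ** 2 + (cand[1] - q[1]) ** 2 + (cand[2] - q[2]) ** 2
            >= min_gap**2
            for q in pts
        )
        if ok:
            pts.append(cand)
    if len(pts) < n_points:
        raise ValueError(
            f"could only place {len(pts)}/{n_points} nuclei with gap {min_gap}"
        )
    return pts


def make_embryo(
    grid: Grid3D,
    seed: int = 0,
    n_nuclei: int = 50,
    nucleus_radius: float | None = None,
    min_gap: float | None = None,
    n_ambient: float = 1.33,
    n_cytoplasm: float = 1.365,
    n_nucleus: float = 1.39,
    n_shell: float = 1.43,
    shell_thickness: float | None = None,
    granularity_amplitude: float = 0.02,
    granularity_length: float | None = None,
    label: Literal["nuclei", "membranes", "none"] = "nuclei",
    kappa: float = 0.0,
) -> Phantom:
    """Parametric multicellular embryo model.

    An ellipsoidal eggshell encloses cytoplasm with band-limited
    granular index fluctuations and non-overlapping labeled nuclei.
    All indices are clamped to [n_ambient, 1.43].  Deterministic under
    the seed; scaled-down defaults (50 nuclei) suit 64^3..128^3 grids.
    """
    Lx, Ly, Lz = grid.extent
    semi = (0.42 * Lx, 0.42 * Ly, 0.42 * Lz)
    if nucleus_radius is None:
        nucleus_radius = 0.07 * min(Lx, Ly, Lz)
    if min_gap is None:
        min_gap = 2.6 * nucleus_radius
    if shell_thickness is None:
        shell_thickness = 2.0 * max(grid.dx, grid.dy, grid.dz)
    if granularity_length is None:
        granularity_length = max(4.0 * grid.dx, 0.04 * min(Lx, Ly, Lz))

    rng = np.random.default_rng(seed)
    z, y, x = _coords(grid)
    zc = z - Lz / 2.0
    # ellipsoid "radius" in normalized coords; 1 on the shell mid-surface
    rho = np.sqrt((x / semi[0]) ** 2 + (y / semi[1]) ** 2 + (zc / semi[2]) ** 2)
    t = shell_thickness / (2.0 * min(semi))  # half-thickness in rho units (approx.)
    inside = rho < 1.0 - t
    shell = (rho >= 1.0 - t) & (rho <= 1.0 + t)

    n = np.full(grid.shape, n_ambient)
    n[inside] = n_cytoplasm
    if granularity_amplitude > 0:
        g = gradient_noise_3d(grid, granularity_length, seed + 1, octaves=2)
        n[inside] += granularity_amplitude * g[inside]
    n[shell] = n_shell

    centers = _poisson_disk_in_ellipsoid(
        rng, n_nuclei, semi, min_gap, margin=nucleus_radius + shell_thickness
    )
    fluor = np.zeros(grid.shape)
    for (cx, cy, cz) in centers:
        occ, box = _sphere_occupancy(
            grid, (cx, cy, cz + Lz / 2.0), nucleus_radius, antialias=True
        )
        n[box] = n[box] * (1 - occ) + occ * n_nucleus
        if label == "nuclei":
            fluor[box] = np.maximum(fluor[box], occ)
    if label == "membranes":
        fluor[shell] = 1.0
    n = np.clip(n, n_ambient, 1.43)
    nc = n.astype(np.complex128)
    if kappa > 0:
        nc = nc + 1j * kappa
    truth = {
        "kind": "embryo",
        "seed": seed,
        "nuclei": [
            {"center": (c[0], c[1], c[2] + Lz / 2.0), "radius": nucleus_radius}
            for c in centers
        ],
        "semi_axes": semi,
        "n_cytoplasm": n_cytoplasm,
        "n_nucleus": n_nucleus,
        "n_shell": n_shell,
    }
    return Phantom(
        refractive=RefractiveVolume(grid=grid, n=nc, n_ambient=n_ambient),
        fluor=FluorophoreVolume(grid=grid, density=fluor),
        truth=truth,
    )


def make_test_chart(
    grid: Grid3D,
    bar_periods: Sequence[int] = (4, 8, 16),
    bars_per_group: int = 3,
    z_plane: int | None = None,
    thickness: int = 1,
    amplitude: float = 1.0,
) -> FluorophoreVolume:
    """USAF-style resolution bar chart embedded at one z plane.

    Each group renders ``bars_per_group`` bars of the given period (in
    pixels, bar width = period/2) running along y, groups stacked along
    y with gaps, all centered in x.
    """
    if z_plane is None:
        z_plane = grid.nz // 2
    density = np.zeros(grid.shape)
    plane = np.zeros(grid.transverse_shape)
    gap = 4
    y0 = gap
    for period in bar_periods:
        bar_w = max(period // 2, 1)
        group_w = bars_per_group * period
        x0 = (grid.nx - group_w) // 2
        height = min(4 * period, grid.ny // (len(bar_periods) + 1) - gap)
        height = max(height, bar_w)
        for b in range(bars_per_group):
            xs = x0 + b * period
            plane[y0 : y0 + height, xs : xs + bar_w] = amplitude
        y0 += height + gap
        if y0 >= grid.ny:
            break
    for dzp in range(thickness):
        if 0 <= z_plane + dzp < grid.nz:
            density[z_plane + dzp] = plane
    return FluorophoreVolume(grid=grid, density=density)
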