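"""Independent analytic and brute-force references for validation.

Nothing here shares propagation code with the modules it checks: the
diffraction oracle is a direct Rayleigh-Sommerfeld sum in real space,
the sphere oracle is the scalar partial-wave (Mie-type) series, the
knife edge is the closed-form Fresnel integral, and the Gaussian-beam /
focus widths are textbook formulas.  These functions are deliberately
slow and simple; they exist to be trusted, not to be fast.

The engine is scalar, so the sphere oracle solves scalar Helmholtz
scattering by a penetrable (possibly coated) sphere — continuity of u
and du/dr at each interface — rather than the vector Mie problem.  In
the low-contrast regime the package targets (|m - 1| << 1) the two
agree closely; a warning is raised outside it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special

from .bpm import PropagatorConfig, propagate
from .fields import PupilSpec, SourceSpec, make_field
from .grid import ComplexField, Grid3D, RefractiveVolume

__all__ = [
    "MieSpec",
    "mie_near_field",
    "mie_phase_function",
    "mie_q_sca",
    "fresnel_knife_edge",
    "gaussian_beam_width",
    "gaussian_beam_fwhm",
    "airy_fwhm_lateral",
    "focus_fwhm_axial",
    "direct_diffraction",
    "sequential_psf",
]


@dataclass(frozen=True)
class MieSpec:
    """Sphere scattering parameters (scalar model).

    For a coated sphere supply n_core/r_core; the outer ``radius`` and
    ``n_sphere`` then describe the shell.
    """

    radius: float  # um (outer)
    n_sphere: float
    wavelength: float  # vacuum, um
    n_ambient: float = 1.33
    n_core: float | None = None
    r_core: float | None = None

    def __post_init__(self) -> None:
        m = self.n_sphere / self.n_ambient
        if abs(m - 1.0) > 0.2:
            warnings.warn(
                f"relative index m={m:.3f} far from 1; the scalar BPM comparison "
                "is outside its validity regime",
                stacklevel=3,
            )
        if (self.n_core is None) != (self.r_core is None):
            raise ValueError("coated sphere needs both n_core and r_core")

    @property
    def size_parameter(self) -> float:
        return 2.0 * np.pi * self.n_ambient * self.radius / self.wavelength

    @property
    def l_max(self) -> int:
        x = self.size_parameter
        return int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))


def _spherical_h1(l: int, z: np.ndarray, derivative: bool = False):
    jl = special.spherical_jn(l, z, derivative=derivative)
    yl = special.spherical_yn(l, z, derivative=derivative)
    return jl + 1j * yl


def _scattering_coefficients(spec: MieSpec, l_max: int | None = None) -> np.ndarray:
    """Exterior partial-wave coefficients b_l of the scattered field.

    Scalar boundary conditions: u and du/dr continuous at every
    interface.  Coated spheres use the shell solution
    beta*(j_l + g*y_l) with g fixed by the core matching, written in
    cross-multiplied form so core Bessel zeros cause no division issues.
    """
    if l_max is None:
        l_max = spec.l_max
    k0 = 2.0 * np.pi / spec.wavelength
    k = spec.n_ambient * k0
    ks = spec.n_sphere * k0  # shell (or solid-sphere) interior
    a = spec.radius
    x = k * a
    xs = ks * a
    b = np.empty(l_max + 1, dtype=np.complex128)
    for l in range(l_max + 1):
        jx = special.spherical_jn(l, x)
        jx_p = special.spherical_jn(l, x, derivative=True)
        hx = _spherical_h1(l, np.array(x))
        hx_p = _spherical_h1(l, np.array(x), derivative=True)
        if spec.n_core is None:
            js = special.spherical_jn(l, xs)
            js_p = special.spherical_jn(l, xs, derivative=True)
            S, S_p = js, js_p
        else:
            kc = spec.n_core * k0
            a1 = spec.r_core
            jc = special.spherical_jn(l, kc * a1)
            jc_p = special.spherical_jn(l, kc * a1, derivative=True)
            js1 = special.spherical_jn(l, ks * a1)
            js1_p = special.spherical_jn(l, ks * a1, derivative=True)
            ys1 = special.spherical_yn(l, ks * a1)
            ys1_p = special.spherical_yn(l, ks * a1, derivative=True)
            # shell mix  g = gamma/beta from core-interface continuity
            g_num = kc * jc_p * js1 - ks * jc * js1_p
            g_den = ks * jc * ys1_p - kc * jc_p * ys1
            # scale-free: use (beta, gamma) ~ (g_den, g_num)
            js2 = special.spherical_jn(l, xs)
            js2_p = special.spherical_jn(l, xs, derivative=True)
            ys2 = special.spherical_yn(l, xs)
            ys2_p = special.spherical_yn(l, xs, derivative=True)
            S = g_den * js2 + g_num * ys2
            S_p = g_den * js2_p + g_num * ys2_p
        num = ks * S_p * jx - k * jx_p * S
        den = ks * S_p * hx - k * hx_p * S
        b[l] = -num / den
    return b


def _legendre_all(l_max: int, mu: np.ndarray) -> np.ndarray:
    """P_l(mu) for l = 0..l_max via upward recursion; shape (l_max+1, ...)."""
    out = np.empty((l_max + 1,) + mu.shape)
    out[0] = 1.0
    if l_max >= 1:
        out[1] = mu
    for l in range(1, l_max):
        out[l + 1] = ((2 * l + 1) * mu * out[l] - l * out[l - 1]) / (l + 1)
    return out


def mie_near_field(
    spec: MieSpec,
    x: np.ndarray,
    y: np.ndarray,
    z_plane: float,
    l_max: int | None = None,
) -> np.ndarray:
    """Total (incident + scattered) intensity on a plane behind the sphere.

    The sphere is centered at the origin; the incident field is a unit
    plane wave exp(i k z).  ``x``/``y`` are 1D coordinate axes in
    micrometers; the plane must not intersect the sphere.  The series is
    truncated at l_max = x + 4 x^(1/3) + 2 (Wiscombe-style rule) unless
    overridden.
    """
    if abs(z_plane) < spec.radius:
        raise ValueError("evaluation plane intersects the sphere")
    if l_max is None:
        l_max = spec.l_max
    k0 = 2.0 * np.pi / spec.wavelength
    k = spec.n_ambient * k0
    b = _scattering_coefficients(spec, l_max)
    X, Y = np.meshgrid(x, y)
    r = np.sqrt(X**2 + Y**2 + z_plane**2)
    mu = z_plane / r
    P = _legendre_all(l_max, mu)
    u = np.zeros(r.shape, dtype=np.complex128)
    kr = k * r
    for l in range(l_max + 1):
        hl = _spherical_h1(l, kr)
        u += (1j**l) * (2 * l + 1) * b[l] * hl * P[l]
    u += np.exp(1j * k * z_plane)  # incident plane wave on the plane
    return np.abs(u) ** 2


def mie_phase_function(
    spec: MieSpec, theta: np.ndarray, l_max: int | None = None
) -> np.ndarray:
    """Normalized angular scattering intensity p(theta), integral-free
    (peak-normalized far-field |f(theta)|^2)."""
    if l_max is None:
        l_max = spec.l_max
    b = _scattering_coefficients(spec, l_max)
    mu = np.cos(np.asarray(theta, dtype=float))
    P = _legendre_all(l_max, mu)
    f = np.zeros(mu.shape, dtype=np.complex128)
    for l in range(l_max + 1):
        f += (2 * l + 1) * b[l] * P[l]
    p = np.abs(f) ** 2
    return p / p.max()


def mie_q_sca(spec: MieSpec, l_max: int | None = None) -> float:
    """Scattering efficiency Q_sca = (4/x^2) sum (2l+1) |b_l|^2."""
    if l_max is None:
        l_max = spec.l_max
    b = _scattering_coefficients(spec, l_max)
    x = spec.size_parameter
    l = np.arange(l_max + 1)
    return float(4.0 / x**2 * np.sum((2 * l + 1) * np.abs(b) ** 2))


def fresnel_knife_edge(
    x: np.ndarray, z: float, wavelength: float, n0: float = 1.0
) -> np.ndarray:
    """Fresnel-diffraction intensity behind a half-plane edge.

    The opaque screen covers x < 0 at z = 0; a unit plane wave arrives
    along z.  Classic limits: I -> 1 far on the lit side, I -> 0 deep in
    shadow, I = 1/4 exactly on the geometric edge line.
    """
    if z <= 0:
        raise ValueError("depth z must be positive")
    lam = wavelength / n0
    v = np.asarray(x, dtype=float) * np.sqrt(2.0 / (lam * z))
    S, C = special.fresnel(v)
    return 0.5 * ((0.5 + C) ** 2 + (0.5 + S) ** 2)


def gaussian_beam_width(w0: float, wavelength: float, n0: float, z: float) -> float:
    """1/e^2 amplitude radius w(z) = w0 sqrt(1 + (z/zR)^2)."""
    zr = np.pi * w0**2 * n0 / wavelength
    return w0 * np.sqrt(1.0 + (z / zr) ** 2)


def gaussian_beam_fwhm(w0: float, wavelength: float, n0: float, z: float) -> float:
    """Intensity FWHM of a Gaussian beam at distance z from the waist."""
    return gaussian_beam_width(w0, wavelength, n0, z) * np.sqrt(2.0 * np.log(2.0))


def airy_fwhm_lateral(na: float, wavelength: float) -> float:
    """Lateral intensity FWHM of the scalar diffraction-limited focus,
    0.514 lambda / NA."""
    return 2.0 * 1.61633 / (2.0 * np.pi) * wavelength / na


def focus_fwhm_axial(na: float, wavelength: float, n0: float) -> float:
    """Axial intensity FWHM of the scalar focus.

    On-axis intensity [sin(u/4)/(u/4)]^2 with u = k NA^2 z / n reaches
    half max at u/4 = 1.39156, giving FWHM = 1.772 n lambda / NA^2.
    """
    return 2.0 * 1.39156 * 4.0 / (2.0 * np.pi) * n0 * wavelength / na**2


def direct_diffraction(field: ComplexField, dz: float, n0: float) -> ComplexField:
    """Direct Rayleigh-Sommerfeld (type I) summation; O(N^4), grids <= 64^2.

    out(p) = sum_q u(q) * K(p - q) dx dy with the exact spherical-wave
    kernel K = (z / 2 pi r^2) (1/r - i k) e^{i k r}.
    """
    ny, nx = field.shape
    if nx > 64 or ny > 64:
        raise ValueError("direct summation oracle is restricted to grids <= 64^2")
    if dz == 0:
        return field.copy()
    k = n0 * field.k0
    dx, dy = field.dx, field.dy
    ox = (np.arange(2 * nx - 1) - (nx - 1)) * dx
    oy = (np.arange(2 * ny - 1) - (ny - 1)) * dy
    OX, OY = np.meshgrid(ox, oy)
    r = np.sqrt(OX**2 + OY**2 + dz**2)
    kern = (dz / (2.0 * np.pi * r**2)) * (1.0 / r - 1j * k) * np.exp(1j * k * r)
    kern = kern * dx * dy
    u = field.values
    out = np.empty_like(u)
    for i in range(ny):
        for j in range(nx):
            block = kern[i : i + ny, j : j + nx][::-1, ::-1]
            out[i, j] = np.sum(u * block)
    res = field.copy()
    res.values = out
    res.z_position = field.z_position + dz
    return res


def sequential_psf(
    volume: RefractiveVolume,
    source_pos: tuple[float, float, float],
    detect_pupil: PupilSpec,
    tile_slices: tuple[slice, slice],
    psf_nz: int,
    config: PropagatorConfig | None = None,
) -> np.ndarray:
    """Single-source reference PSF for the multiplexing equivalence check.

    Propagates one diffraction-limited point source from its plane to
    the detection-side boundary, refocuses through the ideal NA crop
    (re-implemented inline — no PSF-engine code), and crops the given
    camera window.  Returns the raw intensity stack
    (psf_nz, tile_height, tile_width).
    """
    if config is None:
        config = PropagatorConfig()
    grid = volume.grid
    dz = grid.dz
    x, y, z = source_pos
    j0 = int(round(z / dz))
    depth = grid.nz * dz - j0 * dz

    src = make_field(
        SourceSpec(kind="point_source", pupil=detect_pupil, focus_position=(x, y, 0.0)),
        grid,
    )
    res = propagate(src, volume, config, z_start=j0, z_stop=grid.nz)
    exit_values = res.final.values

    # inline ideal-lens refocus: NA crop + homogeneous back-propagation
    from scipy import fft as sp_fft

    k0 = 2.0 * np.pi / detect_pupil.wavelength
    ky = 2.0 * np.pi * sp_fft.fftfreq(grid.ny, d=grid.dy)[:, None]
    kx = 2.0 * np.pi * sp_fft.fftfreq(grid.nx, d=grid.dx)[None, :]
    kr = np.sqrt(kx**2 + ky**2)
    kna = k0 * detect_pupil.na
    soft = detect_pupil.softness
    if soft > 0:
        r0 = (1.0 - soft) * kna
        t = np.clip((kr - r0) / (kna - r0), 0.0, 1.0)
        crop = 1.0 - t * t * t * (t * (6.0 * t - 15.0) + 10.0)
    else:
        crop = (kr <= kna).astype(float)
    arg = (volume.n_ambient * k0) ** 2 - kr**2
    prop_mask = arg > 0
    kz = np.sqrt(np.where(prop_mask, arg, 0.0))
    spectrum = sp_fft.fft2(exit_values) * crop

    half = (psf_nz - 1) / 2.0 * dz
    z_offsets = np.linspace(-depth - half, -depth + half, psf_nz)
    rows, cols = tile_slices
    height = rows.stop - rows.start
    width = cols.stop - cols.start
    out = np.empty((psf_nz, height, width))
    for i, zr in enumerate(z_offsets):
        phase = np.where(prop_mask, np.exp(1j * kz * zr), 0.0)
        u = sp_fft.ifft2(spectrum * phase)
        out[i] = np.abs(u[rows, cols]) ** 2
    return out
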