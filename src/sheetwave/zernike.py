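"""Zernike polynomials in Noll ordering, RMS-normalized on the unit disk.

Noll's single-index scheme: j=1 piston, j=2/3 x/y tilt, j=4 defocus,
j=5/6 astigmatism, j=7/8 coma, ...  With the normalization used here
(sqrt(n+1) for m=0 terms, sqrt(2(n+1)) otherwise) the coefficient of
each mode equals the RMS wavefront contribution of that mode, so
coefficient vectors are directly comparable across modes.
"""

from __future__ import annotations

from math import factorial

import numpy as np

__all__ = ["noll_to_nm", "zernike_noll", "synthesize", "decompose"]


def noll_to_nm(j: int) -> tuple[int, int]:
    """Map Noll index j (>= 1) to radial degree n and azimuthal order m.

    The sign of m encodes sin (m < 0) versus cos (m > 0) terms; Noll
    assigns cosine terms to even j and sine terms to odd j.
    """
    if j < 1:
        raise ValueError("Noll index starts at 1")
    n = 0
    j1 = j - 1
    while j1 > n:
        n += 1
        j1 -= n
    m = (-1) ** j * ((n % 2) + 2 * ((j1 + ((n + 1) % 2)) // 2))
    return n, m


def _radial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho, dtype=float)
    for k in range((n - m) // 2 + 1):
        c = (
            (-1) ** k
            * factorial(n - k)
            / (factorial(k) * factorial((n + m) // 2 - k) * factorial((n - m) // 2 - k))
        )
        out += c * rho ** (n - 2 * k)
    return out


def zernike_noll(j: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Evaluate the RMS-normalized Noll mode Z_j at polar pupil coords.

    ``rho`` should be within [0, 1]; values outside the disk are still
    evaluated (callers mask).
    """
    n, m = noll_to_nm(j)
    rad = _radial(n, abs(m), np.asarray(rho, dtype=float))
    if m == 0:
        return np.sqrt(n + 1.0) * rad
    norm = np.sqrt(2.0 * (n + 1.0))
    if m > 0:
        return norm * rad * np.cos(m * theta)
    return norm * rad * np.sin(-m * theta)


def synthesize(coeffs: np.ndarray, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Wavefront (radians) from Noll coefficients c_1..c_J."""
    coeffs = np.asarray(coeffs, dtype=float)
    out = np.zeros(np.broadcast(rho, theta).shape, dtype=float)
    for idx, c in enumerate(coeffs, start=1):
        if c != 0.0:
            out += c * zernike_noll(idx, rho, theta)
    return out


def decompose(
    phase: np.ndarray,
    rho: np.ndarray,
    theta: np.ndarray,
    mask: np.ndarray,
    j_max: int,
) -> tuple[np.ndarray, float]:
    """Least-squares Noll coefficients of a sampled wavefront.

    Returns (coefficients c_1..c_{j_max}, residual RMS in radians) fit
    over the masked pupil samples.
    """
    rho_m = rho[mask]
    theta_m = theta[mask]
    target = phase[mask]
    design = np.column_stack(
        [zernike_noll(j, rho_m, theta_m) for j in range(1, j_max + 1)]
    )
    coeffs, *_ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ coeffs
    rms = float(np.sqrt(np.mean(resid**2)))
    return coeffs, rms
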