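"""Real, orthonormal, even-order spherical-harmonic basis and helpers.

Convention (identifier ``"real_sym_orthonormal"``): for even l and
-l <= m <= l,

    Y_{l,m}  =  sqrt(2) * (-1)^m * Im[Y_l^{|m|}]   (m < 0)
             =  Y_l^0                               (m = 0)
             =  sqrt(2) * (-1)^m * Re[Y_l^m]        (m > 0)

with Y_l^m the complex orthonormal harmonics. The basis is orthonormal on
the sphere, so a function of constant amplitude A has c00 = A * sqrt(4*pi),
and the spherical mean of any expansion equals c00 / sqrt(4*pi).
"""

from __future__ import annotations

import numpy as np
from scipy.special import sph_harm_y

BASIS_CONVENTION = "real_sym_orthonormal"

__all__ = [
    "BASIS_CONVENTION",
    "sh_degrees",
    "n_coeffs",
    "real_sym_sh_basis",
    "cart_to_spherical",
    "fibonacci_sphere",
    "axial_kernel_coeffs",
    "convolution_weights",
]


def sh_degrees(lmax: int) -> tuple[np.ndarray, np.ndarray]:
    """(l, m) index arrays of the even-order basis up to ``lmax``."""
    ls, ms = [], []
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            ls.append(l)
            ms.append(m)
    return np.asarray(ls), np.asarray(ms)


def n_coeffs(lmax: int) -> int:
    return (lmax + 1) * (lmax + 2) // 2


def cart_to_spherical(xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors -> (polar theta, azimuth phi)."""
    xyz = np.asarray(xyz, dtype=float)
    r = np.linalg.norm(xyz, axis=-1)
    theta = np.arccos(np.clip(xyz[..., 2] / np.where(r == 0, 1.0, r), -1.0, 1.0))
    phi = np.arctan2(xyz[..., 1], xyz[..., 0])
    return theta, phi


def real_sym_sh_basis(lmax: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Design matrix (n_points, n_coeffs) of the real even-order basis."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    ls, ms = sh_degrees(lmax)
    out = np.empty((theta.size, ls.size))
    for j, (l, m) in enumerate(zip(ls, ms)):
        y = sph_harm_y(l, abs(m), theta, phi)
        if m == 0:
            out[:, j] = y.real
        elif m > 0:
            out[:, j] = np.sqrt(2.0) * (-1.0) ** m * y.real
        else:
            out[:, j] = np.sqrt(2.0) * (-1.0) ** m * y.imag
    return out


def fibonacci_sphere(n: int = 300) -> np.ndarray:
    """Deterministic near-uniform direction set on the full sphere, (n, 3)."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = 2.0 * np.pi * i / golden
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def axial_kernel_coeffs(profile, lmax: int, n_quad: int = 128) -> np.ndarray:
    """m=0 SH coefficients r_l of an axially symmetric function of theta.

    ``profile`` maps polar angle theta (array) to amplitude; coefficients are
    computed by Gauss-Legendre quadrature of 2*pi * int f(theta) Y_l0 sin d(theta).
    """
    x, w = np.polynomial.legendre.leggauss(n_quad)  # x = cos(theta)
    theta = np.arccos(x)
    f = profile(theta)
    ls = np.arange(0, lmax + 1, 2)
    out = np.empty(ls.size)
    for j, l in enumerate(ls):
        y = sph_harm_y(l, 0, theta, np.zeros_like(theta)).real
        out[j] = 2.0 * np.pi * np.sum(w * f * y)
    return out


def convolution_weights(r_l: np.ndarray, lmax: int) -> np.ndarray:
    """Per-coefficient forward-convolution weights.

    Convolving an fODF (coefficients f_lm) with an axially symmetric kernel
    whose m=0 coefficients are r_l gives signal coefficients
    s_lm = sqrt(4*pi / (2l+1)) * r_l * f_lm (Funk-Hecke).
    """
    ls, _ = sh_degrees(lmax)
    per_l = {l: r_l[j] for j, l in enumerate(range(0, lmax + 1, 2))}
    return np.array([np.sqrt(4.0 * np.pi / (2 * l + 1)) * per_l[l] for l in ls])
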