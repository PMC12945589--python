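"""Constrained spherical deconvolution and apparent fiber density.

The fiber orientation distribution (fODF) is recovered per voxel by
deconvolving the b0-normalized single-shell signal with an axially
symmetric single-fiber response calibrated from high-FA voxels, under an
iteratively reweighted non-negativity constraint evaluated on a fixed
300-direction sphere (Tournier-style). AFDtotal is the l=0 coefficient of
the fODF in the real orthonormal basis, so the spherical mean of the fODF
is AFDtotal / sqrt(4*pi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dwi import DWIDataset, TensorFitResult
from .grid import ScalarMap, VoxelGrid
from .sh import (
    BASIS_CONVENTION,
    cart_to_spherical,
    convolution_weights,
    fibonacci_sphere,
    real_sym_sh_basis,
    sh_degrees,
)

__all__ = ["ResponseFunction", "FODFField", "estimate_response", "fit_csd", "afd_total"]


@dataclass
class ResponseFunction:
    """Axially symmetric single-fiber response: m=0 even-order SH coefficients."""

    sh_coeffs: np.ndarray  # one coefficient per even l = 0, 2, ..., lmax
    lmax: int
    calibration_n: int
    fa_threshold: float

    def __post_init__(self) -> None:
        self.sh_coeffs = np.asarray(self.sh_coeffs, dtype=float)
        if self.sh_coeffs.size != self.lmax // 2 + 1:
            raise ValueError("need one m=0 coefficient per even l up to lmax")
        if self.sh_coeffs[0] <= 0:
            raise ValueError("response l=0 coefficient must be positive")


@dataclass
class FODFField:
    """Per-voxel fODF spherical-harmonic coefficients (even orders)."""

    grid: VoxelGrid
    sh_coeffs: np.ndarray  # grid.shape + (n_coeffs,)
    mask: np.ndarray
    lmax: int
    basis: str = BASIS_CONVENTION
    n_nonconverged: int = 0

    def amplitudes(self, directions: np.ndarray) -> np.ndarray:
        """fODF amplitudes of in-mask voxels along ``directions`` (n_mask, n_dir)."""
        theta, phi = cart_to_spherical(directions)
        b = real_sym_sh_basis(self.lmax, theta, phi)
        return self.sh_coeffs[self.mask] @ b.T


def estimate_response(
    dwi: DWIDataset,
    fit: TensorFitResult,
    fa_threshold: float = 0.7,
    max_voxels: int = 300,
    lmax: int = 8,
) -> ResponseFunction:
    """Calibrate the single-fiber response from high-FA voxels.

    Each selected voxel's b0-normalized signals are expressed as a function
    of the angle between the gradient and the voxel's principal eigenvector
    (reorientation to the pole); the pooled (angle, signal) samples are
    projected onto the m=0 even-order basis by least squares.
    """
    sel = fit.fa[fit.mask] >= fa_threshold
    n_sel = int(sel.sum())
    if n_sel < 20:
        raise ValueError(
            f"only {n_sel} voxels with FA >= {fa_threshold}; lower the threshold"
        )
    fa_in = fit.fa[fit.mask]
    order = np.argsort(fa_in)[::-1][:max_voxels]
    order = order[fa_in[order] >= fa_threshold]

    sig = dwi.signals[dwi.mask][order]
    b0 = sig[:, dwi.b0_index].mean(axis=1)
    s = sig[:, dwi.dwi_index] / b0[:, None]
    e1 = fit.principal_direction()[order]
    g = dwi.bvecs[dwi.dwi_index]
    cos_t = np.abs(e1 @ g.T)  # antipodal symmetry
    theta = np.arccos(np.clip(cos_t, -1.0, 1.0))

    ls = np.arange(0, lmax + 1, 2)
    design = real_sym_sh_basis(lmax, theta.ravel(), np.zeros(theta.size))
    _, ms = sh_degrees(lmax)
    design = design[:, ms == 0]
    coeffs, *_ = np.linalg.lstsq(design, s.ravel(), rcond=None)
    return ResponseFunction(
        sh_coeffs=coeffs, lmax=lmax, calibration_n=len(order), fa_threshold=fa_threshold
    )


def fit_csd(
    dwi: DWIDataset,
    response: ResponseFunction,
    lmax: int = 8,
    reg_lambda: float = 1.0,
    amp_threshold_tau: float = 0.1,
    max_iter: int = 50,
    n_constraint_dirs: int = 300,
) -> FODFField:
    """Constrained spherical deconvolution of single-shell DWI.

    Per voxel, solve the SH-domain deconvolution of the b0-normalized signal
    by the response with an iterative soft non-negativity constraint:
    sphere directions whose fODF amplitude falls below
    ``amp_threshold_tau * mean(initial amplitude)`` are penalized via
    lambda-weighted least squares until the constraint set stops changing.
    Non-convergent voxels are retained and counted.
    """
    if lmax % 2:
        raise ValueError("lmax must be even")
    n_dirs = dwi.dwi_index.size
    while (lmax + 1) * (lmax + 2) // 2 > n_dirs and lmax > 2:
        lmax -= 2
        warnings.warn(f"too few directions; lowering lmax to {lmax}")
    if response.lmax < lmax:
        raise ValueError("response lmax is lower than the requested fODF lmax")

    ls, _ = sh_degrees(lmax)
    r_l = response.sh_coeffs[: lmax // 2 + 1]
    k = convolution_weights(r_l, lmax)

    g = dwi.bvecs[dwi.dwi_index]
    theta, phi = cart_to_spherical(g)
    b_sig = real_sym_sh_basis(lmax, theta, phi)
    conv = b_sig * k[None, :]

    sphere = fibonacci_sphere(n_constraint_dirs)
    th_s, ph_s = cart_to_spherical(sphere)
    b_sph = real_sym_sh_basis(lmax, th_s, ph_s)

    lam = reg_lambda * np.linalg.norm(conv) / np.linalg.norm(b_sph)
    ata = conv.T @ conv

    sig = dwi.signals[dwi.mask]
    b0 = sig[:, dwi.b0_index].mean(axis=1)
    valid = b0 > 0
    s = np.zeros((sig.shape[0], n_dirs))
    s[valid] = sig[valid][:, dwi.dwi_index] / b0[valid, None]

    # initial estimate: low-order (l <= 4) unconstrained fit
    low = ls <= 4
    x0_low, *_ = np.linalg.lstsq(conv[:, low], s.T, rcond=None)
    n_coef = ls.size
    n_vox = sig.shape[0]
    coeffs = np.zeros((n_vox, n_coef))
    coeffs[:, low] = x0_low.T

    amp0 = coeffs @ b_sph.T
    thr = amp_threshold_tau * amp0.mean(axis=1)

    n_nonconv = 0
    for i in range(n_vox):
        if not valid[i]:
            continue
        x = coeffs[i]
        neg = (b_sph @ x) < thr[i]
        converged = False
        for _ in range(max_iter):
            m = b_sph[neg]
            lhs = ata + (lam**2) * (m.T @ m)
            x = np.linalg.solve(lhs, conv.T @ s[i])
            new_neg = (b_sph @ x) < thr[i]
            if np.array_equal(new_neg, neg):
                converged = True
                break
            neg = new_neg
        if not converged:
            n_nonconv += 1
        coeffs[i] = x
    if n_nonconv:
        warnings.warn(
            f"{n_nonconv}/{n_vox} voxels did not converge within {max_iter} iterations"
        )
    out = np.zeros(dwi.grid.shape + (n_coef,))
    out[dwi.mask] = coeffs
    return FODFField(
        grid=dwi.grid, sh_coeffs=out, mask=dwi.mask, lmax=lmax, n_nonconverged=n_nonconv
    )


def afd_total(fodf: FODFField) -> ScalarMap:
    """AFDtotal: the l=0 fODF coefficient per voxel."""
    values = fodf.sh_coeffs[..., 0]
    return ScalarMap(grid=fodf.grid, values=values, mask=fodf.mask, kind="afd")
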