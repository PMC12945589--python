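"""Diffusion-weighted datasets: containers, forward simulation, tensor fit.

The forward model is a sum of cylindrically symmetric tensor compartments
(axial/radial diffusivities along a fiber orientation) plus an isotropic
remainder, with optional Rician noise on the magnitudes. The tensor fit is
the standard weighted log-linear inversion yielding FA and MD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import VoxelGrid

__all__ = [
    "DWIDataset",
    "TensorFitResult",
    "make_gradient_table",
    "fiber_tensor",
    "simulate_dwi",
    "fit_tensor",
    "tensor_fa",
]

_B0_TOL = 50.0  # s/mm^2: volumes with b below this count as b=0


@dataclass
class DWIDataset:
    """4-D diffusion signals plus FSL-style gradient table.

    ``signals`` has shape grid.shape + (n_volumes,); ``bvals`` in s/mm^2 and
    ``bvecs`` (n_volumes, 3) unit vectors for b > 0 volumes.
    """

    grid: VoxelGrid
    signals: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        nvol = self.signals.shape[-1]
        if self.signals.shape[:-1] != self.grid.shape:
            raise ValueError("signals must have shape grid.shape + (n_volumes,)")
        if self.bvals.shape != (nvol,) or self.bvecs.shape != (nvol, 3):
            raise ValueError("bvals/bvecs do not match the number of volumes")
        if not self.b0_index.size:
            raise ValueError("dataset contains no b=0 volume")
        norms = np.linalg.norm(self.bvecs[self.dwi_index], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("b>0 gradient vectors must be unit norm (tol 1e-6)")

    @property
    def b0_index(self) -> np.ndarray:
        return np.nonzero(self.bvals < _B0_TOL)[0]

    @property
    def dwi_index(self) -> np.ndarray:
        return np.nonzero(self.bvals >= _B0_TOL)[0]

    @property
    def nominal_b(self) -> float:
        return float(np.median(self.bvals[self.dwi_index]))

    def in_mask_signals(self) -> np.ndarray:
        return self.signals[self.mask]


@dataclass
class TensorFitResult:
    """Voxelwise diffusion tensor (lower-triangular order), FA and MD."""

    grid: VoxelGrid
    tensor: np.ndarray  # grid.shape + (6,) order xx, xy, yy, xz, yz, zz
    fa: np.ndarray
    md: np.ndarray
    mask: np.ndarray
    n_clamped: int = 0

    def principal_direction(self) -> np.ndarray:
        """In-mask principal eigenvectors, (n_mask, 3)."""
        m = _tensor_matrices(self.tensor[self.mask])
        w, v = np.linalg.eigh(m)
        return v[:, :, 2]


def make_gradient_table(n_dirs: int = 64, b: float = 1000.0, n_b0: int = 1
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic single-shell gradient table (bvals, bvecs).

    Directions are a Fibonacci-spiral set mapped to the hemisphere (antipodal
    symmetry makes the hemisphere sufficient for even-order models).
    """
    from .sh import fibonacci_sphere

    dirs = fibonacci_sphere(2 * n_dirs)
    dirs = dirs[dirs[:, 2] >= 0][:n_dirs]
    if dirs.shape[0] < n_dirs:  # pad from the other hemisphere if needed
        extra = fibonacci_sphere(4 * n_dirs)
        extra = extra[extra[:, 2] >= 0]
        dirs = extra[:n_dirs]
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(dirs.shape[0], b)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return bvals, bvecs


def fiber_tensor(orientation: np.ndarray, axial: float, radial: float) -> np.ndarray:
    """Cylindrically symmetric diffusion tensor along ``orientation`` (3x3)."""
    u = np.asarray(orientation, dtype=float)
    u = u / np.linalg.norm(u)
    return radial * np.eye(3) + (axial - radial) * np.outer(u, u)


def simulate_dwi(
    fiber_config,
    response_params: tuple[float, float] = (1.7e-3, 0.3e-3),
    bvals: np.ndarray | None = None,
    bvecs: np.ndarray | None = None,
    snr: float = np.inf,
    seed: int = 0,
    iso_diffusivity: float = 3.0e-3,
    grid: VoxelGrid | None = None,
    mask: np.ndarray | None = None,
) -> DWIDataset:
    """Forward-simulate single-shell DWI signals for a set of voxels.

    Parameters
    ----------
    fiber_config : sequence over voxels of sequences of (orientation, fraction)
        Per-voxel fiber compartments; fractions must sum to <= 1 and the
        remainder is an isotropic compartment with ``iso_diffusivity``.
    snr : float
        b=0 signal-to-noise ratio of the Rician noise; ``inf`` for noiseless.
    """
    if bvals is None or bvecs is None:
        bvals, bvecs = make_gradient_table()
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    if not np.any(bvals < _B0_TOL):
        raise ValueError("gradient table must include a b=0 volume")
    dwi_sel = bvals >= _B0_TOL
    norms = np.linalg.norm(bvecs[dwi_sel], axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("b>0 gradient vectors must be unit norm (tol 1e-6)")
    axial, radial = response_params
    n_vox = len(fiber_config)
    if grid is None:
        grid = VoxelGrid(shape=(n_vox, 1, 1), voxel_size=(2.0, 2.0, 2.0), affine=None)
        mask = np.ones(grid.shape, dtype=bool)
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    if int(mask.sum()) != n_vox:
        raise ValueError("fiber_config length must equal the number of in-mask voxels")

    nvol = bvals.size
    sig = np.zeros((n_vox, nvol))
    for i, fibers in enumerate(fiber_config):
        total = 0.0
        for orientation, fraction in fibers:
            if fraction < 0:
                raise ValueError("fiber fractions must be >= 0")
            total += fraction
            d = fiber_tensor(orientation, axial, radial)
            quad = np.einsum("vi,ij,vj->v", bvecs, d, bvecs)
            sig[i] += fraction * np.exp(-bvals * quad)
        if total > 1.0 + 1e-9:
            raise ValueError(f"voxel {i}: fiber fractions sum to {total} > 1")
        sig[i] += (1.0 - total) * np.exp(-bvals * iso_diffusivity)
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        sigma = 1.0 / snr  # b0 signal is 1 by construction
        noise_r = rng.normal(0.0, sigma, size=sig.shape)
        noise_i = rng.normal(0.0, sigma, size=sig.shape)
        sig = np.sqrt((sig + noise_r) ** 2 + noise_i**2)
    signals = np.zeros(grid.shape + (nvol,))
    signals[mask] = sig
    return DWIDataset(grid=grid, signals=signals, bvals=bvals, bvecs=bvecs, mask=mask)


def _tensor_matrices(six: np.ndarray) -> np.ndarray:
    """(n, 6) lower-triangular components -> (n, 3, 3) symmetric matrices."""
    m = np.empty(six.shape[:-1] + (3, 3))
    m[..., 0, 0] = six[..., 0]
    m[..., 0, 1] = m[..., 1, 0] = six[..., 1]
    m[..., 1, 1] = six[..., 2]
    m[..., 0, 2] = m[..., 2, 0] = six[..., 3]
    m[..., 1, 2] = m[..., 2, 1] = six[..., 4]
    m[..., 2, 2] = six[..., 5]
    return m


def tensor_fa(eigvals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from eigenvalues (last axis length 3)."""
    lam = np.asarray(eigvals, dtype=float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(((lam - mean) ** 2).sum(axis=-1))
    den = np.sqrt((lam**2).sum(axis=-1))
    fa = np.zeros(lam.shape[:-1])
    np.divide(num, den, out=fa, where=den > 0)
    return np.sqrt(1.5) * fa


def fit_tensor(dwi: DWIDataset) -> TensorFitResult:
    """Weighted log-linear diffusion-tensor fit per in-mask voxel.

    Log-signals are regressed on the quadratic gradient design with weights
    equal to the squared predicted signal (one reweighting pass from the OLS
    estimate). Voxels with non-positive b=0 signal are excluded from the
    mask with a warning; negative eigenvalues are clamped to 0 for the FA
    computation and counted.
    """
    if dwi.dwi_index.size < 6:
        raise ValueError("tensor fit needs >= 6 diffusion directions plus b=0")
    mask = dwi.mask.copy()
    sig = dwi.signals[mask]
    b0 = sig[:, dwi.b0_index].mean(axis=1)
    good = b0 > 0
    if not np.all(good):
        warnings.warn(f"{int((~good).sum())} voxels with non-positive b0 excluded")
        idx = np.nonzero(mask.ravel())[0][~good]
        flat = mask.ravel()
        flat[idx] = False
        mask = flat.reshape(dwi.mask.shape)
        sig = sig[good]
        b0 = b0[good]

    g = dwi.bvecs
    b = dwi.bvals
    # design for components (xx, xy, yy, xz, yz, zz) + log S0
    design = np.column_stack([
        -b * g[:, 0] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -b * g[:, 1] ** 2,
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
        -b * g[:, 2] ** 2,
        np.ones_like(b),
    ])
    logs = np.log(np.clip(sig, 1e-12, None))
    coef, *_ = np.linalg.lstsq(design, logs.T, rcond=None)
    # one WLS pass: weights = predicted signal squared
    pred = design @ coef
    w = np.exp(pred) ** 2
    coef_w = np.empty_like(coef)
    for i in range(coef.shape[1]):
        dw = design * w[:, i : i + 1]
        coef_w[:, i] = np.linalg.solve(design.T @ dw, dw.T @ logs[i])
    six = coef_w[:6].T
    mats = _tensor_matrices(six)
    lam = np.linalg.eigvalsh(mats)
    n_clamped = int(np.any(lam < 0, axis=-1).sum())
    lam_cl = np.clip(lam, 0.0, None)
    fa_in = tensor_fa(lam_cl)
    md_in = lam.mean(axis=-1)

    shape = dwi.grid.shape
    tensor = np.zeros(shape + (6,))
    fa = np.zeros(shape)
    md = np.zeros(shape)
    tensor[mask] = six
    fa[mask] = fa_in
    md[mask] = md_in
    if n_clamped:
        warnings.warn(f"{n_clamped} voxels had negative eigenvalues clamped for FA")
    return TensorFitResult(grid=dwi.grid, tensor=tensor, fa=fa, md=md, mask=mask,
                           n_clamped=n_clamped)
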