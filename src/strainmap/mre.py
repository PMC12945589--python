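"""Voxelwise mechanical summaries from MRE-derived fields.

Octahedral shear strain (OSS) and maximum principal strain (MPS) are
rotation-invariant eigenvalue summaries of the voxelwise Green-Lagrange
strain tensor; the damping ratio xi = G''/(2 G') summarizes viscous energy
dissipation relative to elastic storage. Normative maps are built by
z-scoring OSS within subject and averaging the z-maps across the healthy
cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid import ComplexModulusField, ScalarMap, StrainTensorField

__all__ = [
    "compute_oss",
    "compute_mps",
    "zscore_within_subject",
    "damping_ratio",
    "normative_mean_map",
    "region_contrast",
    "RegionContrast",
]


def _eigvals(field: StrainTensorField) -> np.ndarray:
    """Eigenvalues of the in-mask tensors, ascending along the last axis."""
    return np.linalg.eigvalsh(field.as_matrices())


def compute_oss(field: StrainTensorField) -> ScalarMap:
    """Octahedral shear strain per voxel.

    OSS = (2/3) * sqrt((e1-e2)^2 + (e2-e3)^2 + (e3-e1)^2) with e1 >= e2 >= e3
    the strain-tensor eigenvalues. OSS is non-negative, invariant to rotation
    of the tensor, and insensitive to the hydrostatic (volumetric) part.
    """
    w = _eigvals(field)
    e1, e2, e3 = w[:, 2], w[:, 1], w[:, 0]
    oss = (2.0 / 3.0) * np.sqrt((e1 - e2) ** 2 + (e2 - e3) ** 2 + (e3 - e1) ** 2)
    out = np.zeros(field.grid.shape)
    out[field.mask] = oss
    return ScalarMap(grid=field.grid, values=out, mask=field.mask, kind="oss")


def compute_mps(field: StrainTensorField) -> ScalarMap:
    """Maximum principal strain: the largest strain-tensor eigenvalue per voxel."""
    w = _eigvals(field)
    out = np.zeros(field.grid.shape)
    out[field.mask] = w[:, 2]
    return ScalarMap(grid=field.grid, values=out, mask=field.mask, kind="mps")


def zscore_within_subject(smap: ScalarMap) -> ScalarMap:
    """Z-score a map across all in-mask voxels of one subject.

    Uses the sample (n-1) standard deviation. The output has in-mask mean 0
    and sample sd 1; outside-mask voxels are set to 0 but carry no meaning.
    """
    inside = smap.in_mask
    if inside.size < 2:
        raise ValueError("z-scoring needs at least 2 in-mask voxels")
    sd = inside.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant map (zero in-mask variance)")
    out = np.zeros(smap.grid.shape)
    out[smap.mask] = (inside - inside.mean()) / sd
    return smap.like(out, kind=f"{smap.kind}_z" if not smap.kind.endswith("_z") else smap.kind)


def damping_ratio(moduli: ComplexModulusField) -> ScalarMap:
    """Damping ratio xi = G'' / (2 G'), dimensionless, >= 0 inside the mask."""
    out = np.zeros(moduli.grid.shape)
    g1 = moduli.storage[moduli.mask]
    g2 = moduli.loss[moduli.mask]
    out[moduli.mask] = g2 / (2.0 * g1)
    return ScalarMap(grid=moduli.grid, values=out, mask=moduli.mask, kind="damping")


def normative_mean_map(zmaps: list[ScalarMap]) -> ScalarMap:
    """Voxelwise arithmetic mean of per-subject z-maps on one grid/mask."""
    if not zmaps:
        raise ValueError("need at least one map")
    first = zmaps[0]
    for m in zmaps[1:]:
        first.check_compatible(m)
    stacked = np.stack([m.values for m in zmaps])
    out = np.zeros(first.grid.shape)
    out[first.mask] = stacked.mean(axis=0)[first.mask]
    return first.like(out, kind="oss_z_normative")


@dataclass
class RegionContrast:
    """Paired high-strain vs low-strain contrast across subjects."""

    hs_means: np.ndarray
    ls_means: np.ndarray
    t: float
    p: float
    n: int

    @property
    def direction(self) -> str:
        d = float(np.mean(self.hs_means - self.ls_means))
        return "hs_greater" if d > 0 else ("ls_greater" if d < 0 else "equal")


def region_contrast(maps: list[ScalarMap], roi) -> RegionContrast:
    """Paired t-test across subjects on (HS mean - LS mean) of any scalar map.

    ``roi`` is a :class:`~strainmap.vulnerability.StrainROIMask`; the test is
    the standard paired t on the per-subject region-mean differences.
    """
    if len(maps) < 2:
        raise ValueError("region contrast needs >= 2 subjects")
    if not roi.hs.any() or not roi.ls.any():
        raise ValueError("HS or LS region is empty")
    hs = np.array([m.values[roi.hs].mean() for m in maps])
    ls = np.array([m.values[roi.ls].mean() for m in maps])
    diff = hs - ls
    if np.all(diff == 0):
        return RegionContrast(hs_means=hs, ls_means=ls, t=0.0, p=1.0, n=len(maps))
    if diff.std(ddof=1) == 0:
        raise ValueError("degenerate paired t-test: zero variance of differences")
    t, p = stats.ttest_rel(hs, ls)
    return RegionContrast(hs_means=hs, ls_means=ls, t=float(t), p=float(p), n=len(maps))
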