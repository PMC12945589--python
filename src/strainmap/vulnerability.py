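"""Normative high-strain / low-strain region definition and validation.

The vulnerability map is built from healthy-cohort OSS z-maps: a voxelwise
one-sample t-test (H0: mean z = 0), Benjamini-Hochberg FDR over in-mask
voxels, and a joint threshold (q < q_thr and t >= t_thr) defining the
high-strain (HS) region; the low-strain (LS) region is its complement
within the brain mask. Generalizability is checked by leave-one-out
cross-validation with a Wilcoxon matched-pairs test on held-out subjects'
HS vs LS mean strain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .grid import ScalarMap, VoxelGrid

__all__ = [
    "VoxelStatMap",
    "StrainROIMask",
    "LooResult",
    "voxelwise_one_sample_t",
    "bh_fdr",
    "define_hs_mask",
    "intersect_masks",
    "loo_cross_validation",
    "wilcoxon_paired",
    "tissue_composition",
]


@dataclass
class VoxelStatMap:
    """Voxelwise one-sample t, two-sided p, and BH-adjusted q volumes."""

    grid: VoxelGrid
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    mask: np.ndarray
    n: int
    n_degenerate: int = 0


@dataclass
class StrainROIMask:
    """Paired HS/LS partition of the brain mask.

    Invariants (asserted on construction): hs and ls are disjoint and their
    union is exactly the brain mask.
    """

    grid: VoxelGrid
    hs: np.ndarray
    ls: np.ndarray
    brain_mask: np.ndarray
    thresholds: tuple[float, float] = (np.nan, np.nan)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.hs = np.asarray(self.hs, dtype=bool)
        self.ls = np.asarray(self.ls, dtype=bool)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if np.any(self.hs & self.ls):
            raise ValueError("HS and LS overlap")
        if not np.array_equal(self.hs | self.ls, self.brain_mask):
            raise ValueError("HS and LS do not partition the brain mask")


@dataclass
class LooResult:
    """Per-fold held-out HS/LS mean strain plus the matched-pairs test."""

    subject_ids: list[str]
    hs_means: np.ndarray
    ls_means: np.ndarray
    wilcoxon_statistic: float
    p: float
    excluded_folds: list[str] = field(default_factory=list)


def voxelwise_one_sample_t(zmaps: list[ScalarMap]) -> VoxelStatMap:
    """One-sample t-test across subjects at every in-mask voxel (H0: mean = 0).

    Degenerate voxels (zero across-subject sd) are retained with t = 0 and
    p = 1 so the BH multiplicity count stays stable; their number is reported
    via a warning and the ``n_degenerate`` field.
    """
    if len(zmaps) < 3:
        raise ValueError("voxelwise t-test needs >= 3 subjects")
    first = zmaps[0]
    for m in zmaps[1:]:
        first.check_compatible(m)
    data = np.stack([m.in_mask for m in zmaps])  # subjects x voxels
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    degenerate = sd == 0
    n_deg = int(degenerate.sum())
    if n_deg:
        warnings.warn(f"{n_deg} degenerate (zero-variance) voxels set to t=0, p=1")
    t = np.zeros_like(mean)
    np.divide(mean, sd / np.sqrt(n), out=t, where=~degenerate)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[degenerate] = 1.0
    q = bh_fdr(p)

    def _vol(flat, fill=0.0):
        out = np.full(first.grid.shape, fill)
        out[first.mask] = flat
        return out

    return VoxelStatMap(
        grid=first.grid,
        t=_vol(t),
        p=_vol(p, fill=1.0),
        q=_vol(q, fill=1.0),
        mask=first.mask.copy(),
        n=n,
        n_degenerate=n_deg,
    )


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Sort ascending, multiply p_(i) by m/i, take the cumulative minimum from
    the largest rank down, cap at 1, and return in the input order.
    """
    p = np.asarray(p, dtype=float)
    flat = p.ravel()
    if flat.size == 0:
        return p.copy()
    if np.any((flat < 0) | (flat > 1)) or not np.all(np.isfinite(flat)):
        raise ValueError("p-values must lie in [0, 1]")
    m = flat.size
    order = np.argsort(flat, kind="stable")
    ranked = flat[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(flat)
    q[order] = q_sorted
    return q.reshape(p.shape)


def define_hs_mask(
    stats_map: VoxelStatMap,
    brain_mask: np.ndarray,
    q_thr: float = 0.05,
    t_thr: float = 4.0,
    min_cluster_size: int = 1,
) -> StrainROIMask:
    """Joint FDR- and effect-size-thresholded high-strain mask.

    HS = {q < q_thr and t >= t_thr} within the brain mask; LS is the
    complement within the brain mask. ``min_cluster_size`` is a reporting
    option (default 1 = no cluster filtering).
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not np.array_equal(brain_mask, stats_map.mask):
        raise ValueError("stat map is not defined on the given brain mask")
    hs = brain_mask & (stats_map.q < q_thr) & (stats_map.t >= t_thr)
    if min_cluster_size > 1 and hs.any():
        labels, n_lab = ndimage.label(hs)
        sizes = np.bincount(labels.ravel())
        keep = np.zeros_like(sizes, dtype=bool)
        keep[1:] = sizes[1:] >= min_cluster_size
        hs = keep[labels]
    if not hs.any():
        raise ValueError(
            "empty high-strain mask: no voxel satisfies "
            f"q < {q_thr} and t >= {t_thr}; review thresholds"
        )
    ls = brain_mask & ~hs
    return StrainROIMask(
        grid=stats_map.grid,
        hs=hs,
        ls=ls,
        brain_mask=brain_mask,
        thresholds=(q_thr, t_thr),
        provenance=f"q<{q_thr} & t>={t_thr}, n={stats_map.n}",
    )


def intersect_masks(a: StrainROIMask, b: StrainROIMask) -> StrainROIMask:
    """Actuation-invariant HS region: intersection of two HS masks."""
    if not a.grid.matches(b.grid) or not np.array_equal(a.brain_mask, b.brain_mask):
        raise ValueError("ROI masks live on different grids or brain masks")
    hs = a.hs & b.hs
    if not hs.any():
        warnings.warn("HS intersection is empty")
    return StrainROIMask(
        grid=a.grid,
        hs=hs,
        ls=a.brain_mask & ~hs,
        brain_mask=a.brain_mask,
        thresholds=a.thresholds,
        provenance=f"intersection[({a.provenance}) & ({b.provenance})]",
    )


def wilcoxon_paired(x, y) -> tuple[float, float]:
    """Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped (Wilcoxon's original treatment); the exact
    two-sided p is used for n <= 25 surviving pairs, the normal approximation
    with continuity correction above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    d = x - y
    n_nonzero = int(np.count_nonzero(d))
    if n_nonzero == 0:
        raise ValueError("all differences are zero")
    method = "exact" if n_nonzero <= 25 else "approx"
    res = stats.wilcoxon(x, y, zero_method="wilcox", correction=(method == "approx"),
                         method=method)
    return float(res.statistic), float(res.pvalue)


def loo_cross_validation(
    zmaps: list[ScalarMap],
    subject_ids: list[str] | None = None,
    q_thr: float = 0.05,
    t_thr: float = 4.0,
) -> LooResult:
    """Leave-one-out cross-validation of the HS/LS definition.

    For each fold the stat map and HS mask are rebuilt from the n-1 remaining
    subjects and the held-out subject's mean strain inside HS and LS is
    recorded; folds whose mask comes up empty are excluded and reported. A
    Wilcoxon matched-pairs test compares the held-out (HS, LS) pairs.
    """
    n = len(zmaps)
    if n < 4:
        raise ValueError("leave-one-out needs >= 4 subjects")
    if subject_ids is None:
        subject_ids = [f"sub-{i:03d}" for i in range(n)]
    brain_mask = zmaps[0].mask
    hs_means, ls_means, kept, excluded = [], [], [], []
    for i in range(n):
        rest = [zmaps[j] for j in range(n) if j != i]
        sm = voxelwise_one_sample_t(rest)
        try:
            roi = define_hs_mask(sm, brain_mask, q_thr=q_thr, t_thr=t_thr)
        except ValueError:
            excluded.append(subject_ids[i])
            warnings.warn(f"fold {subject_ids[i]}: empty HS mask, fold excluded")
            continue
        held = zmaps[i].values
        hs_means.append(held[roi.hs].mean())
        ls_means.append(held[roi.ls].mean())
        kept.append(subject_ids[i])
    if len(kept) < 5:
        raise ValueError("too few valid folds for the matched-pairs test")
    stat, p = wilcoxon_paired(hs_means, ls_means)
    return LooResult(
        subject_ids=kept,
        hs_means=np.asarray(hs_means),
        ls_means=np.asarray(ls_means),
        wilcoxon_statistic=stat,
        p=p,
        excluded_folds=excluded,
    )


def tissue_composition(roi: StrainROIMask, labels: np.ndarray) -> dict[str, float]:
    """Tissue make-up of the HS mask.

    ``labels`` assigns each brain-mask voxel to gray matter (1), white matter
    (2) or other (0). Returns the HS fraction of total brain volume, the HS
    share of all GM and of all WM voxels, and the GM/WM/other fractions
    within the HS mask.
    """
    labels = np.asarray(labels)
    if labels.shape != roi.brain_mask.shape:
        raise ValueError("label volume shape does not match the brain mask")
    brain = roi.brain_mask
    hs = roi.hs
    gm = brain & (labels == 1)
    wm = brain & (labels == 2)
    n_hs = hs.sum()
    out = {
        "hs_fraction_of_brain": n_hs / brain.sum(),
        "hs_share_of_gm": (hs & gm).sum() / max(gm.sum(), 1),
        "hs_share_of_wm": (hs & wm).sum() / max(wm.sum(), 1),
        "gm_fraction_in_hs": (hs & gm).sum() / max(n_hs, 1),
        "wm_fraction_in_hs": (hs & wm).sum() / max(n_hs, 1),
    }
    out["other_fraction_in_hs"] = 1.0 - out["gm_fraction_in_hs"] - out["wm_fraction_in_hs"]
    return {k: float(v) for k, v in out.items()}
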