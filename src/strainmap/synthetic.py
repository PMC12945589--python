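"""Synthetic co-registered cohorts with known mechanical and injury structure.

Every downstream stage of the pipeline is exercised on data from this
module: a smooth normative shear-strain field with planted "vulnerable"
blobs, per-subject noisy strain-tensor realizations, viscoelastic moduli
correlated with the planted structure (stiffer, less dissipative tissue in
high-strain regions), and AFD maps generated linearly in the normative
strain z-score with group-specific slopes and subject random intercepts.

The generative AFD model for subject s at voxel v in strain bin b(v) is

    AFD(v, s) = intercept + slope_group(s) * z(v) + u_s + eta_{s,b(v)} + eps_v

with u_s ~ N(0, random_intercept_sd^2) a global subject offset,
eta_{s,b} ~ N(0, regional_noise_sd^2) regional (strain-stratum) subject
variability, and eps_v ~ N(0, voxel_noise_sd^2) voxelwise noise. The
regional term models the fact that a subject's AFD deviates from its global
offset coherently over anatomical territory, not voxel-by-voxel; it is also
what makes the subject-by-bin table behave like the exchangeable repeated
measures the mixed model assumes. The ``hs_deficit`` preset additionally
subtracts a fixed AFD decrement inside the planted region for the mTBI
group only.

Preset slopes (AFD units per strain z-score) mirror the fitted group
slopes reported for the corresponding cohorts: subacute/chronic
(control 0.041, mTBI 0.029), acute (control 0.041, mTBI 0.043).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import ComplexModulusField, ScalarMap, StrainTensorField, VoxelGrid

__all__ = [
    "ModulusParams",
    "GroundTruthSpec",
    "Preset",
    "PRESETS",
    "ellipsoid_mask",
    "make_normative_field",
    "default_ground_truth",
    "simulate_mre_cohort",
    "simulate_afd_cohort",
    "simulate_binned_afd",
    "simulate_roi_summary",
    "make_tissue_labels",
    "MRECohort",
    "AFDCohort",
]

#: OSS of the unit deviatoric template diag(1, 0, -1).
_TEMPLATE_OSS = (2.0 / 3.0) * np.sqrt(6.0)


@dataclass(frozen=True)
class ModulusParams:
    """Planted viscoelastic contrast between high- and low-strain tissue."""

    storage_baseline: float = 2200.0  # Pa
    storage_hs_increment: float = 300.0  # Pa
    damping_baseline: float = 0.25
    damping_hs_decrement: float = 0.05
    storage_noise_sd: float = 50.0  # Pa
    damping_noise_sd: float = 0.005
    # fractional between-subject variability of the planted HS contrast,
    # clipped so every subject keeps the planted direction
    subject_contrast_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.damping_baseline - self.damping_hs_decrement <= 0:
            raise ValueError("damping baseline minus HS decrement must stay positive")


@dataclass(frozen=True)
class Preset:
    slope_control: float
    slope_mtbi: float
    hs_afd_deficit: float
    phase: str


PRESETS: dict[str, Preset] = {
    "subacute_chronic": Preset(0.041, 0.029, 0.0, "subacute"),
    "acute": Preset(0.041, 0.043, 0.0, "acute"),
    "null": Preset(0.041, 0.041, 0.0, "chronic"),
    "hs_deficit": Preset(0.041, 0.041, 0.02, "acute"),
}


@dataclass
class GroundTruthSpec:
    """Ground truth shared by the MRE and AFD arms of a synthetic study."""

    grid: VoxelGrid
    brain_mask: np.ndarray
    true_hs_region: np.ndarray
    baseline: float
    background: np.ndarray  # smooth zero-mean background (strain units)
    blob_field: np.ndarray  # planted elevation (strain units)
    afd_intercept: float = 0.5
    slope_control: float = 0.041
    slope_mtbi: float = 0.041
    random_intercept_sd: float = 0.03
    regional_noise_sd: float = 0.02
    voxel_noise_sd: float = 0.05
    subject_oss_noise_sd: float = 0.2
    modulus_params: ModulusParams = field(default_factory=ModulusParams)
    seed: int = 0

    def __post_init__(self) -> None:
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        self.true_hs_region = np.asarray(self.true_hs_region, dtype=bool)
        if np.any(self.true_hs_region & ~self.brain_mask):
            raise ValueError("true_hs_region must lie inside the brain mask")
        for name in ("random_intercept_sd", "regional_noise_sd", "voxel_noise_sd",
                     "subject_oss_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def normative_oss_mean(self) -> np.ndarray:
        """Noise-free normative strain field (baseline + background + blobs)."""
        return self.baseline + self.background + self.blob_field

    @property
    def normative_z(self) -> np.ndarray:
        """Population z-score of the normative field across in-mask voxels."""
        out = np.zeros(self.grid.shape)
        inside = self.normative_oss_mean[self.brain_mask]
        out[self.brain_mask] = (inside - inside.mean()) / inside.std(ddof=1)
        return out

    def with_preset(self, preset: str) -> "GroundTruthSpec":
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        p = PRESETS[preset]
        return replace(self, slope_control=p.slope_control, slope_mtbi=p.slope_mtbi)


@dataclass
class MRECohort:
    tensor_fields: list[StrainTensorField]
    modulus_fields: list[ComplexModulusField]
    oss_maps: list[ScalarMap]
    table: pd.DataFrame
    actuation: str


@dataclass
class AFDCohort:
    afd_maps: list[ScalarMap]
    table: pd.DataFrame
    preset: str


def ellipsoid_mask(grid: VoxelGrid, axes_fraction: float = 0.44) -> np.ndarray:
    """Centered ellipsoidal stand-in for a brain mask."""
    idx = np.indices(grid.shape, dtype=float)
    out = np.zeros(grid.shape, dtype=bool)
    r2 = np.zeros(grid.shape)
    for ax in range(3):
        c = (grid.shape[ax] - 1) / 2.0
        a = axes_fraction * grid.shape[ax]
        r2 += ((idx[ax] - c) / a) ** 2
    out[r2 <= 1.0] = True
    return out


def _smooth_field(rng: np.random.Generator, grid: VoxelGrid, smoothness_mm: float,
                  target_sd: float) -> np.ndarray:
    """Zero-mean smooth Gaussian random field with pointwise sd ``target_sd``."""
    noise = rng.standard_normal(grid.shape)
    sigma_vox = [smoothness_mm / v for v in grid.voxel_size]
    sm = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    sd = sm.std()
    if sd == 0 or target_sd == 0:
        return np.zeros(grid.shape)
    return sm * (target_sd / sd)


def make_normative_field(
    grid: VoxelGrid,
    blob_spec: list[tuple[tuple[float, float, float], float, float]],
    background_smoothness: float = 6.0,
    seed: int = 0,
    *,
    background_sd: float = 0.03,
    baseline: float = 1.0,
    brain_mask: np.ndarray | None = None,
    **spec_kwargs,
) -> GroundTruthSpec:
    """Plant vulnerable blobs on a smooth normative strain background.

    Parameters
    ----------
    blob_spec : list of (center, radius_mm, amplitude)
        Spherical elevations; centers in voxel coordinates, radius in mm,
        amplitude in the same (arbitrary) strain units as the baseline.
        Every blob must lie fully inside the brain mask.
    background_smoothness : float
        Gaussian correlation length (mm) of the smooth background.
    background_sd : float
        Pointwise sd of the background (strain units).
    """
    if brain_mask is None:
        brain_mask = ellipsoid_mask(grid)
    rng = np.random.default_rng(seed)
    background = _smooth_field(rng, grid, background_smoothness, background_sd)
    blob_field = np.zeros(grid.shape)
    true_hs = np.zeros(grid.shape, dtype=bool)
    idx = np.indices(grid.shape, dtype=float)
    for center, radius_mm, amplitude in blob_spec:
        if radius_mm <= 0:
            raise ValueError("blob radius must be > 0")
        r2 = np.zeros(grid.shape)
        for ax in range(3):
            r2 += ((idx[ax] - center[ax]) * grid.voxel_size[ax]) ** 2
        ball = r2 <= radius_mm**2
        if not ball.any():
            raise ValueError(f"blob at {center} covers no voxel")
        if np.any(ball & ~brain_mask):
            raise ValueError(f"blob at {center} (r={radius_mm} mm) extends outside the brain mask")
        blob_field[ball] += amplitude
        true_hs |= ball
    return GroundTruthSpec(
        grid=grid,
        brain_mask=brain_mask,
        true_hs_region=true_hs,
        baseline=baseline,
        background=background,
        blob_field=blob_field,
        seed=seed,
        **spec_kwargs,
    )


def default_ground_truth(grid: VoxelGrid | None = None, seed: int = 0,
                         **spec_kwargs) -> GroundTruthSpec:
    """Documented default study conditions.

    Three planted blobs of graded amplitude (1.6, 2.0, 2.4 strain units over
    a unit baseline, radius 12 mm) emulate the handful of anatomically
    distinct structures that concentrate shear strain, over a smooth
    low-amplitude background (sd 0.03, 6 mm correlation length).
    """
    if grid is None:
        grid = VoxelGrid.default()
    nx, ny, nz = grid.shape
    # blob radius scales with the field of view (12 mm on the default grid)
    min_extent = min(s * v for s, v in zip(grid.shape, grid.voxel_size))
    radius = 12.0 * min_extent / 96.0
    # centers spaced > 2 radii apart so the planted regions stay disjoint
    blobs = [
        ((0.50 * nx, 0.46 * ny, 0.42 * nz), radius, 2.0),   # midbrain-like
        ((0.50 * nx, 0.26 * ny, 0.28 * nz), radius, 2.4),   # cerebellum-like
        ((0.24 * nx, 0.50 * ny, 0.34 * nz), radius, 1.6),   # mesial-temporal-like
    ]
    return make_normative_field(grid, blobs, seed=seed, **spec_kwargs)


def _rotation_field(rng: np.random.Generator, grid: VoxelGrid, mask: np.ndarray,
                    smoothness_mm: float = 10.0) -> np.ndarray:
    """Smoothly varying voxelwise rotation matrices, (n_mask, 3, 3)."""
    angles = [
        _smooth_field(rng, grid, smoothness_mm, 1.0)[mask] * np.pi
        for _ in range(3)
    ]
    a, b, c = angles
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    n = a.size
    rz = np.zeros((n, 3, 3))
    rz[:, 0, 0], rz[:, 0, 1] = ca, -sa
    rz[:, 1, 0], rz[:, 1, 1] = sa, ca
    rz[:, 2, 2] = 1.0
    ry = np.zeros((n, 3, 3))
    ry[:, 0, 0], ry[:, 0, 2] = cb, sb
    ry[:, 2, 0], ry[:, 2, 2] = -sb, cb
    ry[:, 1, 1] = 1.0
    rx = np.zeros((n, 3, 3))
    rx[:, 1, 1], rx[:, 1, 2] = cc, -sc
    rx[:, 2, 1], rx[:, 2, 2] = sc, cc
    rx[:, 0, 0] = 1.0
    return np.einsum("nij,njk,nkl->nil", rz, ry, rx)


def _alternating_sex(n: int) -> list[str]:
    return ["F" if i % 2 == 0 else "M" for i in range(n)]


def simulate_mre_cohort(
    spec: GroundTruthSpec,
    n_subjects: int,
    actuation: str = "occipital",
    seed: int = 0,
) -> MRECohort:
    """Per-subject strain-tensor and modulus fields with planted structure.

    Each subject's octahedral shear strain equals the normative field plus
    Gaussian noise (sd ``subject_oss_noise_sd``); the tensor field is built
    by scaling a fixed deviatoric template to that OSS and applying a smooth
    voxelwise rotation, so eigen-analysis downstream recovers the planted
    map exactly. Lateral actuation perturbs the smooth background pattern
    (redrawn from the actuation-specific stream) but not the planted blobs.
    """
    if n_subjects < 3:
        raise ValueError("need n_subjects >= 3 (downstream t-test needs df >= 2)")
    if actuation not in ("occipital", "lateral"):
        raise ValueError(f"unknown actuation {actuation!r}")
    rng = np.random.default_rng([seed, spec.seed, {"occipital": 0, "lateral": 1}[actuation]])
    grid, mask = spec.grid, spec.brain_mask
    if actuation == "lateral":
        bg_sd = spec.background[mask].std() if spec.background[mask].std() > 0 else 0.0
        background = _smooth_field(rng, grid, 6.0, bg_sd)
        normative = spec.baseline + background + spec.blob_field
    else:
        normative = spec.normative_oss_mean
    mp = spec.modulus_params
    tensor_fields, modulus_fields, oss_maps = [], [], []
    rows = []
    sexes = _alternating_sex(n_subjects)
    for i in range(n_subjects):
        oss = normative.copy()
        if spec.subject_oss_noise_sd > 0:
            oss[mask] += rng.normal(0.0, spec.subject_oss_noise_sd, size=int(mask.sum()))
        np.clip(oss, 1e-6, None, out=oss)
        rot = _rotation_field(rng, grid, mask)
        template = np.diag([1.0, 0.0, -1.0]) / _TEMPLATE_OSS
        tensors = np.einsum("nij,jk,nlk->nil", rot, template, rot)
        tensors *= oss[mask][:, None, None]
        tf = StrainTensorField.from_matrices(grid, tensors, mask)

        contrast = np.clip(
            1.0 + rng.normal(0.0, mp.subject_contrast_sd, size=2), 0.2, None
        )
        storage = np.full(grid.shape, mp.storage_baseline)
        storage[spec.true_hs_region] += mp.storage_hs_increment * contrast[0]
        storage[mask] += rng.normal(0.0, mp.storage_noise_sd, size=int(mask.sum()))
        np.clip(storage, 100.0, None, out=storage)
        damping = np.full(grid.shape, mp.damping_baseline)
        damping[spec.true_hs_region] -= mp.damping_hs_decrement * contrast[1]
        damping[mask] += rng.normal(0.0, mp.damping_noise_sd, size=int(mask.sum()))
        np.clip(damping, 0.01, None, out=damping)
        loss = 2.0 * storage * damping
        mf = ComplexModulusField(grid=grid, storage=storage, loss=loss, mask=mask)

        oss_vol = np.zeros(grid.shape)
        oss_vol[mask] = oss[mask]
        oss_maps.append(ScalarMap(grid=grid, values=oss_vol, mask=mask, kind="oss"))
        tensor_fields.append(tf)
        modulus_fields.append(mf)
        rows.append({
            "subject_id": f"mre-{actuation[:3]}-{i:03d}",
            "group": "control",
            "phase": "none",
            "sex": sexes[i],
            "actuation": actuation,
        })
    return MRECohort(
        tensor_fields=tensor_fields,
        modulus_fields=modulus_fields,
        oss_maps=oss_maps,
        table=pd.DataFrame(rows),
        actuation=actuation,
    )


def _bin_index(z: np.ndarray, width: float) -> np.ndarray:
    """Half-open bin index floor(z / width); the top edge is closed."""
    idx = np.floor(np.asarray(z, dtype=float) / width).astype(int)
    zmax = z.max()
    top = int(np.floor(zmax / width))
    # a max sitting exactly on a bin edge belongs to the bin below (closed top)
    if top * width == zmax and zmax > z.min():
        top -= 1
    return np.minimum(idx, top)


def simulate_afd_cohort(
    spec: GroundTruthSpec,
    preset: str,
    n_control: int,
    n_mtbi: int,
    seed: int = 0,
    bin_width: float = 0.25,
) -> AFDCohort:
    """Per-subject AFD maps generated linearly in the normative strain z-map."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    if n_control < 2 or n_mtbi < 2:
        raise ValueError("need >= 2 subjects per group")
    p = PRESETS[preset]
    spec = spec.with_preset(preset)
    rng = np.random.default_rng([seed, spec.seed, 7])
    grid, mask = spec.grid, spec.brain_mask
    z = spec.normative_z
    zin = z[mask]
    bin_idx = _bin_index(zin, bin_width)
    bin_codes = bin_idx - bin_idx.min()
    n_bins = bin_codes.max() + 1
    hs_in = spec.true_hs_region[mask]
    n_in = int(mask.sum())

    maps, rows = [], []
    groups = ["control"] * n_control + ["mtbi"] * n_mtbi
    sexes = _alternating_sex(n_control) + _alternating_sex(n_mtbi)
    counters = {"control": 0, "mtbi": 0}
    for group, sex in zip(groups, sexes):
        slope = spec.slope_control if group == "control" else spec.slope_mtbi
        vals = spec.afd_intercept + slope * zin
        vals = vals + rng.normal(0.0, spec.random_intercept_sd)
        if spec.regional_noise_sd > 0:
            eta = rng.normal(0.0, spec.regional_noise_sd, size=n_bins)
            vals = vals + eta[bin_codes]
        if spec.voxel_noise_sd > 0:
            vals = vals + rng.normal(0.0, spec.voxel_noise_sd, size=n_in)
        if group == "mtbi" and p.hs_afd_deficit != 0.0:
            vals = vals - p.hs_afd_deficit * hs_in
        vol = np.zeros(grid.shape)
        vol[mask] = vals
        maps.append(ScalarMap(grid=grid, values=vol, mask=mask, kind="afd"))
        i = counters[group]
        counters[group] += 1
        rows.append({
            "subject_id": f"{group}-{i:03d}",
            "group": group,
            "phase": p.phase,
            "sex": sex,
        })
    return AFDCohort(afd_maps=maps, table=pd.DataFrame(rows), preset=preset)


def simulate_binned_afd(
    spec: GroundTruthSpec,
    preset: str,
    n_control: int,
    n_mtbi: int,
    seed: int = 0,
    bin_width: float = 0.25,
    min_voxels_per_bin: int = 10,
) -> pd.DataFrame:
    """Subject-by-bin AFD table drawn directly from the generative model.

    Statistically identical to running :func:`simulate_afd_cohort` followed
    by per-bin averaging (bin-mean voxel noise has sd voxel_noise_sd /
    sqrt(n_voxels)), but orders of magnitude faster; used for large
    calibration suites.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    if n_control < 2 or n_mtbi < 2:
        raise ValueError("need >= 2 subjects per group")
    p = PRESETS[preset]
    spec = spec.with_preset(preset)
    rng = np.random.default_rng([seed, spec.seed, 7])
    mask = spec.brain_mask
    zin = spec.normative_z[mask]
    bin_idx = _bin_index(zin, bin_width)
    codes = bin_idx - bin_idx.min()
    n_bins = codes.max() + 1
    counts = np.bincount(codes, minlength=n_bins)
    zsum = np.bincount(codes, weights=zin, minlength=n_bins)
    hs_frac = np.bincount(codes, weights=spec.true_hs_region[mask].astype(float),
                          minlength=n_bins)
    keep = counts >= min_voxels_per_bin
    centers = (np.arange(n_bins) + bin_idx.min() + 0.5) * bin_width
    mean_z = np.divide(zsum, counts, out=np.zeros(n_bins), where=counts > 0)
    hs_share = np.divide(hs_frac, counts, out=np.zeros(n_bins), where=counts > 0)

    rows = []
    groups = ["control"] * n_control + ["mtbi"] * n_mtbi
    sexes = _alternating_sex(n_control) + _alternating_sex(n_mtbi)
    counters = {"control": 0, "mtbi": 0}
    for group, sex in zip(groups, sexes):
        slope = spec.slope_control if group == "control" else spec.slope_mtbi
        u = rng.normal(0.0, spec.random_intercept_sd)
        eta = rng.normal(0.0, spec.regional_noise_sd, size=n_bins)
        eps = rng.normal(0.0, 1.0, size=n_bins) * (
            spec.voxel_noise_sd / np.sqrt(np.maximum(counts, 1))
        )
        mean_afd = spec.afd_intercept + slope * mean_z + u + eta + eps
        if group == "mtbi" and p.hs_afd_deficit != 0.0:
            mean_afd = mean_afd - p.hs_afd_deficit * hs_share
        i = counters[group]
        counters[group] += 1
        for b in np.nonzero(keep)[0]:
            rows.append({
                "subject_id": f"{group}-{i:03d}",
                "group": group,
                "sex": sex,
                "bin_center": centers[b],
                "mean_afd": mean_afd[b],
                "n_voxels": int(counts[b]),
            })
    return pd.DataFrame(rows)


def simulate_roi_summary(
    spec: GroundTruthSpec,
    preset: str,
    n_control: int,
    n_mtbi: int,
    seed: int = 0,
    bin_width: float = 0.25,
) -> pd.DataFrame:
    """Per-subject HS/LS mean AFD drawn directly from the generative model.

    Region means are exact linear functionals of the voxelwise model (the
    regional noise enters through each region's bin composition, the voxel
    noise through 1/sqrt(n_region)), so this reproduces the distribution of
    ``roi_afd_summary(simulate_afd_cohort(...), true region)`` without
    materializing volumes; used for large calibration and power suites.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    if n_control < 2 or n_mtbi < 2:
        raise ValueError("need >= 2 subjects per group")
    p = PRESETS[preset]
    spec = spec.with_preset(preset)
    rng = np.random.default_rng([seed, spec.seed, 13])
    mask = spec.brain_mask
    zin = spec.normative_z[mask]
    codes = _bin_index(zin, bin_width)
    codes = codes - codes.min()
    n_bins = codes.max() + 1
    hs_in = spec.true_hs_region[mask]
    region_stats = {}
    for name, sel in (("hs", hs_in), ("ls", ~hs_in)):
        w = np.bincount(codes[sel], minlength=n_bins).astype(float)
        n_r = w.sum()
        region_stats[name] = (w / n_r, float(zin[sel].mean()), n_r)

    rows = []
    groups = ["control"] * n_control + ["mtbi"] * n_mtbi
    sexes = _alternating_sex(n_control) + _alternating_sex(n_mtbi)
    counters = {"control": 0, "mtbi": 0}
    for group, sex in zip(groups, sexes):
        slope = spec.slope_control if group == "control" else spec.slope_mtbi
        u = rng.normal(0.0, spec.random_intercept_sd)
        eta = rng.normal(0.0, spec.regional_noise_sd, size=n_bins)
        means = {}
        for name, (w, mean_z, n_r) in region_stats.items():
            m = spec.afd_intercept + slope * mean_z + u + w @ eta
            m += rng.normal(0.0, spec.voxel_noise_sd / np.sqrt(n_r))
            if name == "hs" and group == "mtbi":
                m -= p.hs_afd_deficit
            means[name] = m
        i = counters[group]
        counters[group] += 1
        rows.append({
            "subject_id": f"{group}-{i:03d}",
            "group": group,
            "sex": sex,
            "afd_hs": means["hs"],
            "afd_ls": means["ls"],
            "ratio": means["hs"] / means["ls"],
        })
    return pd.DataFrame(rows)


def make_tissue_labels(spec: GroundTruthSpec, seed: int = 0,
                       gm_fraction: float = 0.6) -> np.ndarray:
    """Random GM(1)/WM(2) parcellation of the brain mask for composition tests."""
    rng = np.random.default_rng([seed, 11])
    labels = np.zeros(spec.grid.shape, dtype=int)
    n = int(spec.brain_mask.sum())
    labels[spec.brain_mask] = np.where(rng.random(n) < gm_fraction, 1, 2)
    return labels
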