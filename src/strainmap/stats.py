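"""Group-level strain-stratified statistics.

The unit of analysis is the subject: each subject's AFD map is averaged
within bins of the normative strain z-map (width 0.25 z by default), and
the resulting subject-by-bin table feeds a random-intercept linear mixed
model

    mean_afd ~ group * oss_bin_center + (1 | subject)

exposed statsmodels-style as :class:`StrainAFDModel` /
:class:`StrainAFDResults`. ROI-level comparisons (2x2 mixed ANOVA on
HS/LS means, directed Welch tests on the AFD_HS/AFD_LS ratio, sex-stratified
variants) operate on per-subject region summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
import statsmodels.formula.api as smf

from .grid import ScalarMap
from .synthetic import _bin_index
from .vulnerability import StrainROIMask

__all__ = [
    "BinScheme",
    "build_bins",
    "subject_bin_means",
    "delta_afd_curve",
    "StrainAFDModel",
    "StrainAFDResults",
    "fit_lme",
    "roi_afd_summary",
    "mixed_anova_2x2",
    "ratio_ttest",
    "stratified_contrast",
]


@dataclass(frozen=True)
class BinScheme:
    """Uniform strain-z bins anchored at integer multiples of the width."""

    width: float
    edges: np.ndarray  # ascending, len n_bins + 1
    centers: np.ndarray

    def __post_init__(self) -> None:
        d = np.diff(self.edges)
        if not np.allclose(d, self.width, atol=1e-12):
            raise ValueError("bin edges must be uniform to 1e-12")


def build_bins(normative: ScalarMap, width: float = 0.25) -> tuple[BinScheme, np.ndarray]:
    """Discretize the normative z-map into uniform bins.

    Edges are anchored at floor(min/width)*width; intervals are half-open
    [edge, edge + width) with a closed top edge for the maximum. Returns the
    scheme plus an assignment volume (-1 outside the mask).
    """
    inside = normative.in_mask
    if inside.size == 0:
        raise ValueError("empty mask")
    idx_in = _bin_index(inside, width)
    lo, hi = idx_in.min(), idx_in.max()
    edges = np.arange(lo, hi + 2) * width
    centers = (np.arange(lo, hi + 1) + 0.5) * width
    assignment = np.full(normative.grid.shape, -1, dtype=int)
    assignment[normative.mask] = idx_in - lo
    return BinScheme(width=width, edges=edges, centers=centers), assignment


def subject_bin_means(
    afd: ScalarMap,
    bins: BinScheme,
    assignment: np.ndarray,
    subject_meta: dict,
    min_voxels_per_bin: int = 10,
) -> pd.DataFrame:
    """Mean AFD per strain bin for one subject.

    Bins with fewer than ``min_voxels_per_bin`` voxels are dropped. Returns
    one row per surviving bin with the subject metadata attached.
    """
    if assignment.shape != afd.grid.shape:
        raise ValueError("bin assignment volume does not match the AFD grid")
    codes = assignment[afd.mask]
    vals = afd.in_mask
    n_bins = bins.centers.size
    counts = np.bincount(codes, minlength=n_bins)
    sums = np.bincount(codes, weights=vals, minlength=n_bins)
    keep = counts >= min_voxels_per_bin
    if not keep.any():
        raise ValueError("no bin survives the minimum-voxel filter")
    rows = []
    for b in np.nonzero(keep)[0]:
        rows.append({
            **subject_meta,
            "bin_center": bins.centers[b],
            "mean_afd": sums[b] / counts[b],
            "n_voxels": int(counts[b]),
        })
    return pd.DataFrame(rows)


def delta_afd_curve(table: pd.DataFrame, confidence: float = 0.95) -> pd.DataFrame:
    """Per-bin group difference in mean AFD (control - mTBI) with a t CI.

    The CI is the pooled-variance two-sample t interval across subjects
    within each bin; bins observed in only one group are omitted with a
    warning.
    """
    rows = []
    for center, sub in table.groupby("bin_center"):
        c = sub.loc[sub["group"] == "control", "mean_afd"].to_numpy()
        m = sub.loc[sub["group"] == "mtbi", "mean_afd"].to_numpy()
        if c.size == 0 or m.size == 0:
            warnings.warn(f"bin {center}: only one group present, omitted")
            continue
        diff = c.mean() - m.mean()
        df = c.size + m.size - 2
        if df > 0:
            sp2 = (
                ((c.size - 1) * c.var(ddof=1) if c.size > 1 else 0.0)
                + ((m.size - 1) * m.var(ddof=1) if m.size > 1 else 0.0)
            ) / df
            se = np.sqrt(sp2 * (1 / c.size + 1 / m.size))
            tcrit = sps.t.ppf(0.5 + confidence / 2, df)
            lo, hi = diff - tcrit * se, diff + tcrit * se
        else:
            lo = hi = np.nan
        rows.append({
            "bin_center": center, "delta_afd": diff,
            "ci_low": lo, "ci_high": hi,
            "n_control": c.size, "n_mtbi": m.size,
        })
    return pd.DataFrame(rows)


@dataclass
class StrainAFDResults:
    """Fitted strain-stratified mixed model.

    Fixed effects use treatment coding (control = 0, mTBI = 1) with the
    strain covariate centered at its grand mean, so ``group`` is the group
    difference at mean strain and ``interaction`` is the mTBI-minus-control
    slope difference. ``slope_control``/``slope_mtbi`` are the per-group
    strain slopes.
    """

    params: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    slope_control: float
    slope_mtbi: float
    random_intercept_var: float
    method: str
    singular: bool
    n_subjects: int
    n_obs: int
    model: "StrainAFDModel" = field(repr=False, default=None)

    @property
    def interaction(self) -> float:
        return float(self.params["interaction"])

    @property
    def slope_attenuation(self) -> float:
        """Control-minus-mTBI slope difference (the printed-convention interaction)."""
        return self.slope_control - self.slope_mtbi

    def summary(self) -> str:
        lines = [
            "Strain-stratified AFD mixed model (random intercept per subject)",
            f"  method: {self.method}   subjects: {self.n_subjects}   obs: {self.n_obs}",
            f"  random-intercept variance: {self.random_intercept_var:.6g}"
            + ("   [singular fit]" if self.singular else ""),
            f"  {'term':<12}{'estimate':>12}{'2.5%':>12}{'97.5%':>12}{'p':>10}",
        ]
        for name in self.params.index:
            lo, hi = self.conf_int.loc[name]
            lines.append(
                f"  {name:<12}{self.params[name]:>12.5f}{lo:>12.5f}{hi:>12.5f}"
                f"{self.pvalues[name]:>10.3g}"
            )
        lines.append(
            f"  slope_control: {self.slope_control:.5f}   slope_mtbi: {self.slope_mtbi:.5f}"
        )
        return "\n".join(lines)


class StrainAFDModel:
    """Random-intercept mixed model of subject-level AFD on strain bins.

    Parameters
    ----------
    table : DataFrame
        Subject-by-bin table with columns ``subject_id``, ``group``
        (control/mtbi), ``bin_center`` and ``mean_afd``.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"subject_id", "group", "bin_center", "mean_afd"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"table is missing columns {sorted(missing)}")
        counts = table.groupby("group")["subject_id"].nunique()
        if set(counts.index) != {"control", "mtbi"} or counts.min() < 2:
            raise ValueError("need >= 2 subjects in each of the control and mtbi groups")
        if table["bin_center"].nunique() < 3:
            raise ValueError("need >= 3 strain bins")
        self.table = table.copy()
        self.table["group_mtbi"] = (self.table["group"] == "mtbi").astype(float)
        self.table["oss_c"] = self.table["bin_center"] - self.table["bin_center"].mean()

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "StrainAFDModel":
        return cls(table)

    def fit(self, reml: bool = True) -> StrainAFDResults:
        """Fit by REML (default) with an ML fallback on convergence trouble."""
        method = "reml" if reml else "ml"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(
                "mean_afd ~ group_mtbi * oss_c", self.table,
                groups=self.table["subject_id"],
            )
            try:
                res = md.fit(reml=reml)
            except Exception:
                res = md.fit(reml=False, method="lbfgs")
                method = "ml"
        rename = {
            "Intercept": "intercept",
            "group_mtbi": "group",
            "oss_c": "oss",
            "group_mtbi:oss_c": "interaction",
        }
        params = res.params.drop("Group Var").rename(rename)
        ci = res.conf_int().drop("Group Var").rename(index=rename)
        ci.columns = ["2.5%", "97.5%"]
        pvals = res.pvalues.drop("Group Var").rename(rename)
        re_var = float(res.cov_re.iloc[0, 0]) if res.cov_re.size else 0.0
        singular = re_var <= 1e-10
        if singular:
            warnings.warn("singular fit: random-intercept variance is ~0")
        return StrainAFDResults(
            params=params,
            conf_int=ci,
            pvalues=pvals,
            slope_control=float(params["oss"]),
            slope_mtbi=float(params["oss"] + params["interaction"]),
            random_intercept_var=re_var,
            method=method,
            singular=singular,
            n_subjects=self.table["subject_id"].nunique(),
            n_obs=len(self.table),
            model=self,
        )


def fit_lme(table: pd.DataFrame, reml: bool = True) -> StrainAFDResults:
    """Functional wrapper around :class:`StrainAFDModel`."""
    return StrainAFDModel.from_table(table).fit(reml=reml)


def roi_afd_summary(
    afd_maps: list[ScalarMap],
    roi: StrainROIMask,
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """Per-subject HS mean, LS mean and AFD_HS/AFD_LS ratio.

    Subjects with non-positive LS mean are excluded from ratio analyses
    (``ratio`` set to NaN) with a warning.
    """
    if not roi.hs.any() or not roi.ls.any():
        raise ValueError("HS or LS region is empty")
    if len(afd_maps) != len(meta):
        raise ValueError("one metadata row per AFD map required")
    rows = []
    for smap, (_, m) in zip(afd_maps, meta.iterrows()):
        hs_mean = float(smap.values[roi.hs].mean())
        ls_mean = float(smap.values[roi.ls].mean())
        ratio = hs_mean / ls_mean if ls_mean > 0 else np.nan
        if ls_mean <= 0:
            warnings.warn(f"subject {m.get('subject_id')}: LS mean <= 0, ratio dropped")
        rows.append({
            "subject_id": m.get("subject_id"),
            "group": m.get("group"),
            "sex": m.get("sex"),
            "afd_hs": hs_mean,
            "afd_ls": ls_mean,
            "ratio": ratio,
        })
    return pd.DataFrame(rows)


def mixed_anova_2x2(summary: pd.DataFrame) -> pd.DataFrame:
    """2 (group, between) x 2 (region HS/LS, within) mixed-design ANOVA on AFD.

    Returns a table with F and p for the group, region and interaction terms.
    """
    counts = summary.groupby("group")["subject_id"].nunique()
    if counts.min() < 2 or counts.size < 2:
        raise ValueError("need >= 2 subjects per group")
    long = summary.melt(
        id_vars=["subject_id", "group"],
        value_vars=["afd_hs", "afd_ls"],
        var_name="region",
        value_name="afd",
    )
    long["region"] = long["region"].map({"afd_hs": "HS", "afd_ls": "LS"})
    if long.groupby(["group", "region"])["afd"].var().fillna(0).sum() == 0:
        raise ValueError("degenerate (zero-variance) AFD data")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(
            data=long, dv="afd", within="region", between="group", subject="subject_id"
        )
    pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
    out = aov.set_index("Source").loc[["group", "region", "Interaction"], ["F", pcol]]
    out.index = ["group", "region", "interaction"]
    return out.rename(columns={pcol: "p"})


def ratio_ttest(
    summary: pd.DataFrame,
    direction: str = "mtbi_lower",
    equal_var: bool = False,
) -> tuple[float, float]:
    """Directed two-sample t-test on the AFD_HS/AFD_LS ratio (Welch default).

    ``direction="mtbi_lower"`` tests H1: mean mTBI ratio < mean control
    ratio; ``"mtbi_higher"`` tests the opposite tail. Returns (t, one-sided
    p) with t computed as control minus mTBI.
    """
    if direction not in ("mtbi_lower", "mtbi_higher"):
        raise ValueError("direction must be 'mtbi_lower' or 'mtbi_higher'")
    c = summary.loc[summary["group"] == "control", "ratio"].dropna().to_numpy()
    m = summary.loc[summary["group"] == "mtbi", "ratio"].dropna().to_numpy()
    if c.size < 2 or m.size < 2:
        raise ValueError("need >= 2 subjects with valid ratios per group")
    if c.var(ddof=1) == 0 and m.var(ddof=1) == 0:
        raise ValueError("degenerate variance in both groups")
    alternative = "greater" if direction == "mtbi_lower" else "less"
    res = sps.ttest_ind(c, m, equal_var=equal_var, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def stratified_contrast(
    summary: pd.DataFrame,
    stratify_by: str = "sex",
    direction: str = "mtbi_lower",
    equal_var: bool = False,
) -> dict[str, tuple[float, float]]:
    """Ratio t-test repeated within each stratum (e.g. per sex).

    Strata lacking two valid subjects in either group are skipped with a
    warning; an error is raised if no stratum is testable.
    """
    out: dict[str, tuple[float, float]] = {}
    for level, sub in summary.groupby(stratify_by):
        counts = sub.dropna(subset=["ratio"]).groupby("group")["subject_id"].nunique()
        if counts.reindex(["control", "mtbi"]).fillna(0).min() < 2:
            warnings.warn(f"stratum {level!r} skipped: too few subjects per group")
            continue
        out[str(level)] = ratio_ttest(sub, direction=direction, equal_var=equal_var)
    if not out:
        raise ValueError("no stratum has >= 2 subjects per group")
    return out
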