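"""Binning, group curves, the mixed model, ANOVA and ratio tests."""

import numpy as np
import pandas as pd
import pytest

from strainmap.grid import ScalarMap, VoxelGrid
from strainmap.stats import (
    StrainAFDModel,
    build_bins,
    delta_afd_curve,
    fit_lme,
    mixed_anova_2x2,
    ratio_ttest,
    roi_afd_summary,
    stratified_contrast,
    subject_bin_means,
)
from strainmap.vulnerability import StrainROIMask

from oracles import mixed_anova_ss_oracle


def scalar_from(values, kind="oss_z"):
    v = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    grid = VoxelGrid(shape=v.shape, voxel_size=(1, 1, 1), affine=None)
    return ScalarMap(grid=grid, values=v, mask=np.ones(grid.shape, bool), kind=kind)


class TestBins:
    def test_halfopen_assignment(self):
        """0.10 with width 0.25 lands in [0, 0.25), center 0.125."""
        norm = scalar_from([0.10, 0.30, 0.74])
        scheme, assignment = build_bins(norm, width=0.25)
        assert scheme.centers[assignment[0, 0, 0]] == pytest.approx(0.125)
        assert scheme.centers[assignment[1, 0, 0]] == pytest.approx(0.375)
        assert scheme.centers[assignment[2, 0, 0]] == pytest.approx(0.625)

    def test_top_edge_closed(self):
        """A maximum sitting exactly on a bin edge joins the bin below."""
        norm = scalar_from([0.10, 0.50])
        scheme, assignment = build_bins(norm, width=0.25)
        assert assignment[1, 0, 0] == assignment.max()
        assert scheme.centers[assignment[1, 0, 0]] == pytest.approx(0.375)

    def test_bin_count_for_typical_range(self):
        """A [-1, 4] range with width 0.25 yields 20 bins."""
        vals = np.linspace(-1.0, 4.0, 400)
        scheme, _ = build_bins(scalar_from(vals), width=0.25)
        assert scheme.centers.size == 20
        assert np.allclose(np.diff(scheme.edges), 0.25)

    def test_empty_mask_rejected(self):
        grid = VoxelGrid(shape=(3, 1, 1), voxel_size=(1, 1, 1), affine=None)
        empty = ScalarMap(grid=grid, values=np.zeros(grid.shape),
                          mask=np.zeros(grid.shape, bool), kind="oss_z")
        with pytest.raises(ValueError, match="empty mask"):
            build_bins(empty)


class TestSubjectBinMeans:
    def test_means_and_minimum_filter(self):
        norm = scalar_from([0.1] * 12 + [0.3] * 3)
        scheme, assignment = build_bins(norm, width=0.25)
        afd = scalar_from([0.4, 0.6] * 6 + [1.0, 1.0, 1.0], kind="afd")
        rows = subject_bin_means(afd, scheme, assignment,
                                 {"subject_id": "s0", "group": "control"})
        assert len(rows) == 1  # 3-voxel bin dropped by the min-10 filter
        assert rows.iloc[0]["mean_afd"] == pytest.approx(0.5)
        assert rows.iloc[0]["n_voxels"] == 12
        with pytest.raises(ValueError, match="no bin survives"):
            subject_bin_means(afd, scheme, assignment, {}, min_voxels_per_bin=99)

    def test_uniform_afd_constant_bins(self):
        rng = np.random.default_rng(0)
        norm = scalar_from(rng.normal(size=60))
        scheme, assignment = build_bins(norm)
        afd = scalar_from(np.full(60, 0.77), kind="afd")
        rows = subject_bin_means(afd, scheme, assignment, {"subject_id": "s"},
                                 min_voxels_per_bin=1)
        np.testing.assert_allclose(rows["mean_afd"], 0.77)


class TestDeltaCurve:
    def _table(self, per_bin):
        rows = []
        for center, (ctrl, mtbi) in per_bin.items():
            for i, v in enumerate(ctrl):
                rows.append({"subject_id": f"c{i}", "group": "control",
                             "bin_center": center, "mean_afd": v})
            for i, v in enumerate(mtbi):
                rows.append({"subject_id": f"m{i}", "group": "mtbi",
                             "bin_center": center, "mean_afd": v})
        return pd.DataFrame(rows)

    def test_hand_two_sample_interval(self):
        """control {0.5,0.6} vs mTBI {0.4,0.5}: diff 0.1, pooled t CI, df 2."""
        curve = delta_afd_curve(self._table({0.125: ([0.5, 0.6], [0.4, 0.5])}))
        row = curve.iloc[0]
        assert row["delta_afd"] == pytest.approx(0.1)
        sp = np.sqrt((0.005 + 0.005) / 2)
        se = sp * np.sqrt(0.5 + 0.5)
        from scipy.stats import t as tdist

        half = tdist.ppf(0.975, 2) * se
        assert row["ci_low"] == pytest.approx(0.1 - half)
        assert row["ci_high"] == pytest.approx(0.1 + half)

    def test_identical_groups_and_shift(self):
        curve = delta_afd_curve(self._table({
            0.125: ([0.5, 0.6, 0.7], [0.5, 0.6, 0.7]),
            0.375: ([0.5, 0.6, 0.7], [0.4, 0.5, 0.6]),
        }))
        first = curve[curve.bin_center == 0.125].iloc[0]
        assert first["delta_afd"] == pytest.approx(0.0)
        assert first["ci_low"] < 0 < first["ci_high"]
        second = curve[curve.bin_center == 0.375].iloc[0]
        assert second["delta_afd"] == pytest.approx(0.1)

    def test_single_group_bin_omitted(self):
        table = self._table({0.125: ([0.5, 0.6], [0.4, 0.5])})
        extra = pd.DataFrame([{"subject_id": "c9", "group": "control",
                               "bin_center": 0.875, "mean_afd": 0.9}])
        with pytest.warns(UserWarning, match="omitted"):
            curve = delta_afd_curve(pd.concat([table, extra], ignore_index=True))
        assert 0.875 not in set(curve["bin_center"])


def exact_line_table(slope_control=0.03, slope_mtbi=0.02, intercept=0.5,
                     centers=(0.0, 1.0, 2.0, 3.0), n_per_group=3):
    rows = []
    for g, slope in (("control", slope_control), ("mtbi", slope_mtbi)):
        for i in range(n_per_group):
            for c in centers:
                rows.append({"subject_id": f"{g}-{i}", "group": g,
                             "bin_center": c, "mean_afd": intercept + slope * c})
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_exact_generative_lines_recovered(self):
        """Zero noise: slopes exact to 1e-8, interaction = slope difference."""
        res = fit_lme(exact_line_table())
        assert res.slope_control == pytest.approx(0.03, abs=1e-8)
        assert res.slope_mtbi == pytest.approx(0.02, abs=1e-8)
        assert res.interaction == pytest.approx(-0.01, abs=1e-8)
        assert res.slope_attenuation == pytest.approx(0.01, abs=1e-8)
        assert res.singular  # no between-subject variance to estimate

    def test_balanced_no_random_variance_matches_ols(self):
        """With zero between-subject variance the fixed effects are the OLS fit."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(4)
        table = exact_line_table(n_per_group=2)
        table["mean_afd"] += rng.normal(0, 0.01, size=len(table))
        res = fit_lme(table)
        df = table.copy()
        df["g"] = (df["group"] == "mtbi").astype(float)
        df["zc"] = df["bin_center"] - df["bin_center"].mean()
        ols = smf.ols("mean_afd ~ g * zc", df).fit()
        assert res.params["oss"] == pytest.approx(ols.params["zc"], abs=1e-6)
        assert res.params["interaction"] == pytest.approx(ols.params["g:zc"], abs=1e-6)

    def test_summary_mentions_key_terms(self):
        text = fit_lme(exact_line_table()).summary()
        for token in ("interaction", "slope_control", "slope_mtbi", "subjects"):
            assert token in text

    def test_input_validation(self):
        table = exact_line_table()
        with pytest.raises(ValueError, match="missing columns"):
            StrainAFDModel(table.drop(columns=["mean_afd"]))
        with pytest.raises(ValueError, match=">= 2 subjects"):
            StrainAFDModel(table[table.subject_id != "mtbi-0"]
                           [lambda d: (d.group == "control") | (d.subject_id == "mtbi-1")])
        few_bins = table[table.bin_center < 2.0]
        with pytest.raises(ValueError, match=">= 3"):
            StrainAFDModel(few_bins[few_bins.bin_center < 1.0])

    def test_delta_curve_consistent_with_lme(self, truth_tiny):
        """Regression of the per-bin difference curve on centers equals the
        fitted control-minus-mTBI slope difference (same data, two routes)."""
        from strainmap.experiments import binned_table_from_cohort
        from strainmap.synthetic import simulate_afd_cohort

        cohort = simulate_afd_cohort(truth_tiny, "subacute_chronic", 12, 12, seed=6)
        table = binned_table_from_cohort(truth_tiny, cohort)
        res = fit_lme(table)
        curve = delta_afd_curve(table)
        slope = np.polyfit(curve["bin_center"], curve["delta_afd"], 1)[0]
        assert slope == pytest.approx(res.slope_attenuation, abs=3e-3)


def roi_summary_from(hs_ls_by_group):
    rows = []
    for group, pairs in hs_ls_by_group.items():
        for i, (hs, ls) in enumerate(pairs):
            rows.append({"subject_id": f"{group}-{i}", "group": group,
                         "sex": "F" if i % 2 == 0 else "M",
                         "afd_hs": hs, "afd_ls": ls, "ratio": hs / ls})
    return pd.DataFrame(rows)


class TestRoiSummary:
    def _roi(self):
        grid = VoxelGrid(shape=(4, 1, 1), voxel_size=(1, 1, 1), affine=None)
        brain = np.ones(grid.shape, bool)
        hs = np.zeros(grid.shape, bool)
        hs[:2] = True
        return grid, StrainROIMask(grid=grid, hs=hs, ls=brain & ~hs, brain_mask=brain)

    def test_ratio_identities(self):
        grid, roi = self._roi()
        meta = pd.DataFrame([{"subject_id": "a", "group": "control", "sex": "F"}])
        uniform = [ScalarMap(grid=grid, values=np.full(grid.shape, 0.5),
                             mask=roi.brain_mask, kind="afd")]
        assert roi_afd_summary(uniform, roi, meta)["ratio"].iloc[0] == pytest.approx(1.0)
        vals = np.zeros(grid.shape)
        vals[roi.hs] = 0.45
        vals[roi.ls] = 0.50
        smap = ScalarMap(grid=grid, values=vals, mask=roi.brain_mask, kind="afd")
        out = roi_afd_summary([smap], roi, meta)
        assert out["ratio"].iloc[0] == pytest.approx(0.9)
        scaled = ScalarMap(grid=grid, values=3.0 * vals, mask=roi.brain_mask, kind="afd")
        out2 = roi_afd_summary([scaled], roi, meta)
        assert out2["ratio"].iloc[0] == pytest.approx(0.9)  # scale invariant


class TestMixedAnova:
    def test_matches_textbook_ss_decomposition(self):
        """Balanced 2-per-cell toy: F ratios equal the hand SS decomposition."""
        summary = roi_summary_from({
            "control": [(0.52, 0.50), (0.55, 0.51)],
            "mtbi": [(0.44, 0.50), (0.46, 0.52)],
        })
        aov = mixed_anova_2x2(summary)
        f_group, f_region, f_inter = mixed_anova_ss_oracle(
            summary["afd_hs"], summary["afd_ls"],
            (summary["group"] == "mtbi").astype(int),
        )
        assert aov.loc["group", "F"] == pytest.approx(f_group, rel=1e-8)
        assert aov.loc["region", "F"] == pytest.approx(f_region, rel=1e-8)
        assert aov.loc["interaction", "F"] == pytest.approx(f_inter, rel=1e-8)

    def test_additive_shifts_give_no_interaction(self):
        """Pure group and region main effects leave the interaction at ~0."""
        rng = np.random.default_rng(1)
        base = rng.normal(0.5, 0.02, size=8)
        eps = rng.normal(0, 1e-3, size=(8, 2))  # keeps the error stratum non-degenerate
        summary = roi_summary_from({
            "control": [(b + 0.05 + e[0], b + e[1]) for b, e in zip(base[:4], eps[:4])],
            "mtbi": [(b + 0.02 + e[0], b - 0.03 + e[1]) for b, e in zip(base[4:], eps[4:])],
        })
        aov = mixed_anova_2x2(summary)
        f_group, f_region, f_inter = mixed_anova_ss_oracle(
            summary["afd_hs"], summary["afd_ls"],
            (summary["group"] == "mtbi").astype(int),
        )
        assert aov.loc["interaction", "F"] == pytest.approx(f_inter, rel=1e-8)
        assert aov.loc["interaction", "F"] < 4.0  # no planted interaction

    def test_degenerate_data_rejected(self):
        flat = roi_summary_from({"control": [(0.5, 0.5)] * 3, "mtbi": [(0.5, 0.5)] * 3})
        with pytest.raises(ValueError, match="degenerate"):
            mixed_anova_2x2(flat)


class TestRatioTests:
    def test_hand_welch(self):
        """control {1.00,1.02} vs mTBI {0.90,0.92}: Welch t = 0.1/sqrt(2e-4/2+2e-4/2)."""
        summary = roi_summary_from({
            "control": [(1.00, 1.0), (1.02, 1.0)],
            "mtbi": [(0.90, 1.0), (0.92, 1.0)],
        })
        t, p = ratio_ttest(summary)
        se = np.sqrt(2e-4 / 2 + 2e-4 / 2)
        assert t == pytest.approx(0.1 / se, rel=1e-10)
        assert 0 < p < 0.05

    def test_identical_groups_and_direction_flip(self):
        summary = roi_summary_from({
            "control": [(0.9, 1.0), (1.1, 1.0)],
            "mtbi": [(0.9, 1.0), (1.1, 1.0)],
        })
        t, p = ratio_ttest(summary)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(0.5)
        t2, p2 = ratio_ttest(summary, direction="mtbi_higher")
        assert p2 == pytest.approx(1.0 - p)

    def test_stratified(self):
        summary = roi_summary_from({
            "control": [(0.9, 1.0)] * 4 + [(1.0, 1.0)] * 4,
            "mtbi": [(0.8, 1.0)] * 4 + [(0.9, 1.0)] * 4,
        })
        # make values vary so the t-test is defined
        rng = np.random.default_rng(0)
        summary["ratio"] += rng.normal(0, 0.01, len(summary))
        res = stratified_contrast(summary, stratify_by="sex")
        assert set(res) == {"F", "M"}
        single_sex = summary[summary.sex == "F"]
        res_f = stratified_contrast(single_sex, stratify_by="sex")
        t_direct, p_direct = ratio_ttest(single_sex)
        assert res_f["F"][0] == pytest.approx(t_direct)
        with pytest.warns(UserWarning, match="skipped"):
            small = summary[(summary.sex == "F")
                            | ((summary.sex == "M") & (summary.group == "control"))]
            out = stratified_contrast(small, stratify_by="sex")
        assert "M" not in out
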