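"""Independent brute-force oracles used to cross-check the implementation.

Everything here follows definitions literally (sorting, enumeration,
textbook sums of squares, dense-grid deconvolution) and shares no code with
the package paths it checks.
"""

import numpy as np
from scipy.optimize import nnls


def bh_stepup_oracle(p):
    """Benjamini-Hochberg step-up by the literal definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def joint_threshold_oracle(t, q, brain_mask, q_thr, t_thr):
    """Voxel-by-voxel evaluation of the joint HS rule."""
    hs = np.zeros_like(brain_mask, dtype=bool)
    it = np.ndindex(brain_mask.shape)
    for idx in it:
        if brain_mask[idx] and q[idx] < q_thr and t[idx] >= t_thr:
            hs[idx] = True
    return hs


def oss_closed_form(eigvals):
    e1, e2, e3 = sorted(eigvals, reverse=True)
    return (2.0 / 3.0) * np.sqrt((e1 - e2) ** 2 + (e2 - e3) ** 2 + (e3 - e1) ** 2)


def mixed_anova_ss_oracle(hs, ls, groups):
    """Textbook 2 (between) x 2 (within) mixed-ANOVA F ratios.

    hs/ls: per-subject region means; groups: 0/1 labels. Returns
    (F_group, F_region, F_interaction) from the classical sums-of-squares
    decomposition with subjects nested in groups.
    """
    hs = np.asarray(hs, float)
    ls = np.asarray(ls, float)
    groups = np.asarray(groups)
    y = np.stack([hs, ls], axis=1)  # subjects x regions
    n, r = y.shape
    grand = y.mean()
    levels = np.unique(groups)
    # between-subjects partition
    ss_group = sum(
        (y[groups == g].size) * (y[groups == g].mean() - grand) ** 2 for g in levels
    )
    subj_means = y.mean(axis=1)
    ss_subj_within = sum(
        r * (subj_means[i] - y[groups == groups[i]].mean()) ** 2 for i in range(n)
    )
    df_group = levels.size - 1
    df_subj = n - levels.size
    # within-subjects partition
    region_means = y.mean(axis=0)
    ss_region = n * ((region_means - grand) ** 2).sum()
    cell_means = np.array([[y[groups == g, j].mean() for j in range(r)] for g in levels])
    ss_cells = sum(
        (groups == g).sum() * (cell_means[gi, j] - grand) ** 2
        for gi, g in enumerate(levels)
        for j in range(r)
    )
    ss_inter = ss_cells - ss_group - ss_region
    ss_total = ((y - grand) ** 2).sum()
    ss_err_within = ss_total - ss_group - ss_subj_within - ss_region - ss_inter
    df_region = r - 1
    df_inter = df_group * df_region
    df_err = df_subj * df_region
    f_group = (ss_group / df_group) / (ss_subj_within / df_subj)
    f_region = (ss_region / df_region) / (ss_err_within / df_err)
    f_inter = (ss_inter / df_inter) / (ss_err_within / df_err)
    return f_group, f_region, f_inter


def csd_nnls_oracle(signals, bvals, bvecs, response_axial, response_radial,
                    iso_diffusivity=3.0e-3, n_grid=724):
    """Dense-grid non-negative deconvolution, an independent route to AFD.

    Models each voxel's signal as a non-negative combination of single-fiber
    signal profiles centered on a dense direction grid plus an isotropic
    column, solved by NNLS; 'AFD' is the summed fiber weight divided by
    sqrt(4*pi) (the l=0 coefficient of a sum of unit delta functions).
    """
    from strainmap.sh import fibonacci_sphere

    grid_dirs = fibonacci_sphere(n_grid)
    grid_dirs = grid_dirs[grid_dirs[:, 2] >= 0]  # antipodal symmetry
    sel = bvals > 50
    g = bvecs[sel]
    b = bvals[sel]
    cols = []
    for u in grid_dirs:
        d = response_radial * np.eye(3) + (response_axial - response_radial) * np.outer(u, u)
        cols.append(np.exp(-b * np.einsum("vi,ij,vj->v", g, d, g)))
    a = np.column_stack(cols + [np.exp(-b * iso_diffusivity)])
    afd = np.empty(signals.shape[0])
    for i, s in enumerate(signals):
        w, _ = nnls(a, s[sel])
        afd[i] = w[:-1].sum() / np.sqrt(4.0 * np.pi)
    return afd
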