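"""Figures: the strain-binned group-difference curve and ROI ratio strip plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_delta_afd_curve", "plot_ratio_strip"]


def plot_delta_afd_curve(curve: pd.DataFrame, path=None, title: str | None = None):
    """Mean control-minus-mTBI AFD per strain bin with its 95% CI."""
    fig, ax = plt.subplots(figsize=(6, 4))
    yerr = np.vstack([
        curve["delta_afd"] - curve["ci_low"],
        curve["ci_high"] - curve["delta_afd"],
    ])
    ax.errorbar(curve["bin_center"], curve["delta_afd"], yerr=yerr,
                fmt="o-", capsize=3, color="#1f4e79")
    ax.axhline(0.0, color="0.6", lw=0.8, ls="--")
    ax.set_xlabel("normative OSS bin center (z)")
    ax.set_ylabel(r"$\Delta$AFD (control $-$ mTBI)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_ratio_strip(summary: pd.DataFrame, path=None, title: str | None = None):
    """Per-subject AFD_HS/AFD_LS ratios by group."""
    fig, ax = plt.subplots(figsize=(4, 4))
    rng = np.random.default_rng(0)
    for i, group in enumerate(["control", "mtbi"]):
        vals = summary.loc[summary["group"] == group, "ratio"].dropna()
        x = i + rng.uniform(-0.08, 0.08, size=len(vals))
        ax.plot(x, vals, "o", alpha=0.7,
                color="#1f4e79" if group == "control" else "#b0413e")
        ax.hlines(vals.mean(), i - 0.2, i + 0.2, color="k", lw=1.5)
    ax.set_xticks([0, 1], ["control", "mTBI"])
    ax.set_ylabel(r"AFD$_{HS}$ / AFD$_{LS}$")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig
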