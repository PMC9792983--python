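"""Figure rendering for fitted state effects and stride clouds."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats_models import StateEffectEstimate


def state_means_barplot(estimate: StateEffectEstimate, path) -> None:
    """Bar plot of least-square means with 95% confidence intervals."""
    fig, ax = plt.subplots(figsize=(4, 3))
    labels = [lv.level for lv in estimate.levels]
    means = [lv.mean for lv in estimate.levels]
    err_lo = [lv.mean - lv.ci_low for lv in estimate.levels]
    err_hi = [lv.ci_high - lv.mean for lv in estimate.levels]
    ax.bar(labels, means, yerr=[err_lo, err_hi], capsize=4, color="#4878a8")
    ax.set_ylabel(estimate.parameter)
    ax.set_title(f"{estimate.parameter} by {estimate.factor} (LS means, 95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def swing_scatter(table: pd.DataFrame, path, group_col: str = "state") -> None:
    """Swing time vs swing length scatter with 2-sigma ellipses per group,
    split by front/hind limb grouping."""
    swing_t = table[table["parameter"] == "swing_time"]
    swing_l = table[table["parameter"] == "swing_length"]
    key = ["pass", "limb", "stride_index"]
    merged = swing_t.merge(swing_l, on=key + [group_col, "limb_group"], suffixes=("_t", "_l"))
    groups = sorted(merged[group_col].unique())
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5), sharex=True, sharey=True)
    for ax, limb_group in zip(axes, ("front", "hind")):
        sub_g = merged[merged["limb_group"] == limb_group]
        for i, g in enumerate(groups):
            sub = sub_g[sub_g[group_col] == g]
            if sub.empty:
                continue
            x, y = sub["value_t"].to_numpy(), sub["value_l"].to_numpy()
            color = plt.cm.viridis(i / max(len(groups) - 1, 1))
            ax.scatter(x, y, s=6, alpha=0.4, color=color, label=str(g))
            if len(sub) > 2:
                _ellipse(ax, x, y, color)
        ax.set_title(f"{limb_group} limbs")
        ax.set_xlabel("swing time (s)")
    axes[0].set_ylabel("swing length (m)")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _ellipse(ax, x: np.ndarray, y: np.ndarray, color) -> None:
    cov = np.cov(x, y)
    vals, vecs = np.linalg.eigh(cov)
    theta = np.linspace(0, 2 * np.pi, 100)
    circle = np.stack([np.cos(theta), np.sin(theta)])
    shape = vecs @ np.diag(2 * np.sqrt(np.maximum(vals, 0))) @ circle
    ax.plot(x.mean() + shape[0], y.mean() + shape[1], color=color, lw=1)
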