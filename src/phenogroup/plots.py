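"""Report figures: group allocation, per-group coefficients, MAE histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .utils import FEATURE_NAMES

__all__ = ["plot_group_allocation", "plot_group_coefficients", "plot_mae_histograms"]


def plot_group_allocation(partition_df: pd.DataFrame, path) -> None:
    """One row per group; markers colored by diagnostic cohort if present."""
    df = partition_df.copy()
    groups = sorted(df["group_id"].unique())
    cohorts = sorted(df["cohort"].dropna().unique()) if "cohort" in df else []
    cmap = plt.get_cmap("tab10")
    colors = {c: cmap(i % 10) for i, c in enumerate(cohorts)}
    fig, ax = plt.subplots(figsize=(7, 0.4 * max(len(groups), 4) + 1.5))
    for row, g in enumerate(groups):
        members = df[df["group_id"] == g]
        for k, (_, m) in enumerate(members.iterrows()):
            c = colors.get(m.get("cohort"), "gray")
            ax.plot(k, row, "o", color=c, markersize=9)
    ax.set_yticks(range(len(groups)), [f"group {g}" for g in groups])
    ax.set_xlabel("individuals in group")
    ax.set_title("Group allocation of individuals")
    if cohorts:
        handles = [plt.Line2D([], [], marker="o", ls="", color=colors[c], label=c) for c in cohorts]
        ax.legend(handles=handles, loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_group_coefficients(summary_df: pd.DataFrame, path, group_ids=None) -> None:
    """Posterior coefficient intervals per feature for selected groups."""
    if group_ids is None:
        sizes = summary_df.groupby("group_id")["size"].first().sort_values(ascending=False)
        group_ids = list(sizes.index[:2])
    fig, axes = plt.subplots(1, len(group_ids), figsize=(5 * len(group_ids), 4), squeeze=False)
    for ax, g in zip(axes[0], group_ids):
        sub = summary_df[summary_df["group_id"] == g].sort_values("feature")
        y = np.arange(len(sub))
        ax.errorbar(
            sub["post_mean"],
            y,
            xerr=[sub["post_mean"] - sub["q2.5"], sub["q97.5"] - sub["post_mean"]],
            fmt="o",
            capsize=3,
        )
        labels = [
            f"{FEATURE_NAMES[int(j)]} (r={r:.2f})" if np.isfinite(r) else FEATURE_NAMES[int(j)]
            for j, r in zip(sub["feature"], sub["pearson_r"])
        ]
        ax.set_yticks(y, labels, fontsize=8)
        ax.axvline(0, color="gray", lw=0.8)
        ax.set_title(f"group {g} (n={int(sub['size'].iloc[0])})")
        ax.set_xlabel("posterior coefficient")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_mae_histograms(results: dict, path) -> None:
    """Stacked per-model histograms of per-participant mean MAE."""
    fig, axes = plt.subplots(len(results), 1, figsize=(7, 2.2 * len(results)), sharex=True, squeeze=False)
    for ax, (name, df) in zip(axes[:, 0], results.items()):
        ax.hist(df["mean_mae"], bins=np.arange(0, df["mean_mae"].max() + 1, 0.5), edgecolor="k")
        ax.set_ylabel("participants")
        ax.set_title(name, fontsize=9)
    axes[-1, 0].set_xlabel("mean absolute error (score points)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
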