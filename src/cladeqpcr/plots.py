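"""Minimal figure helpers: depth box plots and Tm-vs-Cp scatter."""
from __future__ import annotations

from pathlib import Path

import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

DEPTH_COLORS = {"3m": "tab:orange", "DCM": "tab:green", "DCM+40": "tab:blue"}


def plot_depth_boxes(quant: pd.DataFrame, path: str | Path,
                     response: str = "rel_rbcL") -> Path:
    """Box plots of relative expression by depth class, one panel per clade.

    Whiskers span the non-outlier range with the standard 1.5 x IQR rule.
    """
    path = Path(path)
    clades = sorted(quant["clade"].unique())
    fig, axes = plt.subplots(1, len(clades), figsize=(4 * len(clades), 4),
                             squeeze=False)
    for ax, clade in zip(axes[0], clades):
        sub = quant[(quant["clade"] == clade) & quant["included"]]
        depths = [d for d in DEPTH_COLORS if d in set(sub["depth_class"])]
        data = [sub.loc[sub["depth_class"] == d, response].dropna()
                for d in depths]
        box = ax.boxplot(data, labels=depths, whis=1.5, patch_artist=True)
        for patch, d in zip(box["boxes"], depths):
            patch.set_facecolor(DEPTH_COLORS[d])
        ax.set_yscale("log")
        ax.set_title(clade)
        ax.set_ylabel(response)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_tm_vs_cp(profiles: pd.DataFrame, cp_calls: pd.DataFrame,
                  metadata: pd.DataFrame, path: str | Path) -> Path:
    """Major-peak Tm against Cp per primer set, colored by depth class."""
    path = Path(path)
    merged = (profiles.merge(cp_calls, on=["sample_id", "target"])
              .merge(metadata[["sample_id", "depth_class"]], on="sample_id"))
    targets = sorted(merged["target"].unique())
    fig, axes = plt.subplots(2, 3, figsize=(12, 7), squeeze=False)
    for ax, target in zip(axes.ravel(), targets):
        sub = merged[merged["target"] == target]
        for depth, color in DEPTH_COLORS.items():
            s = sub[sub["depth_class"] == depth]
            ax.scatter(s["cp"], s["tm_major"], s=8, color=color, label=depth)
        ax.set_title(target)
        ax.set_xlabel("Cp (cycles)")
        ax.set_ylabel("Tm (degC)")
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
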