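"""QC and summary figures (matplotlib, Agg backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def bar_with_cells(summaries, value_attr: str, per_cell_attr: str, ylabel: str, path):
    """Per-timepoint bars with single-cell points and SEM error bars."""
    labels = [s.timepoint_label for s in summaries]
    means = [getattr(s, value_attr) for s in summaries]
    sems = [s.sem for s in summaries]
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(labels))
    ax.bar(x, means, yerr=sems, capsize=4, color="tab:blue", alpha=0.7, zorder=1)
    rng = np.random.default_rng(0)
    for i, s in enumerate(summaries):
        vals = np.asarray(getattr(s, per_cell_attr))
        jitter = rng.uniform(-0.15, 0.15, size=len(vals))
        ax.scatter(x[i] + jitter, vals, facecolors="none", edgecolors="k", zorder=2)
    ax.set_xticks(x)
    ax.set_xticklabels(labels, rotation=30, ha="right")
    ax.set_ylabel(ylabel)
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def normal_overlay(labels2d, origins, normals, path, stride: int = 8):
    """Diagnostic overlay: label mask, inner-membrane curve, normal quiver."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(labels2d, cmap="viridis", interpolation="nearest")
    o = np.asarray(origins)[::stride]
    n = np.asarray(normals)[::stride]
    ax.quiver(o[:, 1], o[:, 0], n[:, 1], -n[:, 0], color="w", scale=30, width=0.003)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def distance_histograms(histograms: dict, threshold_nm: float, path):
    """Per-timepoint intermembrane distance histograms with the control threshold."""
    n = len(histograms)
    fig, axes = plt.subplots(1, n, figsize=(3 * n, 3), sharey=True, squeeze=False)
    for ax, (label, (edges, counts)) in zip(axes[0], histograms.items()):
        if len(counts):
            ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", color="tab:gray")
        ax.axvline(threshold_nm, color="r", ls="--", lw=1)
        ax.set_title(str(label))
        ax.set_xlabel("separation (nm)")
    axes[0][0].set_ylabel("rays")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
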