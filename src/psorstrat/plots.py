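"""Figure-style exports: score heatmaps, scan heatmap, genotype chart."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def score_heatmap(matrix: pd.DataFrame, path, title: str = "",
                  calls: pd.DataFrame | None = None) -> None:
    """Subjects x signatures heatmap on the log2-ratio color scale.

    If a long-format cytokine call table is given, up-bias cells are
    marked with '^' and down-bias cells with 'v'.
    """
    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * matrix.shape[1]), max(4, 0.18 * matrix.shape[0]))
    )
    lim = np.nanmax(np.abs(matrix.to_numpy())) or 1.0
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=-lim, vmax=lim)
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.shape[0]))
    ax.set_yticklabels(matrix.index, fontsize=6)
    if calls is not None:
        glyph = {"up-bias": "^", "down-bias": "v"}
        for _, row in calls.iterrows():
            if row["call"] in glyph:
                i = matrix.index.get_loc(row["subject"])
                j = matrix.columns.get_loc(row["cytokine_set"])
                ax.text(j, i, glyph[row["call"]], ha="center", va="center",
                        fontsize=5)
    fig.colorbar(im, ax=ax, label="log2 ratio")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def scan_heatmap(results: pd.DataFrame, path) -> None:
    """Cell-type x cytokine-set Spearman heatmap with per-row extremes boxed."""
    mat = results.pivot(index="cytokine_set", columns="cell_signature",
                        values="r_s")
    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * mat.shape[1]), max(3, 0.25 * mat.shape[0]))
    )
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="PiYG_r",
                   vmin=-1, vmax=1)
    for i, row in enumerate(mat.to_numpy()):
        if np.all(np.isnan(row)):
            continue
        for j, color in ((np.nanargmax(row), "blue"),
                         (np.nanargmin(row), "magenta")):
            ax.add_patch(plt.Rectangle((j - 0.5, i - 0.5), 1, 1, fill=False,
                                       edgecolor=color, lw=1.5))
    ax.set_xticks(range(mat.shape[1]))
    ax.set_xticklabels(mat.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(mat.shape[0]))
    ax.set_yticklabels(mat.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="Spearman r_s")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def genotype_heatmap(counts: pd.DataFrame, path) -> None:
    """Subjects x loci chart: homozygous / heterozygous / non-carrier / missing."""
    from matplotlib.colors import ListedColormap

    cmap = ListedColormap(["lightgrey", "orange", "firebrick", "white"])
    data = counts.to_numpy(float).copy()
    data[np.isnan(data)] = 3
    fig, ax = plt.subplots(
        figsize=(max(4, 0.22 * counts.shape[1]), max(4, 0.15 * counts.shape[0]))
    )
    ax.imshow(data, aspect="auto", cmap=cmap, vmin=-0.5, vmax=3.5)
    ax.set_xticks(range(counts.shape[1]))
    ax.set_xticklabels(counts.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(counts.shape[0]))
    ax.set_yticklabels(counts.index, fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
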