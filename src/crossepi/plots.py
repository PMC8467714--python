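"""Figure helpers: two-locus Punnett-square plots and class-fraction bars."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .epistasis import EpistasisEffect, TwoLocusTable, decompose  # noqa: E402

GENOTYPE_LABELS = ("BB", "BX", "XX")


def punnett_plot(table: TwoLocusTable, path: str | Path) -> None:
    """3x3 observed-vs-expected incidence heatmap for one locus pair."""
    expected, effects = decompose(table)
    obs = table.incidence
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2))
    for ax, mat, title in zip(axes, (obs, expected, effects),
                              ("observed", "expected", "effect")):
        vmax = np.nanmax(np.abs(mat)) or 1.0
        cmap = "RdBu_r" if title == "effect" else "viridis"
        vmin = -vmax if title == "effect" else 0
        im = ax.imshow(mat, cmap=cmap, vmin=vmin, vmax=vmax)
        for i in range(3):
            for j in range(3):
                ax.text(j, i, f"{mat[i, j]:.3f}", ha="center", va="center",
                        fontsize=8)
        ax.set_xticks(range(3), GENOTYPE_LABELS)
        ax.set_yticks(range(3), GENOTYPE_LABELS)
        ax.set_title(f"{title} ({table.defect})", fontsize=9)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.suptitle(" x ".join(table.pair), fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def protective_fraction_plot(summary: pd.DataFrame, path: str | Path) -> None:
    """Bar chart of the protective fraction of significant effects per class."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    sub = summary.dropna(subset=["fraction_protective"])
    ax.bar(sub["genotype_class"], sub["fraction_protective"], color="#4477aa")
    for _, row in sub.iterrows():
        mark = "*" if row["p_vs_half"] < 0.05 else ""
        ax.text(row["genotype_class"], row["fraction_protective"] + 0.02,
                f"{row['n_protective']}/{row['n_significant']}{mark}",
                ha="center", fontsize=8)
    ax.axhline(0.5, color="grey", linestyle="--", linewidth=0.8)
    ax.set_ylabel("fraction protective")
    ax.set_ylim(0, 1.05)
    plt.setp(ax.get_xticklabels(), rotation=20, ha="right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def scan_plot(scan_table: pd.DataFrame, stat: str, thresholds: dict,
              path: str | Path) -> None:
    """Genome-wide scan plot of LOD or -log10 p against marker index."""
    fig, ax = plt.subplots(figsize=(8, 3))
    vals = scan_table[stat] if stat in scan_table else -np.log10(scan_table["p"])
    colors = np.where(scan_table.get("chrom", pd.Series(1, index=scan_table.index))
                      % 2 == 0, "#4477aa", "#66ccee")
    ax.scatter(range(len(scan_table)), vals, s=6, c=colors)
    for name, thr in thresholds.items():
        ax.axhline(thr, linestyle="--", linewidth=0.8,
                   color="red" if "0.05" in str(name) or name == "significant"
                   else "blue")
    ax.set_xlabel("marker index")
    ax.set_ylabel(stat if stat in scan_table else "-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
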