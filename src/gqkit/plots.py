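"""Heatmap and scatter rendering for pipeline reports."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402
from matplotlib.colors import LinearSegmentedColormap  # noqa: E402

# yellow (low) -> black (high), the conventional contact-probability scale
YELLOW_BLACK = LinearSegmentedColormap.from_list("yellow_black", ["#ffff99", "#b8860b", "#000000"])


def save_heatmap(table: pd.DataFrame, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * table.shape[1]), max(3, 0.25 * table.shape[0]))
    )
    im = ax.imshow(table.values, aspect="auto", cmap=YELLOW_BLACK, vmin=0)
    ax.set_xticks(range(table.shape[1]))
    ax.set_xticklabels(table.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(table.shape[0]))
    ax.set_yticklabels(table.index, fontsize=6)
    if title:
        ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_stability_scatter(table: pd.DataFrame, path: str | Path, cutoff: int = 15) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, marker, color in (("stable", "o", "tab:blue"), ("unstable", "x", "tab:red")):
        sub = table[table["label"] == label]
        ax.scatter(sub["mean_intermolecular"], sub["mean_quartet"],
                   marker=marker, color=color, label=label)
    ax.axhline(cutoff, ls="--", color="grey", lw=1)
    ax.set_xlabel("mean intermolecular H-bonds")
    ax.set_ylabel("mean quartet H-bonds")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
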