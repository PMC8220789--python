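"""Basic report plots: RI ranking bars and the assessment heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .assessment import COLOUR_ORDER  # noqa: E402


def plot_ranking(ranking: pd.DataFrame, path: str | Path) -> None:
    """Horizontal bar chart of RIs in rank order, coloured by subclass."""
    palette = {"Fundamental": "#1b7837", "Important": "#fdb863", "Relevant": "#998ec3"}
    fig, ax = plt.subplots(figsize=(7, 0.3 * len(ranking) + 1.5))
    order = ranking.sort_values("rank", ascending=False)
    ax.barh(
        order.index.astype(str),
        order["ri"],
        color=[palette[s] for s in order["subclass"]],
    )
    ax.set_xlabel("Relative Index")
    ax.set_xlim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_assessment(matrix: pd.DataFrame, path: str | Path) -> None:
    """Traffic-light heatmap of a resolved performance matrix."""
    codes = matrix.map(COLOUR_ORDER.get).to_numpy(dtype=float)
    cmap = matplotlib.colors.ListedColormap(["#d7191c", "#ffffbf", "#1a9641"])
    fig, ax = plt.subplots(
        figsize=(0.45 * matrix.shape[1] + 2, 0.45 * matrix.shape[0] + 1.5)
    )
    ax.imshow(codes, cmap=cmap, vmin=0, vmax=2, aspect="auto")
    ax.set_xticks(np.arange(matrix.shape[1]), matrix.columns, rotation=90)
    ax.set_yticks(np.arange(matrix.shape[0]), matrix.index)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
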