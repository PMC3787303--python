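"""Minimal plotting: a matrix-to-image heatmap convenience."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def save_heatmap(
    matrix: pd.DataFrame,
    path: str,
    title: str | None = None,
    cmap: str = "RdBu_r",
    vmin: float | None = None,
    vmax: float | None = None,
) -> None:
    """Render a numeric DataFrame (e.g. log2 fold-changes or z-scores) as
    a labelled heatmap PNG/PDF."""
    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * matrix.shape[1] + 2), max(3, 0.25 * matrix.shape[0] + 1.5))
    )
    im = ax.imshow(matrix.to_numpy(dtype=float), aspect="auto", cmap=cmap, vmin=vmin, vmax=vmax)
    ax.set_xticks(range(matrix.shape[1]), labels=[str(c) for c in matrix.columns],
                  rotation=90, fontsize=7)
    ax.set_yticks(range(matrix.shape[0]), labels=[str(i) for i in matrix.index], fontsize=6)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
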