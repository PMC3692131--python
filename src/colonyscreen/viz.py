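"""Static visual summaries of plates and score distributions.

Heatmaps show colony sizes or scores in plate layout (NA cells drawn in
a distinct colour); histograms show the score distribution with an
optional highlighted selection range whose genes are returned as a
sorted table, ready for export to external enrichment services.
"""

from __future__ import annotations

from typing import Iterable, Optional

import matplotlib

matplotlib.use("Agg")  # file export only; no display needed

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib import colors as mcolors

from .core import ScoreRecord
from .io import records_to_frame

__all__ = ["export_heatmap", "export_histogram", "select_genes"]


def export_heatmap(grid: np.ndarray, path: Optional[str] = None,
                   title: str = "", cmap: str = "viridis",
                   gamma: float = 1.0, na_color: str = "#c0c0c0",
                   vmin: Optional[float] = None,
                   vmax: Optional[float] = None):
    """Draw a plate grid as a heatmap; NA positions get a distinct colour.

    ``gamma`` < 1 accentuates changes in the low range of the colour
    scale, > 1 the high range (power-law normalization).
    """
    grid = np.asarray(grid, dtype=float)
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad(na_color)
    finite = grid[np.isfinite(grid)]
    if vmin is None:
        vmin = float(finite.min()) if finite.size else 0.0
    if vmax is None:
        vmax = float(finite.max()) if finite.size else 1.0
    if vmax <= vmin:
        vmax = vmin + 1.0
    norm = mcolors.PowerNorm(gamma=gamma, vmin=vmin, vmax=vmax)
    fig, ax = plt.subplots(figsize=(max(4, grid.shape[1] / 6),
                                    max(3, grid.shape[0] / 6)))
    im = ax.imshow(np.ma.masked_invalid(grid), cmap=cm, norm=norm,
                   interpolation="nearest")
    ax.set_title(title)
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    fig.colorbar(im, ax=ax, shrink=0.8)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def select_genes(records: Iterable[ScoreRecord],
                 selection_range: tuple[float, float]) -> pd.DataFrame:
    """Genes whose score lies inside [low, high], sorted by score."""
    df = records_to_frame(list(records))
    low, high = selection_range
    sel = df[df["score"].between(low, high)]
    return sel.sort_values("score", kind="stable").reset_index(drop=True)


def export_histogram(records: Iterable[ScoreRecord],
                     selection_range: Optional[tuple[float, float]] = None,
                     path: Optional[str] = None, bins: int = 50,
                     table_path: Optional[str] = None):
    """Histogram of interaction scores with an optional highlighted range.

    Returns ``(figure, table)`` where the table lists the genes inside
    the selection range sorted by score (empty frame for an empty
    selection).  Raises ``ValueError`` when no record carries a score.
    """
    records = list(records)
    df = records_to_frame(records)
    scores = df["score"].dropna()
    if scores.empty:
        raise ValueError("no non-NA score to plot")
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(scores, bins=bins, color="#4878a8", edgecolor="white")
    ax.set_xlabel("interaction score")
    ax.set_ylabel("colonies")
    table = pd.DataFrame(columns=df.columns)
    if selection_range is not None:
        low, high = selection_range
        ax.axvspan(max(low, scores.min()), min(high, scores.max()),
                   color="#d88c3c", alpha=0.3)
        table = select_genes(records, selection_range)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    if table_path is not None:
        table.to_csv(table_path, sep="\t", index=False)
    return fig, table
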