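"""Optional matplotlib figures: rose plots of movement directions and
similarity heatmaps. Imported lazily so the core package has no hard
matplotlib dependency."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .pseudobulk import SimilarityMatrix
from .tracks import DirectionHistogram

__all__ = ["rose_plot", "similarity_heatmap"]


def rose_plot(hist: DirectionHistogram, out: Path | str | None = None, ax=None):
    """Polar bar chart of a direction histogram (counts per angular bin)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    centers = np.deg2rad((hist.bin_edges[:-1] + hist.bin_edges[1:]) / 2)
    width = np.deg2rad(np.diff(hist.bin_edges))
    ax.bar(centers, hist.counts, width=width, bottom=0.0, edgecolor="black", alpha=0.8)
    ax.set_title(f"movement directions (window = {hist.window} frames)")
    if out is not None:
        ax.figure.savefig(out, dpi=150, bbox_inches="tight")
    return ax


def similarity_heatmap(sim: SimilarityMatrix, out: Path | str | None = None, ax=None):
    """Query x reference correlation heatmap with cluster tick labels."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    m = sim.matrix
    im = ax.imshow(m.values, vmin=-1, vmax=1, cmap="RdBu_r", aspect="auto")
    ax.set_xticks(range(m.shape[1]), [str(c) for c in m.columns], rotation=90)
    ax.set_yticks(range(m.shape[0]), [str(c) for c in m.index])
    ax.set_xlabel("reference cluster")
    ax.set_ylabel("query cluster")
    ax.figure.colorbar(im, ax=ax, label=f"Pearson r ({sim.n_genes} markers)")
    if out is not None:
        ax.figure.savefig(out, dpi=150, bbox_inches="tight")
    return ax
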