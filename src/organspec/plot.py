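"""Minimal plotting helper: organ x organ OSG-overlap heatmap."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_overlap_heatmap"]


def plot_overlap_heatmap(overlap: pd.DataFrame, path: str) -> None:
    """Render an overlap-count matrix (as from
    :func:`organspec.classify.overlap_matrix`) to an image file."""
    n = overlap.shape[0]
    fig, ax = plt.subplots(figsize=(max(4, n * 0.25), max(4, n * 0.25)))
    im = ax.imshow(overlap.to_numpy(), cmap="Reds")
    ax.set_xticks(range(n), overlap.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(n), overlap.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="shared organ-specific genes")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
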