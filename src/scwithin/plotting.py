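"""Basic plots for run artifacts."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_embedding"]


def plot_embedding(coords: np.ndarray, labels, path: str | Path,
                   title: str = "") -> None:
    """Scatter the 2-D embedding colored by a categorical label per cell."""
    labels = pd.Series(list(labels)).astype(str)
    coords = np.asarray(coords)
    fig, axis = plt.subplots(figsize=(6, 5))
    for name in sorted(labels.unique()):
        mask = (labels == name).to_numpy()
        axis.scatter(coords[mask, 0], coords[mask, 1], s=4, label=name,
                     alpha=0.7)
    axis.set_xlabel("tsne1")
    axis.set_ylabel("tsne2")
    if title:
        axis.set_title(title)
    axis.legend(markerscale=3, fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
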