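"""Scatter-plot export of 2-D/3-D embeddings, colored by class."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .types import Embedding, ValidationError


def plot_embedding(emb: Embedding, labels=None, path=None, title=None):
    """Save a scatter plot of the first two (or three) embedding coordinates.

    ``labels`` is an optional per-sample class vector aligned with the
    embedding rows; classes get distinct colors.  SVG or PNG is chosen by
    the file suffix.
    """
    if emb.d < 2:
        raise ValidationError("plotting needs at least 2 embedding dimensions")
    three_d = emb.d >= 3
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(111, projection="3d" if three_d else None)
    coords = emb.coords
    if labels is None:
        groups = {"samples": np.arange(coords.shape[0])}
    else:
        labels = np.asarray(labels)
        groups = {str(c): np.flatnonzero(labels == c) for c in np.unique(labels)}
    for name, idx in groups.items():
        pts = [coords[idx, 0], coords[idx, 1]] + ([coords[idx, 2]] if three_d else [])
        ax.scatter(*pts, label=name, s=25, alpha=0.8)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    if three_d:
        ax.set_zlabel("dim 3")
    ax.set_title(title or f"{emb.method} embedding")
    if labels is not None:
        ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
        return None
    return fig
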