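"""Minimal network and heatmap plots for fitted results."""

from __future__ import annotations

import numpy as np

from .datatypes import DyadMatrix, Partition

__all__ = ["plot_network", "plot_heatmap"]


def plot_network(m: DyadMatrix, partition: Partition | None = None, ax=None):
    """Spring-free circular layout; edge width proportional to weight."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    n = m.n
    theta = 2 * np.pi * np.arange(n) / n
    xy = np.c_[np.cos(theta), np.sin(theta)]
    wmax = m.values.max() or 1.0
    for i in range(n):
        for j in range(i + 1 if not m.directed else 0, n):
            if i == j or m.values[i, j] <= 0:
                continue
            ax.plot(
                xy[[i, j], 0], xy[[i, j], 1],
                lw=3 * m.values[i, j] / wmax, color="0.6", zorder=1,
            )
    colors = None
    if partition is not None:
        cmap = ["C0", "C1", "C2", "C3", "C4", "C5"]
        colors = [
            cmap[partition.membership.get(ind, 0) % len(cmap)]
            for ind in m.ids
        ]
    ax.scatter(xy[:, 0], xy[:, 1], s=300, c=colors or "C0", zorder=2)
    for k, ind in enumerate(m.ids):
        ax.annotate(
            ind, xy[k] * 1.15, ha="center", va="center", fontsize=8
        )
    ax.set_axis_off()
    ax.set_xlim(-1.4, 1.4)
    ax.set_ylim(-1.4, 1.4)
    return ax


def plot_heatmap(m: DyadMatrix, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(m.values, cmap="viridis")
    ax.set_xticks(range(m.n), m.ids, rotation=90, fontsize=7)
    ax.set_yticks(range(m.n), m.ids, fontsize=7)
    plt.colorbar(im, ax=ax, shrink=0.8)
    return ax
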