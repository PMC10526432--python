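"""Basic matrix and graph renderings of difference results.

Deliberately minimal: a significance matrix per feature family and a
circular-layout differential network per band. Scalp-topography
interpolation is out of scope.
"""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .core import BAND_NAMES, MONTAGE_16
from .stats_networks import DiffNetwork, DiffResult


def plot_difference_map(results: list[DiffResult], path, title: str = "") -> Path:
    """Heatmap of -log10(p) per (band, channel), significant cells starred."""
    channels = list(dict.fromkeys(r.target for r in results))
    bands = [b for b in BAND_NAMES if any(r.band == b for r in results)]
    mat = np.full((len(bands), len(channels)), np.nan)
    sig = np.zeros_like(mat, dtype=bool)
    for r in results:
        i, j = bands.index(r.band), channels.index(r.target)
        mat[i, j] = -np.log10(max(r.p_value, 1e-300))
        sig[i, j] = r.significant
    fig, ax = plt.subplots(figsize=(10, 3))
    im = ax.imshow(mat, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(channels)), channels, rotation=90, fontsize=7)
    ax.set_yticks(range(len(bands)), bands)
    for i in range(len(bands)):
        for j in range(len(channels)):
            if sig[i, j]:
                ax.text(j, i, "*", ha="center", va="center", color="white")
    fig.colorbar(im, label="-log10 p")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_network(net: DiffNetwork, path, groups=("A", "B"),
                 channel_names=MONTAGE_16) -> Path:
    """Circular graph of significant edges; colour encodes the higher group."""
    g = nx.Graph()
    g.add_nodes_from(channel_names)
    colors = []
    for pair, direction, _ in net.edges:
        a, b = pair.split("-")
        g.add_edge(a, b)
        colors.append("tab:red" if direction == groups[1] else "tab:blue")
    fig, ax = plt.subplots(figsize=(5, 5))
    pos = nx.circular_layout(g)
    nx.draw_networkx(g, pos=pos, ax=ax, node_size=300, font_size=7,
                     node_color="lightgray", edge_color=colors, width=2)
    ax.set_title(f"{net.band}: {net.ratio} ({groups[1]}-higher/{groups[0]}-higher)")
    ax.axis("off")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
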