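"""Basic visualisation: connectivity-matrix heatmaps and region digraphs.

Requires matplotlib (optional dependency, extra ``plot``).
"""

from __future__ import annotations

import numpy as np

from .bayesian import ConnectivityMatrix
from .netstats import RegionNetwork


def plot_connectivity(matrix: ConnectivityMatrix, ax=None, masked_only=True):
    """Heatmap of directed strengths (row = source, column = target).

    Non-significant entries are blanked when a mask is present and
    ``masked_only`` is set, mirroring the usual EC-matrix figures.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    s = matrix.strengths.copy()
    if masked_only and matrix.mask is not None:
        s = np.where(matrix.mask, s, np.nan)
    n = s.shape[0]
    im = ax.imshow(s, origin="upper", cmap="viridis",
                   extent=(0.5, n + 0.5, n + 0.5, 0.5))
    ax.set_xlabel("target channel")
    ax.set_ylabel("source channel")
    title = " ".join(
        str(v) for v in (matrix.subject_id, matrix.state, matrix.band) if v
    )
    ax.set_title(title or "directed coupling strength")
    plt.colorbar(im, ax=ax, label="coupling strength (rad/s)")
    return ax


def plot_region_network(network: RegionNetwork, ax=None, threshold=None):
    """Directed graph of interregional EC: nodes on a circle, arrows
    weighted by strength; edges below ``threshold`` are hidden."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    labels = network.labels
    R = len(labels)
    angles = 2 * np.pi * np.arange(R) / R
    pos = np.column_stack([np.cos(angles), np.sin(angles)])
    for (x, y), label in zip(pos, labels):
        ax.text(1.12 * x, 1.12 * y, label, ha="center", va="center")
        ax.plot(x, y, "o", color="0.3", ms=10)
    finite = network.ec[np.isfinite(network.ec)]
    vmax = finite.max() if finite.size else 1.0
    for i in range(R):
        for j in range(R):
            v = network.ec[i, j]
            if i == j or not np.isfinite(v):
                continue
            if threshold is not None and v < threshold:
                continue
            start, end = pos[i], pos[j]
            ax.annotate(
                "", xy=end + 0.12 * (start - end),
                xytext=start + 0.12 * (end - start),
                arrowprops=dict(
                    arrowstyle="-|>", lw=0.5 + 2.5 * v / vmax,
                    color=plt.cm.viridis(v / vmax), shrinkA=8, shrinkB=8,
                    connectionstyle="arc3,rad=0.12",
                ),
            )
    ax.set_xlim(-1.35, 1.35)
    ax.set_ylim(-1.35, 1.35)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
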