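"""Basic plots: complexity-entropy scatter and spike raster."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .ordinal import CEPoint  # noqa: E402
from .spikes import SpikeTrain  # noqa: E402

__all__ = ["plot_ce_plane", "plot_raster"]


def plot_ce_plane(points: list[CEPoint] | dict[str, list[CEPoint]], ax=None):
    """Scatter of (Hs, Cjs) points; pass a dict to overlay labelled groups."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    groups = points if isinstance(points, dict) else {"": points}
    for label, pts in groups.items():
        ax.scatter([p.hs for p in pts], [p.cjs for p in pts], s=14,
                   label=label or None, alpha=0.8)
    ax.set_xlabel("normalized permutation entropy $H_s$")
    ax.set_ylabel("statistical complexity $C_{js}$")
    ax.set_xlim(0, 1.02)
    ax.set_ylim(bottom=0)
    if isinstance(points, dict):
        ax.legend(frameon=False)
    return ax


def plot_raster(spikes: SpikeTrain, ax=None):
    """Spike raster: one row per channel, a dot per spike."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    for row, (cid, t) in enumerate(zip(spikes.channel_ids, spikes.times)):
        ax.plot(t, [row] * t.size, "|", color="k", markersize=3)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("channel")
    ax.set_yticks(range(len(spikes.channel_ids)))
    ax.set_yticklabels(spikes.channel_ids, fontsize=6)
    return ax
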