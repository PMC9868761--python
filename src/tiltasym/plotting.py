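"""Poincaré scatter rendering (optional, matplotlib)."""

from __future__ import annotations

import numpy as np

from .poincare import PlotGeometry


def plot_poincare(geom: PlotGeometry, ax=None, signal_label: str = "signal", **scatter_kw):
    """Scatter of (s_i, s_{i+1}) with the line of identity and centroid.

    Returns the matplotlib Axes.  Points above the LI (decelerations /
    pressure rises) are drawn darker than points below.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    above = ~geom.on_li & (geom.d_perp > 0)
    below = ~geom.on_li & (geom.d_perp < 0)
    kw = {"s": 12, "alpha": 0.7, **scatter_kw}
    ax.scatter(geom.x[above], geom.y[above], color="#1f3d7a", label="above LI", **kw)
    ax.scatter(geom.x[below], geom.y[below], color="#7aa0d4", label="below LI", **kw)
    ax.scatter(geom.x[geom.on_li], geom.y[geom.on_li], color="0.6", label="on LI", **kw)
    lims = [min(geom.x.min(), geom.y.min()), max(geom.x.max(), geom.y.max())]
    pad = 0.05 * (lims[1] - lims[0] or 1.0)
    lims = [lims[0] - pad, lims[1] + pad]
    ax.plot(lims, lims, color="0.3", lw=0.8, zorder=0)
    ax.plot(*geom.centroid, marker="+", color="crimson", ms=10, mew=2)
    ax.set_xlim(lims)
    ax.set_ylim(lims)
    ax.set_xlabel(f"{signal_label}$_i$")
    ax.set_ylabel(f"{signal_label}$_{{i+1}}$")
    ax.set_aspect("equal")
    return ax
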