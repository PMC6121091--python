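"""Auxiliary aquagram plots (radar and linear). Non-contractual output:
the data tables on the AquagramResult are the canonical product."""

from __future__ import annotations

import numpy as np

from .aquagram import AquagramResult

__all__ = ["plot_aquagram_radar", "plot_aquagram_linear"]


def plot_aquagram_radar(result: AquagramResult, ax=None):
    """Radar chart of per-group values; returns the matplotlib axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    n = len(result.axes)
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    closed = np.concatenate([theta, theta[:1]])
    for g, row in zip(result.groups, result.values):
        ax.plot(closed, np.concatenate([row, row[:1]]), label=g)
    ax.set_xticks(theta)
    ax.set_xticklabels(result.axes)
    ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1), fontsize="small")
    return ax


def plot_aquagram_linear(result: AquagramResult, ax=None):
    """Linear aquagram with CI bands when present; returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.arange(len(result.axes))
    for i, g in enumerate(result.groups):
        (line,) = ax.plot(x, result.values[i], marker="o", label=g)
        if result.lo95 is not None:
            ax.fill_between(x, result.lo95[i], result.hi95[i],
                            alpha=0.2, color=line.get_color())
    ax.set_xticks(x)
    ax.set_xticklabels(result.axes, rotation=45)
    unit = "°C equivalent" if result.mode.startswith("temp") else "normalized absorbance"
    ax.set_ylabel(unit)
    ax.legend(fontsize="small")
    return ax
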