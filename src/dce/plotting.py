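"""Static diagnostics plots: consensus CDFs, delta-AUC and a sorted heatmap."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_cdfs", "plot_delta_auc", "plot_consensus_heatmap"]


def _axes(ax):
    if ax is None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_cdfs(cdfs, k_values, ax=None):
    """Consensus CDF per cluster size on one axis."""
    ax = _axes(ax)
    x = np.linspace(0, 1, 201)
    for cdf, k in zip(cdfs, k_values):
        ax.step(x, cdf(x), where="post", label=f"k={k}")
    ax.set_xlabel("consensus index")
    ax.set_ylabel("CDF")
    ax.legend()
    return ax


def plot_delta_auc(dauc: dict, ax=None):
    """Relative change in area under the consensus CDF across k."""
    ax = _axes(ax)
    ks = sorted(dauc)
    ax.plot(ks, [dauc[k] for k in ks], marker="o")
    ax.set_xlabel("k")
    ax.set_ylabel("relative change in AUC")
    return ax


def plot_consensus_heatmap(cm, labels=None, ax=None):
    """Consensus matrix heatmap, rows/columns sorted by cluster then value."""
    ax = _axes(ax)
    values = cm.values if hasattr(cm, "values") else np.asarray(cm)
    if labels is not None:
        order = np.lexsort((-values.sum(axis=1), np.asarray(labels)))
        values = values[np.ix_(order, order)]
    ax.imshow(values, vmin=0, vmax=1, cmap="viridis", interpolation="nearest")
    ax.set_xlabel("samples")
    ax.set_ylabel("samples")
    return ax
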