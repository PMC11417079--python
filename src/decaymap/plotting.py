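"""Figure helpers: per-method error box plots and binned error surfaces."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_error_boxes", "plot_binned_surface"]


def plot_error_boxes(frame: pd.DataFrame, metric: str = "accuracy", ax=None):
    """Box plot of a per-slice metric grouped by method."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    methods = list(frame["method"].unique())
    data = [frame.loc[frame["method"] == m, metric].values for m in methods]
    ax.boxplot(data, tick_labels=methods)
    ax.set_ylabel(metric)
    ax.tick_params(axis="x", rotation=30)
    return ax


def plot_binned_surface(surface, what: str = "median", ax=None):
    """Heat map of the binned signed-error statistics over (T_true, SNR)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    img = surface.median_2d if what == "median" else surface.iqr_2d
    extent = [
        surface.t_edges[0],
        surface.t_edges[-1],
        surface.snr_edges[0],
        surface.snr_edges[-1],
    ]
    lim = np.nanmax(np.abs(img)) if np.isfinite(img).any() else 1.0
    kw = dict(cmap="RdBu_r", vmin=-lim, vmax=lim) if what == "median" else {}
    im = ax.imshow(img, origin="lower", aspect="auto", extent=extent, **kw)
    ax.set_xlabel("T_true")
    ax.set_ylabel("SNR (dB)")
    plt.colorbar(im, ax=ax, label=f"{what} signed T error")
    return ax
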