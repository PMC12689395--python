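"""Quick-look plots: sweep dose-response curves, sigmoid fits, lattice slices."""

from __future__ import annotations

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap

from .core import CAPILLARY, LabeledGrid
from .pipeline import aggregate_sweep
from .sigmoid import CapillaryViabilityResults
from .viability import extract_mid_slice

#: medium, alpha, beta, delta, capillary
_TYPE_COLORS = ["#f5f5f5", "#e6b800", "#2e8b57", "#4169e1", "#c0392b"]


def plot_sweep(records, ax=None):
    """Viable proportion vs capillary count (mean ± SEM per glucose)."""
    if ax is None:
        _, ax = plt.subplots()
    agg = aggregate_sweep(records)
    for glucose, sub in agg.groupby("glucose"):
        ax.errorbar(sub["n_capillaries"], sub["mean"], yerr=sub["sem"],
                    marker="o", capsize=3, label=glucose)
    ax.set_xlabel("capillaries")
    ax.set_ylabel("viable proportion")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    return ax


def plot_viability_fit(results: CapillaryViabilityResults, ax=None):
    """Observed vs fitted viable proportions with the 1:1 line."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot([0, 1], [0, 1], "k--", lw=1)
    ax.plot(results.model.viable, results.fitted, "o", alpha=0.7)
    ax.set_xlabel("observed viable proportion")
    ax.set_ylabel("fitted viable proportion")
    ax.set_title(f"R² = {results.r_squared:.3f}, MSE = {results.mse:.4f}")
    return ax


def plot_mid_slice(grid: LabeledGrid, field=None, ax=None):
    """Middle z plane: cell/capillary type map, or an oxygen field (µM)
    with capillary voxels overlaid."""
    if ax is None:
        _, ax = plt.subplots()
    sl = extract_mid_slice(grid)
    types = grid.type_of[sl]
    if field is None:
        ax.imshow(types.T, origin="lower", cmap=ListedColormap(_TYPE_COLORS),
                  vmin=0, vmax=4, interpolation="nearest")
    else:
        z = grid.shape[2] // 2
        im = ax.imshow(field.concentration[:, :, z].T, origin="lower",
                       cmap="turbo", interpolation="nearest")
        plt.colorbar(im, ax=ax, label="oxygen (µM)")
        cap = np.ma.masked_where(types.T != CAPILLARY, types.T)
        ax.imshow(cap, origin="lower", cmap=ListedColormap(["#ffffff"]),
                  interpolation="nearest")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    return ax
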