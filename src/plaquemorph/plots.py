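"""Scatter + fitted-curve figures for the consistency report."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_fit_grid", "plot_fit"]


def plot_fit(ax, x, y, entry):
    """One scatter panel with the linear and power fitted curves."""
    ax.scatter(x, y, s=10, alpha=0.6, edgecolors="none")
    xs = np.linspace(np.min(x), np.max(x), 200)
    lin = entry["linear"]
    ax.plot(xs, lin.a + lin.b * xs, "-", lw=1,
            label=f"linear R²={lin.r_squared:.2f}")
    pw = entry.get("power")
    if pw is not None:
        ax.plot(xs[xs > 0], pw.a * xs[xs > 0] ** pw.b, "--", lw=1,
                label=f"power R²={pw.r_squared:.2f}")
    ax.set_xlabel(entry["x"], fontsize=7)
    ax.set_ylabel(entry["y"], fontsize=7)
    ax.tick_params(labelsize=6)
    ax.legend(fontsize=5, frameon=False)


def plot_fit_grid(plaque_df, entries, path, ncols: int = 5):
    """Small-multiple grid of all pairwise parameter fits."""
    n = len(entries)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.6 * nrows))
    axes = np.atleast_1d(axes).ravel()
    for ax, entry in zip(axes, entries):
        plot_fit(ax, plaque_df[entry["x"]], plaque_df[entry["y"]], entry)
    for ax in axes[n:]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
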