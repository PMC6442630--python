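"""Convenience plots: the Chernoff-ratio map and the delta-ARI scatter.

These are thin wrappers over matplotlib; all quantities they draw are
computed by the pipeline module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pipeline import ExperimentResult, MapGrid


def plot_chernoff_map(grid: MapGrid, eda_points: pd.DataFrame | None = None, ax=None):
    """Render the Chernoff-ratio surface with the rho=1 contour and y=x line.

    Optionally overlays EDA projection points (hemisphere in red, tissue in
    blue).  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    with np.errstate(invalid="ignore", divide="ignore"):
        logrho = np.log(grid.rho)
    lim = np.nanmax(np.abs(logrho)) or 1.0
    pcm = ax.pcolormesh(
        grid.xs, grid.ys, logrho, cmap="RdBu_r", vmin=-lim, vmax=lim,
        shading="nearest",
    )
    plt.colorbar(pcm, ax=ax, label=r"$\log\,\rho$  ($\rho>1$: ASE preferred)")
    for c in grid.contours:
        ax.plot(c[:, 0], c[:, 1], "k-", lw=2)
    ax.plot([0, 1], [0, 1], "k-", lw=0.8)  # rank-1 submodel boundary
    if eda_points is not None:
        colors = {"hemisphere": "red", "tissue": "blue"}
        for track, sub in eda_points.groupby("track"):
            ax.scatter(sub["x"], sub["y"], s=12, c=colors.get(track), label=track)
        ax.legend()
    ax.set_xlabel(r"$x=\min(a,c)/\max(a,c)$")
    ax.set_ylabel(r"$y=b/\max(a,c)$")
    return ax


def plot_delta_ari(result: ExperimentResult, ax=None):
    """Scatter of per-replicate (x, y) delta-ARI coordinates."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    df = result.replicates
    ax.scatter(df["x_rep"], df["y_rep"], s=14)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("ARI(LSE, hemisphere) - ARI(LSE, tissue)")
    ax.set_ylabel("ARI(ASE, hemisphere) - ARI(ASE, tissue)")
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    return ax
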