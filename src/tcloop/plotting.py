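"""Matplotlib renderings of bifurcation diagrams and basin maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .basins import BasinGrid
from .bifurcation import BifurcationDiagram

__all__ = ["plot_bifurcation", "plot_basin_grid"]

# basin colour convention: high-firing basin light blue, baseline light red
BASIN_COLORS = {"zero": "#f4b8b8", "high": "#b8d4f4", "unresolved": "#dddddd"}


def plot_bifurcation(diagram: BifurcationDiagram, path=None):
    """Stable (blue) and unstable (red) branches of S, T, V against a."""
    df = diagram.to_dataframe()
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharex=True)
    for ax, var in zip(axes, ["S", "T", "V"]):
        for (bid, stab), grp in df.groupby(["branch_id", "stability"]):
            color = "tab:blue" if stab == "stable" else "tab:red"
            ax.plot(grp["a"], grp[var], ".", ms=2, color=color)
        if diagram.a_hat is not None:
            ax.axvline(diagram.a_hat, ls=":", lw=0.8, color="gray")
        ax.set_xlabel("a")
        ax.set_ylabel(f"{var} (Hz)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_basin_grid(grid: BasinGrid, path=None):
    """Basin map in the V/S plane; attractors drawn as filled dots."""
    uniq = sorted(set(grid.labels.ravel()))
    codes = {lab: i for i, lab in enumerate(uniq)}
    img = np.vectorize(codes.get)(grid.labels)
    cmap = matplotlib.colors.ListedColormap(
        [BASIN_COLORS.get(lab, "#cccccc") for lab in uniq])
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.pcolormesh(grid.v_values, grid.s_values, img, cmap=cmap, shading="auto")
    for eq in grid.attractors:
        ax.plot(eq.V, eq.S, "ko", ms=6)
    ax.set_xlabel("V (Hz)")
    ax.set_ylabel("S (Hz)")
    ax.set_title(f"a={grid.params.a:g}, T(0)={grid.T_init:g} Hz")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
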