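"""Residual persistence charts.

The chart is a rectangle heatmap: subjects along x, complexity k along y,
cell colour increasing monotonically with persistence.  When p-values are
supplied, non-significant cells (p >= alpha) are drawn smaller and
desaturated so that the eye is drawn to persistences that both are large and
survive the resampling test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib import colors as mcolors
from matplotlib.collections import PatchCollection
from matplotlib.patches import Rectangle

__all__ = ["persistence_color_norm", "render_persistence_chart"]


def persistence_color_norm(P: np.ndarray) -> mcolors.Normalize:
    """Monotone map from persistence values to colour intensity in [0, 1]."""
    vmax = float(np.max(P))
    return mcolors.Normalize(vmin=0.0, vmax=vmax if vmax > 0 else 1.0)


def render_persistence_chart(
    P,
    pvals=None,
    alpha: float = 0.05,
    path=None,
    cmap: str = "viridis",
    shrink: float = 0.45,
    ax=None,
):
    """Draw a persistence chart and optionally write it to ``path``.

    Parameters
    ----------
    P
        d x k_max persistence matrix (DataFrame with subject index and
        complexity columns, or a plain array).
    pvals
        Optional matrix of the same shape; cells with ``p >= alpha`` are
        drawn at ``shrink`` of the full cell size and desaturated.
    path
        Output file; the format (png/pdf/svg) follows the extension.
    """
    if isinstance(P, pd.DataFrame):
        values = P.to_numpy(dtype=float)
        subjects = [str(s) for s in P.index]
        ks = [str(k) for k in P.columns]
    else:
        values = np.asarray(P, dtype=float)
        subjects = [str(i) for i in range(values.shape[0])]
        ks = [str(k + 1) for k in range(values.shape[1])]
    if not np.all(np.isfinite(values)):
        raise ValueError("persistence matrix must be finite")
    if pvals is not None:
        pv = np.asarray(pvals, dtype=float)
        if pv.shape != values.shape:
            raise ValueError("p-value matrix shape must match the persistences")
    norm = persistence_color_norm(values)
    colormap = plt.get_cmap(cmap)

    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(
            figsize=(max(4.0, 0.14 * len(subjects)), max(3.0, 0.14 * len(ks)))
        )
    else:
        fig = ax.figure
    patches, facecolors = [], []
    d, kmax = values.shape
    for i in range(d):
        for j in range(kmax):
            big = pvals is None or pv[i, j] < alpha
            size = 1.0 if big else shrink
            rgba = np.array(colormap(norm(values[i, j])))
            if not big:
                rgba[:3] = 0.55 * rgba[:3] + 0.45  # desaturate towards grey
            off = (1.0 - size) / 2.0
            patches.append(Rectangle((i + off, j + off), size, size))
            facecolors.append(rgba)
    ax.add_collection(PatchCollection(patches, facecolor=facecolors, edgecolor="none"))
    ax.set_xlim(0, d)
    ax.set_ylim(0, kmax)
    step = max(1, d // 40)
    ax.set_xticks(np.arange(0, d, step) + 0.5)
    ax.set_xticklabels(subjects[::step], rotation=90, fontsize=6)
    kstep = max(1, kmax // 30)
    ax.set_yticks(np.arange(0, kmax, kstep) + 0.5)
    ax.set_yticklabels(ks[::kstep], fontsize=6)
    ax.set_xlabel("subject")
    ax.set_ylabel("complexity k")
    fig.colorbar(
        plt.cm.ScalarMappable(norm=norm, cmap=colormap), ax=ax, label="persistence"
    )
    if path is not None:
        fig.savefig(path, bbox_inches="tight", dpi=150)
        if own_fig:
            plt.close(fig)
        return path
    return ax
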