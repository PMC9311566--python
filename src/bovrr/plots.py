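"""Plotting helpers: Miami plot of variant significance and merit scatters."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def miami_plot(effect_table: pd.DataFrame, title: str = "", ax=None):
    """Additive -log10(p) above the axis, dominance below, by position.

    Expects the per-variant table with chrom, pos, p_a, p_d and the
    significance flags; returns the matplotlib Axes.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    t = effect_table.sort_values(["chrom", "pos"])
    chroms = list(dict.fromkeys(t["chrom"]))
    offset = 0
    centers = []
    for i, c in enumerate(chroms):
        sub = t[t["chrom"] == c]
        x = sub["pos"].to_numpy() + offset
        color = f"C{i % 2}"
        ax.scatter(x, -np.log10(sub["p_a"].clip(lower=1e-300)), s=4, c=color)
        ax.scatter(x, np.log10(sub["p_d"].clip(lower=1e-300)), s=4, c=color)
        centers.append((offset + x.max()) / 2 if len(x) else offset)
        offset = x.max() if len(x) else offset
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xticks(centers)
    ax.set_xticklabels(chroms)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"additive  $-\log_{10}p$   /   dominance  $\log_{10}p$")
    if title:
        ax.set_title(title)
    return ax


def merit_scatter(
    proj_cw: pd.DataFrame,
    proj_wtw: pd.DataFrame,
    color: pd.Series | None = None,
    color_label: str = "",
    ax=None,
):
    """Projected total WtW against total CW, quadrant lines at the means.

    ``color`` (indexed by animal_id) shades the dots, e.g. by pHet or
    ROH bases.  Returns the Axes.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    cw = proj_cw.set_index("animal_id")["total"]
    wtw = proj_wtw.set_index("animal_id")["total"]
    common = cw.index.intersection(wtw.index)
    cw, wtw = cw.loc[common], wtw.loc[common]
    c = color.reindex(common) if color is not None else None
    sc = ax.scatter(cw, wtw, c=c, s=8, cmap="viridis")
    if c is not None:
        plt.colorbar(sc, ax=ax, label=color_label)
    ax.axvline(cw.mean(), color="k", lw=0.8)
    ax.axhline(wtw.mean(), color="k", lw=0.8)
    ax.set_xlabel("projected total CW effect, age 8 (kg)")
    ax.set_ylabel("projected total WtW effect, age 8 (kg)")
    for label, xq, yq in (("LL", 0.02, 0.02), ("LH", 0.02, 0.95),
                          ("HH", 0.95, 0.95), ("HL", 0.95, 0.02)):
        ax.text(xq, yq, label, transform=ax.transAxes, fontsize=9)
    return ax
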