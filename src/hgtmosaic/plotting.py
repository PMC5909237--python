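"""Minimal plotting: a linear origin track for one clone."""

from __future__ import annotations

import pandas as pd


def plot_origin_track(consolidated: pd.DataFrame, universe: pd.DataFrame, ax=None):
    """Plot per-gene final origins along the genome as a colored strip.

    Donor-origin genes are drawn above the axis, recipient below,
    undetermined/discordant on it. Returns the matplotlib axis.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2))
    df = consolidated.merge(universe[["gene_id", "start", "end"]], on="gene_id")
    levels = {"donor": 1, "recipient": -1}
    colors = {"donor": "tab:green", "recipient": "tab:blue"}
    for _, g in df.iterrows():
        y = levels.get(g["origin_final"], 0)
        c = colors.get(g["origin_final"], "tab:gray")
        ax.plot([g["start"], g["end"]], [y, y], color=c, lw=3, solid_capstyle="butt")
    ax.set_ylim(-2, 2)
    ax.set_yticks([-1, 0, 1], ["recipient", "other", "donor"])
    ax.set_xlabel("recipient genome position (bp)")
    return ax
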