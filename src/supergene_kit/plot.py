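"""Plot helpers for the three signature figures: the per-SNP linkage-span
profile with called high-LD intervals, the ancestry-painting raster, and the
stacked divergence-time profile."""

from __future__ import annotations

import numpy as np


def plot_ld_profile(profile, ax=None, highlight_intervals=True):
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ax.plot(profile.pos / 1e6, profile.s / 1e6, lw=0.5, color="black")
    if highlight_intervals:
        for a, b in profile.intervals:
            ax.axvspan(a / 1e6, b / 1e6, color="0.85", zorder=0)
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel("linkage span S (Mb)")
    return ax


def plot_painting(pm, ax=None):
    """Raster of painted genotypes: dark/light grey homozygotes, split heterozygotes."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    ax = ax or plt.gca()
    cmap = ListedColormap(["0.25", "0.8", "0.55", "white"])
    ax.imshow(
        pm.states.T, aspect="auto", interpolation="nearest", cmap=cmap, vmin=0, vmax=3,
        extent=[pm.pos[0], pm.pos[-1], len(pm.individuals), 0],
    )
    ax.set_yticks(np.arange(len(pm.individuals)) + 0.5)
    ax.set_yticklabels(pm.individuals, fontsize=6)
    ax.set_xlabel("position (bp)")
    return ax


def plot_divergence_profile(stacked, ax=None):
    """Lines per population over windows; vertical gaps are divergence times."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    for pop, df in stacked.groupby("population"):
        df = df.sort_values("window")
        ax.plot(df.window, df.y, label=pop, lw=1)
        if {"lower", "upper"} <= set(df.columns):
            ax.fill_between(df.window, df.lower, df.upper, alpha=0.2)
    ax.invert_yaxis()
    ax.set_xlabel("window start (bp)")
    ax.set_ylabel("stacked divergence time")
    ax.legend(fontsize=6)
    return ax
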