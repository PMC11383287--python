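"""Figure helpers: dendrograms, growth curves, GR curves, PCA scatters."""

from __future__ import annotations

import numpy as np

CATEGORY_COLORS = {"low": "#4878cf", "moderate": "#e8a33d", "high": "#d1495b"}


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_dendrogram(layout, ax=None):
    """Render a lineage dendrogram from a DendrogramLayout."""
    ax = _ax(ax)
    for _, seg in layout.segments.iterrows():
        ax.hlines(seg.y, seg.x0, seg.x1, color="0.2", lw=1)
        if seg.died:
            ax.plot(seg.x1, seg.y, "x", color="crimson", ms=5)
    for _, con in layout.connectors.iterrows():
        ax.vlines(con.x, con.y0, con.y1, color="0.2", lw=1)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("lineage")
    ax.set_yticks([])
    return ax


def plot_growth_curves(results, ax=None):
    """Living-cell counts over time for a list of PopulationResults."""
    ax = _ax(ax)
    series = []
    for res in results:
        t, c = res.living_series()
        series.append(c)
        ax.plot(t, c, color="0.7", lw=0.8)
    if series:
        ax.plot(t, np.median(np.stack(series), axis=0), color="k", lw=2,
                label="median")
        ax.legend()
    ax.set_xlabel("time (h)")
    ax.set_ylabel("living cells")
    return ax


def plot_gr_curve(table, ax=None, label=None):
    """Median GR vs dose with standard-error bars."""
    ax = _ax(ax)
    tab = table[table.dose_uM > 0]
    ax.errorbar(tab.dose_uM, tab.gr_median, yerr=tab.gr_sem, fmt="o-",
                capsize=3, label=label)
    ax.set_xscale("log")
    ax.axhline(0.0, color="0.8", ls="--")
    ax.set_xlabel("dose (uM)")
    ax.set_ylabel("GR value")
    ax.set_ylim(-1.05, 1.15)
    return ax


def plot_pca_scores(scores, counts, categories, ax=None, components=(1, 2)):
    """PC scatter sized by division count and colored by phenotype bin."""
    ax = _ax(ax)
    i, j = components[0] - 1, components[1] - 1
    counts = np.asarray(counts, dtype=float)
    sizes = 10 + 8 * counts
    for cat in ("low", "moderate", "high"):
        sel = np.array([c == cat for c in categories])
        if sel.any():
            ax.scatter(scores[sel, i], scores[sel, j], s=sizes[sel],
                       c=CATEGORY_COLORS[cat], alpha=0.7, label=cat,
                       edgecolors="none")
    ax.set_xlabel(f"PC{components[0]}")
    ax.set_ylabel(f"PC{components[1]}")
    ax.legend(title="divisions")
    return ax


def plot_division_probability(table, ax=None, label=None):
    """Division probability vs cycle progress."""
    ax = _ax(ax)
    ax.plot(table.progress, table.p_divide, "-", label=label)
    ax.axhline(0.5, color="0.8", ls="--")
    ax.set_xlabel("cell cycle progress at drug addition")
    ax.set_ylabel("division probability")
    ax.set_ylim(-0.02, 1.02)
    return ax
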