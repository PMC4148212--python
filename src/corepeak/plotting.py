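"""Plot helpers for the standard figures of the analysis.

Each function takes the payload computed by the corresponding library
operation and returns a matplotlib ``Axes``; nothing here recomputes results.
"""

from __future__ import annotations

from typing import Mapping

import matplotlib

matplotlib.use("Agg")  # headless-safe default
import matplotlib.pyplot as plt
import numpy as np


def plot_overlap_curve(curve, ax=None):
    """Percent overlap vs rank with the selected cutoff marked."""
    ax = ax or plt.gca()
    ax.plot(curve.ranks, curve.percent, marker="o", ms=3)
    ax.axvline(curve.cutoff_rank, color="red", ls="--", lw=1)
    ax.set_xlabel("rank")
    ax.set_ylabel("% overlap")
    return ax

def plot_width_histogram(hist: Mapping[int, int], bin: int = 100, ax=None):
    ax = ax or plt.gca()
    ax.bar([k * bin for k in hist], list(hist.values()), width=bin * 0.9, align="edge")
    ax.set_xlabel("peak width (bp)")
    ax.set_ylabel("peaks")
    return ax

def plot_meta_profile(profile: dict, label: str | None = None, ax=None):
    ax = ax or plt.gca()
    ax.plot(profile["offsets"], profile["mean"], label=label)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("offset from anchor (bp)")
    ax.set_ylabel("mean signal")
    return ax

def plot_heatmap(heatmap: dict, ax=None):
    ax = ax or plt.gca()
    ax.imshow(heatmap["matrix"], aspect="auto", interpolation="nearest",
              extent=[heatmap["offsets"][0], heatmap["offsets"][-1],
                      len(heatmap["matrix"]), 0])
    ax.set_xlabel("offset from anchor (bp)")
    ax.set_ylabel("peaks (by width)")
    return ax

def plot_class_enrichment(table, ax=None):
    """Paired bars of peak% vs genome% per chromatin class."""
    ax = ax or plt.gca()
    x = np.arange(len(table))
    colors = {"RED": "red", "YELLOW": "gold", "BLUE": "blue",
              "GREEN": "green", "BLACK": "black"}
    ax.bar(x - 0.2, table["peak_percent"], width=0.4,
           color=[colors[c] for c in table.index], label="peaks")
    ax.bar(x + 0.2, table["genome_percent"], width=0.4, color="lightgrey",
           edgecolor="grey", label="genome")
    ax.set_xticks(x, table.index, rotation=45)
    ax.set_ylabel("%")
    ax.legend()
    return ax
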