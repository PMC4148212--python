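"""Peak width statistics, width histograms and proximity clustering."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import Peak

__all__ = [
    "peak_widths",
    "width_stats",
    "width_histogram",
    "proximity_counts",
    "width_density_compare",
]


def peak_widths(peaks: Sequence[Peak]) -> np.ndarray:
    """Widths in bp, honoring an explicit table width column where present."""
    return np.array([p.width for p in peaks], dtype=int)


def width_stats(peaks: Sequence[Peak], threshold: int = 2000) -> dict:
    """Summary width statistics of a peak set.

    Mean and median are rounded to the nearest integer bp (the precision at
    which such statistics are conventionally reported).

    Returns ``{n, mean, median, max, count_over_threshold,
    fraction_over_threshold}``; raises on an empty peak list.
    """
    if len(peaks) == 0:
        raise ValueError("width_stats requires a non-empty peak list")
    widths = peak_widths(peaks)
    over = int((widths > threshold).sum())
    return {
        "n": int(len(widths)),
        "mean": int(round(float(np.mean(widths)))),
        "median": int(round(float(np.median(widths)))),
        "max": int(widths.max()),
        "count_over_threshold": over,
        "fraction_over_threshold": over / len(widths),
    }


def width_histogram(peaks: Sequence[Peak], bin: int = 100) -> dict[int, int]:
    """Counts of peak widths per ``bin``-bp bin.

    Bin ``k`` counts widths in ``[k*bin, (k+1)*bin)``; the counts sum to the
    number of peaks.
    """
    if bin <= 0:
        raise ValueError("bin must be positive")
    hist: dict[int, int] = {}
    for w in peak_widths(peaks):
        k = int(w // bin)
        hist[k] = hist.get(k, 0) + 1
    return dict(sorted(hist.items()))


def proximity_counts(
    peaks: Sequence[Peak], window: int = 5000, mode: str = "gap"
) -> np.ndarray:
    """Per-peak count of other peaks within ``window`` bp.

    Distance is the nearest-edge gap between peak intervals (overlapping peaks
    have distance 0); ``mode="center"`` switches to center-to-center distance.
    Symmetric: if peak i counts peak j, then j counts i.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    n = len(peaks)
    counts = np.zeros(n, dtype=int)
    order = sorted(range(n), key=lambda i: (peaks[i].chrom, peaks[i].interval.start))
    for a_pos, i in enumerate(order):
        pi = peaks[i]
        for j in order[a_pos + 1 :]:
            pj = peaks[j]
            if pj.chrom != pi.chrom:
                break
            if mode == "gap":
                dist = max(
                    0,
                    max(pi.interval.start, pj.interval.start)
                    - min(pi.interval.end, pj.interval.end),
                )
            elif mode == "center":
                ci = (pi.interval.start + pi.interval.end) / 2
                cj = (pj.interval.start + pj.interval.end) / 2
                dist = abs(cj - ci)
            else:
                raise ValueError(f"unknown proximity mode: {mode!r}")
            if dist <= window:
                counts[i] += 1
                counts[j] += 1
            elif mode == "gap" and pj.interval.start - pi.interval.end > window:
                # sorted by start: no later peak can be closer to i
                break
    return counts


def width_density_compare(
    peak_sets: Mapping[str, Sequence[Peak]],
    quantiles: Sequence[float] = (0.05, 0.25, 0.75, 0.95),
) -> pd.DataFrame:
    """Per-set width summaries for overlay density comparisons.

    One row per named peak set with n, mean, median, and the requested
    quantiles — the payload behind cross-factor width-distribution plots.
    """
    if not peak_sets:
        raise ValueError("at least one peak set required")
    rows = {}
    for name, peaks in peak_sets.items():
        widths = peak_widths(peaks)
        row = {
            "n": len(widths),
            "mean": int(round(float(np.mean(widths)))),
            "median": int(round(float(np.median(widths)))),
        }
        for q in quantiles:
            row[f"q{int(q * 100):02d}"] = float(np.quantile(widths, q))
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index")
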