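"""Chromatin-class enrichment of summit windows and pairwise peak-set overlap.

Each peak contributes a fixed window centered on its summit (default 100 bp:
``[summit-50, summit+50)``); the window is assigned to the chromatin class
with which it shares the most base pairs. Enrichment compares the percent of
peaks per class with the percent of the segmented genome in that class.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .genome_model import (
    CHROMATIN_CLASSES,
    Peak,
    Segmentation,
    overlapping_indices,
)

__all__ = ["class_composition", "venn_overlap"]


def _segmentation_trees(seg: Segmentation) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv, label in zip(seg.intervals, seg.labels):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, label)
    return trees


def assign_class(
    peak: Peak, trees: dict[str, IntervalTree], summit_window: int
) -> str | None:
    """Class with maximal bp overlap of the summit-centered window, or None
    when the window misses the segmentation entirely. Ties resolve in the
    fixed class order RED > YELLOW > BLUE > GREEN > BLACK."""
    half = summit_window // 2
    lo = max(0, peak.summit - half)
    hi = lo + summit_window
    tree = trees.get(peak.chrom)
    if tree is None:
        return None
    overlap_bp = {c: 0 for c in CHROMATIN_CLASSES}
    for hit in tree.overlap(lo, hi):
        overlap_bp[hit.data] += min(hi, hit.end) - max(lo, hit.begin)
    best = max(overlap_bp.values())
    if best == 0:
        return None
    return next(c for c in CHROMATIN_CLASSES if overlap_bp[c] == best)


def class_composition(
    peaks: Sequence[Peak], segmentation: Segmentation, summit_window: int = 100
) -> pd.DataFrame:
    """Chromatin-class composition and enrichment of a peak set.

    One row per class with ``peak_percent`` (share of assigned peaks whose
    summit window falls in the class), ``genome_percent`` (share of segmented
    bp) and their ratio (``enrichment``; 1 = no enrichment). Both percent
    columns sum to 100; peaks whose window misses the segmentation are counted
    in the ``n_unassigned`` attribute.
    """
    if summit_window <= 0:
        raise ValueError("summit_window must be positive")
    total_bp = segmentation.total_basepairs()
    if total_bp == 0:
        raise ValueError("segmentation covers no base pairs")
    trees = _segmentation_trees(segmentation)
    counts = {c: 0 for c in CHROMATIN_CLASSES}
    unassigned = 0
    for p in peaks:
        cls = assign_class(p, trees, summit_window)
        if cls is None:
            unassigned += 1
        else:
            counts[cls] += 1
    assigned = sum(counts.values())
    if assigned == 0:
        raise ValueError("no peak summit window overlaps the segmentation")
    class_bp = segmentation.class_basepairs()
    rows = []
    for c in CHROMATIN_CLASSES:
        peak_pct = 100.0 * counts[c] / assigned
        genome_pct = 100.0 * class_bp[c] / total_bp
        rows.append(
            {
                "class": c,
                "n_peaks": counts[c],
                "peak_percent": peak_pct,
                "genome_percent": genome_pct,
                "enrichment": peak_pct / genome_pct if genome_pct > 0 else float("nan"),
            }
        )
    df = pd.DataFrame(rows).set_index("class")
    df.attrs["n_unassigned"] = unassigned
    return df


def venn_overlap(peaks_a: Sequence[Peak], peaks_b: Sequence[Peak]) -> dict[str, int]:
    """Pairwise overlap counts between two peak sets.

    A peak of A is shared iff it overlaps >= 1 peak of B (and symmetrically);
    the two directional shared counts can differ when peaks split or merge
    across sets, so both are reported. ``a_only + shared_from_a == |A|``.
    """
    shared_a = overlapping_indices(peaks_a, peaks_b)
    shared_b = overlapping_indices(peaks_b, peaks_a)
    return {
        "a_total": len(peaks_a),
        "b_total": len(peaks_b),
        "shared_from_a": len(shared_a),
        "shared_from_b": len(shared_b),
        "a_only": len(peaks_a) - len(shared_a),
        "b_only": len(peaks_b) - len(shared_b),
    }
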