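"""Replicate concordance by maximum percent overlap of ranked peak lists.

Biological replicates of a ChIP experiment are compared by ranking each peak
list by significance (descending -log10 p), measuring the percent overlap
between the top-r peaks of both lists across a grid of ranks r, and taking the
rank r* that maximizes the overlap as the cutoff. Peaks of the reference list
above the cutoff that overlap the other list's top-r* form the consensus; a
"superset" of high-confidence peaks is the subset of a reference list that
overlaps every one of several other lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome_model import Peak, overlapping_indices

__all__ = [
    "OverlapCurve",
    "rank_peaks",
    "percent_overlap_directional",
    "percent_overlap_at_rank",
    "default_rank_grid",
    "max_overlap_cutoff",
    "consensus_peaks",
    "superset",
]


@dataclass(frozen=True)
class OverlapCurve:
    """Percent overlap as a function of rank, with the selected cutoff.

    ``cutoff_rank`` is the smallest rank attaining the maximum of ``percent``.
    """

    ranks: tuple[int, ...]
    percent: tuple[float, ...]
    cutoff_rank: int

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.ranks, self.ranks[1:])):
            raise ValueError("ranks must be strictly increasing")
        if any(not (0.0 <= p <= 100.0) for p in self.percent):
            raise ValueError("percent values must lie in [0, 100]")
        if self.cutoff_rank not in self.ranks:
            raise ValueError("cutoff_rank must be one of the evaluated ranks")

    @property
    def max_percent(self) -> float:
        return max(self.percent)


def rank_peaks(peaks: Sequence[Peak]) -> list[Peak]:
    """Order peaks by descending significance, ties by (chrom, start).

    The tie rule makes the ranking stable and reproducible across runs and
    platforms. Idempotent on already-ranked input.
    """
    return sorted(
        peaks,
        key=lambda p: (-p.neg_log10_p, p.interval.chrom, p.interval.start),
    )


def percent_overlap_directional(
    ranked_a: Sequence[Peak], ranked_b: Sequence[Peak], r: int
) -> tuple[float, float]:
    """One-directional percent overlaps (A-in-B, B-in-A) at rank ``r``."""
    if not (1 <= r <= min(len(ranked_a), len(ranked_b))):
        raise ValueError(
            f"rank {r} out of range 1..{min(len(ranked_a), len(ranked_b))}"
        )
    top_a, top_b = ranked_a[:r], ranked_b[:r]
    a_hit = len(overlapping_indices(top_a, top_b))
    b_hit = len(overlapping_indices(top_b, top_a))
    return 100.0 * a_hit / r, 100.0 * b_hit / r


def percent_overlap_at_rank(
    ranked_a: Sequence[Peak], ranked_b: Sequence[Peak], r: int
) -> float:
    """Symmetric percent overlap at rank ``r``.

    Mean of the two directional overlaps, removing any list-size asymmetry:
    ``O(r) = 100/2 * (|topA(r) hit by topB(r)|/r + |topB(r) hit by topA(r)|/r)``.
    """
    fwd, rev = percent_overlap_directional(ranked_a, ranked_b, r)
    return 0.5 * (fwd + rev)


def default_rank_grid(n_a: int, n_b: int, n_points: int = 50) -> list[int]:
    """Evenly spaced ranks from min(100, m) to m where m = min(n_a, n_b)."""
    m = min(n_a, n_b)
    if m < 1:
        raise ValueError("both peak lists must be non-empty")
    lo = min(100, m)
    grid = np.unique(np.linspace(lo, m, num=min(n_points, m - lo + 1)).astype(int))
    return [int(r) for r in grid]


def max_overlap_cutoff(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    rank_grid: Sequence[int] | None = None,
) -> OverlapCurve:
    """Evaluate the overlap curve on a rank grid and select the cutoff.

    The cutoff is the smallest grid rank attaining the maximum percent overlap
    (ties resolved toward the more stringent list).
    """
    ranked_a, ranked_b = rank_peaks(peaks_a), rank_peaks(peaks_b)
    if rank_grid is None:
        rank_grid = default_rank_grid(len(ranked_a), len(ranked_b))
    grid = sorted(set(int(r) for r in rank_grid))
    if not grid:
        raise ValueError("rank grid is empty")
    percent = [percent_overlap_at_rank(ranked_a, ranked_b, r) for r in grid]
    best = max(percent)
    cutoff = next(r for r, p in zip(grid, percent) if p == best)
    return OverlapCurve(tuple(grid), tuple(percent), cutoff)


def consensus_peaks(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    curve: OverlapCurve,
    mode: str = "reference",
) -> list[Peak]:
    """Peaks present in both replicates at the selected cutoff.

    Takes the top-r* peaks of the reference list A that overlap at least one of
    the top-r* peaks of B. Coordinates come from A (``mode="reference"``,
    keeping a well-defined summit); ``mode="union"`` widens each consensus peak
    to the union span with its overlapping partners in B.
    """
    ranked_a = rank_peaks(peaks_a)[: curve.cutoff_rank]
    ranked_b = rank_peaks(peaks_b)[: curve.cutoff_rank]
    hits = overlapping_indices(ranked_a, ranked_b)
    result = [ranked_a[i] for i in sorted(hits)]
    if mode == "reference":
        return result
    if mode == "union":
        from dataclasses import replace

        from .genome_model import GenomicInterval, overlap_pairs

        pairs = overlap_pairs(result, ranked_b)
        out = []
        for i, peak in enumerate(result):
            partners = [ranked_b[j].interval for (a, j) in pairs if a == i]
            start = min([peak.interval.start] + [iv.start for iv in partners])
            end = max([peak.interval.end] + [iv.end for iv in partners])
            iv = GenomicInterval(peak.chrom, start, end)
            out.append(
                replace(
                    peak,
                    interval=iv,
                    summit_offset=peak.summit - start,
                )
            )
        return out
    raise ValueError(f"unknown consensus mode: {mode!r}")


def superset(
    reference: Sequence[Peak], others: Sequence[Sequence[Peak]]
) -> list[Peak]:
    """Reference peaks overlapping at least one peak in *every* other list.

    The high-confidence subset of the reference common to all datasets; its
    size is non-increasing as lists are added.
    """
    if not others:
        raise ValueError("superset requires at least one other peak list")
    keep = set(range(len(reference)))
    for other in others:
        keep &= overlapping_indices(reference, other)
        if not keep:
            break
    return [reference[i] for i in sorted(keep)]
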