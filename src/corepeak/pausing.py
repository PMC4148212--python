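"""Promoter-proximal RNAP II pausing: per-transcript pause ratios, decile
classification, and decile enrichment of peak-bound transcripts.

The pause ratio (pausing index) of a transcript is the density of polymerase
signal in a short TSS-proximal window divided by the density over the
remaining gene body; high values indicate promoter-proximal pausing. Both
windows run in transcription direction: the TSS window is ``[TSS, TSS+250)``
and the gene body everything from the end of that window to the TES. A
pseudocount in both windows keeps the ratio finite on empty windows; the
density (counts per bp) form makes ratios comparable across transcript
lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .annotation import AnnotationRecord
from .genome_model import BinnedTrack, Transcript

__all__ = [
    "PauseRecord",
    "pause_ratio",
    "pause_ratios",
    "pause_deciles",
    "peak_pause_enrichment",
]


@dataclass(frozen=True)
class PauseRecord:
    transcript_id: str
    tss_count: float
    body_count: float
    pause_ratio: float | None
    usable: bool


def _windows(transcript: Transcript, tss_window: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """Genomic (start, end) of the TSS window and gene body, strand-aware."""
    iv = transcript.interval
    if transcript.strand == "+":
        tss_win = (iv.start, iv.start + tss_window)
        body = (iv.start + tss_window, iv.end)
    else:
        tss_win = (iv.end - tss_window, iv.end)
        body = (iv.start, iv.end - tss_window)
    return tss_win, body


def pause_ratio(
    track: BinnedTrack,
    transcript: Transcript,
    tss_window: int = 250,
    min_body: int = 500,
    pseudocount: float = 1.0,
) -> PauseRecord:
    """Pause ratio of one transcript from a binned polymerase track.

    ``PR = ((tss_count + eps) / tss_window) / ((body_count + eps) / body_len)``
    with counts summed (fractionally at bin edges) over the strand-aware
    windows. Transcripts shorter than ``tss_window + min_body`` are marked
    unusable and excluded from decile analyses; uniform coverage gives PR
    close to 1.
    """
    usable = transcript.length > tss_window + min_body
    (t0, t1), (b0, b1) = _windows(transcript, tss_window)
    tss_count = track.window_sum(transcript.chrom, t0, t1)
    body_count = track.window_sum(transcript.chrom, b0, b1)
    if not usable:
        return PauseRecord(transcript.transcript_id, tss_count, body_count, None, False)
    body_len = b1 - b0
    pr = ((tss_count + pseudocount) / tss_window) / (
        (body_count + pseudocount) / body_len
    )
    return PauseRecord(transcript.transcript_id, tss_count, body_count, pr, True)


def pause_ratios(
    track: BinnedTrack,
    transcripts: Sequence[Transcript],
    tss_window: int = 250,
    min_body: int = 500,
    pseudocount: float = 1.0,
) -> list[PauseRecord]:
    return [
        pause_ratio(track, t, tss_window, min_body, pseudocount) for t in transcripts
    ]


def pause_deciles(
    records: Sequence[PauseRecord], n_quantiles: int = 10
) -> dict[str, int]:
    """Quantile class (1..n, n = most paused) per usable transcript.

    Transcripts are ranked by pause ratio (ties broken by transcript id, so
    degenerate inputs still yield balanced classes) and split into
    ``n_quantiles`` groups of ``n/10 +- 1``. Invariant under any monotone
    transform of the ratios.
    """
    usable = [r for r in records if r.usable]
    if len(usable) < n_quantiles:
        raise ValueError(
            f"need >= {n_quantiles} usable transcripts, got {len(usable)}"
        )
    ranked = sorted(usable, key=lambda r: (r.pause_ratio, r.transcript_id))
    n = len(ranked)
    return {
        r.transcript_id: min(n_quantiles, pos * n_quantiles // n + 1)
        for pos, r in enumerate(ranked)
    }


def peak_pause_enrichment(
    tss_annotations: Sequence[AnnotationRecord],
    deciles: Mapping[str, int],
    n_quantiles: int = 10,
) -> dict[int, float]:
    """Percent of peak-bound transcripts falling in each pausing decile.

    ``tss_annotations`` are annotation records of peaks overlapping TSSs
    (category ``overlapStart``) against the same transcript set the deciles
    were computed from. Percentages are over distinct peak-bound transcripts
    with a decile assignment and sum to 100; a uniformly random peak set is
    flat near ``100/n`` per decile.
    """
    bound = {
        r.transcript_id
        for r in tss_annotations
        if r.assigned and r.category == "overlapStart" and r.transcript_id in deciles
    }
    if not bound:
        raise ValueError("no peak-associated transcripts with decile assignment")
    counts = np.zeros(n_quantiles, dtype=int)
    for tid in bound:
        counts[deciles[tid] - 1] += 1
    return {d + 1: 100.0 * counts[d] / len(bound) for d in range(n_quantiles)}
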