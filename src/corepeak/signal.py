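"""Binned-signal operations: upper-quantile normalization, anchored
meta-profiles, width-ordered heatmap matrices and locus profiles.

All operations work on :class:`~corepeak.genome_model.BinnedTrack` objects
(fixed 100 bp bins by default). Normalization rescales each sample so that a
high quantile (default 0.95) of its nonzero bin counts matches across samples
— robust to the zero-dominated background of a sparse genome. Profiles are
anchored at peak summits (or transcript TSSs), optionally mirrored for anchors
whose nearest transcript is on the minus strand so that "downstream" always
points right.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import BinnedTrack, GenomicInterval, Peak, Transcript

__all__ = [
    "upper_quantile_normalize",
    "meta_profile",
    "heatmap_matrix",
    "locus_profile",
]


def _track_quantile(track: BinnedTrack, q: float, nonzero: bool) -> float:
    values = track.all_values()
    if nonzero:
        values = values[values > 0]
    if len(values) == 0:
        raise ValueError("track has no nonzero bins; cannot normalize")
    return float(np.quantile(values, q))


def upper_quantile_normalize(
    tracks: Mapping[str, BinnedTrack],
    q: float = 0.95,
    nonzero: bool = True,
) -> tuple[dict[str, BinnedTrack], dict[str, float]]:
    """Upper-quantile normalization across samples.

    Each track t is scaled by ``s_t = Q_ref / Q_t`` where ``Q_t`` is the
    q-quantile of its nonzero bin counts (all bins if ``nonzero=False``) and
    ``Q_ref`` the geometric mean of the per-track quantiles — a reference
    symmetric in the samples. After scaling all tracks share the same
    q-quantile. Scale-equivariant: pre-multiplying a track by c does not change
    its normalized output.

    Returns ``(scaled_tracks, scale_factors)``.
    """
    if not tracks:
        raise ValueError("no tracks given")
    quantiles = {name: _track_quantile(t, q, nonzero) for name, t in tracks.items()}
    log_q = [np.log(v) for v in quantiles.values()]
    q_ref = float(np.exp(np.mean(log_q)))
    factors = {name: q_ref / qt for name, qt in quantiles.items()}
    scaled = {name: tracks[name].scaled(factors[name]) for name in tracks}
    return scaled, factors


def _anchor_positions(anchors: Sequence) -> list[tuple[str, int]]:
    """Anchor coordinates: summit for peaks, TSS for transcripts."""
    out = []
    for a in anchors:
        if isinstance(a, Peak):
            out.append((a.chrom, a.summit))
        elif isinstance(a, Transcript):
            out.append((a.chrom, a.tss))
        else:
            chrom, pos = a
            out.append((chrom, int(pos)))
    return out


def _anchor_strands(
    anchors: Sequence, strand_source: Sequence[Transcript] | None
) -> list[str]:
    """Strand per anchor: its own strand for transcripts, else the strand of
    the nearest transcript TSS in ``strand_source`` ('+' when no source)."""
    strands = []
    for a in anchors:
        if isinstance(a, Transcript):
            strands.append(a.strand)
        elif strand_source:
            pos = a.summit if isinstance(a, Peak) else int(a[1])
            chrom = a.chrom if isinstance(a, Peak) else a[0]
            nearby = [t for t in strand_source if t.chrom == chrom]
            if nearby:
                t = min(nearby, key=lambda t: (abs(pos - t.tss), t.transcript_id))
                strands.append(t.strand)
            else:
                strands.append("+")
        else:
            strands.append("+")
    return strands


def _extract_windows(
    track: BinnedTrack,
    anchors: Sequence,
    flank: int,
    strand_source: Sequence[Transcript] | None,
) -> tuple[np.ndarray, list[int], int]:
    """Per-anchor signal windows of ``2*flank/bin + 1`` bins centered on the
    anchor bin, minus-strand windows reversed. Returns (matrix, kept_indices,
    n_dropped)."""
    if flank % track.bin_size != 0:
        raise ValueError("flank must be a multiple of the bin size")
    half = flank // track.bin_size
    positions = _anchor_positions(anchors)
    strands = _anchor_strands(anchors, strand_source)
    rows, kept = [], []
    dropped = 0
    for idx, ((chrom, pos), strand) in enumerate(zip(positions, strands)):
        if chrom not in track.counts:
            dropped += 1
            continue
        center = pos // track.bin_size
        lo, hi = center - half, center + half + 1
        if lo < 0 or hi > track.n_bins(chrom):
            dropped += 1
            continue
        window = track.counts[chrom][lo:hi]
        if strand == "-":
            window = window[::-1]
        rows.append(window)
        kept.append(idx)
    if not rows:
        raise ValueError("no usable anchors (all dropped at chromosome edges)")
    return np.vstack(rows), kept, dropped


def meta_profile(
    track: BinnedTrack,
    anchors: Sequence,
    flank: int,
    strand_source: Sequence[Transcript] | None = None,
) -> dict:
    """Average signal around anchors.

    Anchors are peak summits, transcript TSSs, or raw ``(chrom, pos)`` pairs.
    The profile covers ``[-flank, +flank]`` in bin-centered offsets; windows of
    anchors assigned to minus-strand transcripts are mirrored before averaging
    so transcription direction is consistent. Anchors whose window leaves the
    chromosome are dropped and counted.

    Returns ``{"offsets", "mean", "n_used", "n_dropped"}``.
    """
    matrix, kept, dropped = _extract_windows(track, anchors, flank, strand_source)
    half = flank // track.bin_size
    offsets = np.arange(-half, half + 1) * track.bin_size
    return {
        "offsets": offsets,
        "mean": matrix.mean(axis=0),
        "n_used": len(kept),
        "n_dropped": dropped,
    }


def heatmap_matrix(
    track: BinnedTrack,
    peaks: Sequence[Peak],
    flank: int = 500,
    order: str = "width",
    anchor: str = "summit",
) -> dict:
    """Per-peak signal windows as a matrix, rows ordered by descending width.

    ``anchor="summit"`` centers windows on peak summits (so column means equal
    the corresponding meta-profile); ``anchor="center"`` uses the interval
    midpoint. Ties in width are broken by genomic position.

    Returns ``{"matrix", "offsets", "peak_names", "n_dropped"}``.
    """
    if anchor == "summit":
        anchor_items: Sequence = peaks
    elif anchor == "center":
        anchor_items = [
            (p.chrom, (p.interval.start + p.interval.end) // 2) for p in peaks
        ]
    else:
        raise ValueError(f"unknown anchor mode: {anchor!r}")
    matrix, kept, dropped = _extract_windows(track, anchor_items, flank, None)
    kept_peaks = [peaks[i] for i in kept]
    if order == "width":
        perm = sorted(
            range(len(kept_peaks)),
            key=lambda i: (
                -kept_peaks[i].width,
                kept_peaks[i].chrom,
                kept_peaks[i].interval.start,
            ),
        )
    elif order == "none":
        perm = list(range(len(kept_peaks)))
    else:
        raise ValueError(f"unknown row order: {order!r}")
    half = flank // track.bin_size
    return {
        "matrix": matrix[perm],
        "offsets": np.arange(-half, half + 1) * track.bin_size,
        "peak_names": [kept_peaks[i].name for i in perm],
        "n_dropped": dropped,
    }


def locus_profile(
    tracks: Mapping[str, BinnedTrack | Sequence[BinnedTrack]],
    region: GenomicInterval,
) -> pd.DataFrame:
    """Exact per-bin values of each track over a genomic region.

    Track values may be single tracks or lists of replicate tracks, in which
    case the per-bin replicate mean is reported. Rows are indexed by bin start
    coordinate; the region must lie within the chromosome.
    """
    out = {}
    index = None
    for name, value in tracks.items():
        replicates = value if isinstance(value, (list, tuple)) else [value]
        vectors = []
        for track in replicates:
            if region.chrom not in track.counts:
                raise ValueError(f"region chromosome {region.chrom!r} not in track")
            if region.end > track.chrom_sizes[region.chrom]:
                raise ValueError("region extends past the end of the chromosome")
            b = track.bin_size
            lo, hi = region.start // b, -(-region.end // b)
            vectors.append(track.counts[region.chrom][lo:hi])
            if index is None:
                index = np.arange(lo, hi) * b
        out[name] = np.mean(vectors, axis=0)
    return pd.DataFrame(out, index=index)
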