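"""Independent brute-force oracles used to cross-check the implementation.

Everything here is a direct quadratic (or otherwise naive) re-derivation from
first principles, deliberately sharing no code with the package internals.
"""

from __future__ import annotations


def _iv(obj):
    return obj.interval if hasattr(obj, "interval") else obj


def brute_overlap_pairs(set_a, set_b):
    """All-pairs O(n^2) scan for >=1 bp half-open overlap."""
    pairs = []
    for i, a in enumerate(set_a):
        a = _iv(a)
        for j, b in enumerate(set_b):
            b = _iv(b)
            if a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end):
                pairs.append((i, j))
    return sorted(pairs)


def brute_proximity_counts(peaks, window, mode="gap"):
    counts = [0] * len(peaks)
    for i in range(len(peaks)):
        for j in range(len(peaks)):
            if i == j or peaks[i].chrom != peaks[j].chrom:
                continue
            a, b = peaks[i].interval, peaks[j].interval
            if mode == "gap":
                dist = max(0, max(a.start, b.start) - min(a.end, b.end))
            else:
                dist = abs((a.start + a.end) / 2 - (b.start + b.end) / 2)
            if dist <= window:
                counts[i] += 1
    return counts


def brute_percent_overlap(ranked_a, ranked_b, r):
    """Symmetric mean of both one-directional overlap fractions at rank r."""
    top_a, top_b = ranked_a[:r], ranked_b[:r]
    hit_a = sum(
        1
        for a in top_a
        if any(
            a.chrom == b.chrom
            and max(a.interval.start, b.interval.start)
            < min(a.interval.end, b.interval.end)
            for b in top_b
        )
    )
    hit_b = sum(
        1
        for b in top_b
        if any(
            a.chrom == b.chrom
            and max(a.interval.start, b.interval.start)
            < min(a.interval.end, b.interval.end)
            for a in top_a
        )
    )
    return 100.0 * 0.5 * (hit_a / r + hit_b / r)


def brute_superset(reference, others):
    out = []
    for peak in reference:
        if all(
            any(
                peak.chrom == o.chrom
                and max(peak.interval.start, o.interval.start)
                < min(peak.interval.end, o.interval.end)
                for o in other
            )
            for other in others
        ):
            out.append(peak)
    return out


def brute_venn(peaks_a, peaks_b):
    shared_a = sum(
        1
        for a in peaks_a
        if any(
            a.chrom == b.chrom
            and max(a.interval.start, b.interval.start)
            < min(a.interval.end, b.interval.end)
            for b in peaks_b
        )
    )
    shared_b = sum(
        1
        for b in peaks_b
        if any(
            a.chrom == b.chrom
            and max(a.interval.start, b.interval.start)
            < min(a.interval.end, b.interval.end)
            for a in peaks_a
        )
    )
    return {
        "a_total": len(peaks_a),
        "b_total": len(peaks_b),
        "shared_from_a": shared_a,
        "shared_from_b": shared_b,
        "a_only": len(peaks_a) - shared_a,
        "b_only": len(peaks_b) - shared_b,
    }


def brute_annotate(peak, transcripts):
    """Nearest-TSS scan and geometric categorisation, rederived directly.

    Returns (category, transcript_id, signed strand-adjusted distance), or
    None when no transcript shares the peak's chromosome.
    """
    candidates = [t for t in transcripts if t.chrom == peak.chrom]
    if not candidates:
        return None
    best = None
    for t in candidates:
        tss = t.interval.start if t.strand == "+" else t.interval.end - 1
        key = (abs(peak.summit - tss), t.transcript_id)
        if best is None or key < best[0]:
            best = (key, t, tss)
    _, t, tss = best
    tes = t.interval.end - 1 if t.strand == "+" else t.interval.start
    d = peak.summit - tss if t.strand == "+" else tss - peak.summit
    a, b = peak.interval, t.interval
    if max(a.start, b.start) < min(a.end, b.end):
        if a.start <= b.start and a.end >= b.end:
            cat = "includeFeature"
        elif a.start <= tss < a.end:
            cat = "overlapStart"
        elif a.start <= tes < a.end:
            cat = "overlapEnd"
        else:
            cat = "inside"
    else:
        cat = "upstream" if d < 0 else "downstream"
    return cat, t.transcript_id, d


def random_intervals(rng, n, n_chroms=3, genome=100_000, max_len=2_000):
    """Random intervals for oracle comparisons."""
    from corepeak.genome_model import GenomicInterval

    out = []
    for _ in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, genome - max_len))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def random_peaks(rng, n, n_chroms=3, genome=100_000, max_len=2_000):
    from corepeak.genome_model import Peak

    out = []
    for k, iv in enumerate(random_intervals(rng, n, n_chroms, genome, max_len)):
        out.append(
            Peak(
                iv,
                name=f"p{k}",
                summit_offset=int(rng.integers(0, iv.width)),
                neg_log10_p=float(rng.exponential(3.0)),
            )
        )
    return out
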