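"""Core genomic data model and file I/O.

All coordinates are 0-based half-open ``[start, end)`` internally, following the
BED ecosystem convention. Spreadsheet peak tables are declared 1-based inclusive
and converted on read, so that their printed width column (``end - start + 1``)
equals the in-memory width.

The module provides the interval types used throughout the package
(:class:`GenomicInterval`, :class:`Peak`, :class:`Transcript`,
:class:`BinnedTrack`, :class:`Segmentation`), readers/writers for narrowPeak,
BED6/BED12, GTF/GFF3, bedGraph and BED4 segmentations, and the interval-overlap
engine (:func:`overlap_pairs`) every downstream stage is built on.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Peak",
    "Transcript",
    "BinnedTrack",
    "Segmentation",
    "CHROMATIN_CLASSES",
    "FormatError",
    "read_peaks",
    "write_peaks",
    "read_transcripts",
    "read_binned_track",
    "write_binned_track",
    "read_segmentation",
    "write_segmentation",
    "overlap_pairs",
    "overlapping_indices",
]

#: The five principal chromatin types of the Drosophila genome segmentation:
#: RED (active, developmentally regulated), YELLOW (active, housekeeping),
#: BLUE (Polycomb-repressed), GREEN (classic heterochromatin), BLACK (silent).
CHROMATIN_CLASSES = ("RED", "YELLOW", "BLUE", "GREEN", "BLACK")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and max(self.start, other.start) < min(
            self.end, other.end
        )


@dataclass(frozen=True)
class Peak:
    """A called binding peak: an interval plus summit offset and significance.

    ``summit_offset`` is the distance in bp from ``interval.start`` to the
    position of maximal signal; ``neg_log10_p`` is the -log10 p-value assigned
    by the peak caller. ``declared_width`` carries an explicit width column from
    a source table when one was present (it then takes precedence over
    ``end - start`` in width statistics).
    """

    interval: GenomicInterval
    name: str = ""
    summit_offset: int = 0
    neg_log10_p: float = 0.0
    score: float = 0.0
    declared_width: int | None = None
    summit_imputed: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.summit_offset < self.interval.width):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside peak of width "
                f"{self.interval.width} ({self.name!r})"
            )
        if not (math.isfinite(self.neg_log10_p) and self.neg_log10_p >= 0):
            raise ValueError(f"neg_log10_p must be finite and >= 0 ({self.name!r})")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def summit(self) -> int:
        """Absolute genomic position of the summit."""
        return self.interval.start + self.summit_offset

    @property
    def width(self) -> int:
        """Peak width in bp; honors an explicit table width column if present."""
        return self.declared_width if self.declared_width is not None else self.interval.width


@dataclass(frozen=True)
class Transcript:
    """A stranded transcript interval.

    TSS is the 5' end in transcription direction: ``start`` on the plus strand
    and ``end - 1`` on the minus strand; the TES is the opposite end.
    """

    interval: GenomicInterval
    strand: str
    transcript_id: str
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    @property
    def length(self) -> int:
        return self.interval.width


class BinnedTrack:
    """Fixed-width binned coverage: one non-negative count vector per chromosome.

    Bin ``i`` covers ``[i*bin_size, (i+1)*bin_size)``; each vector has length
    ``ceil(chrom_size / bin_size)``.
    """

    def __init__(
        self,
        counts: Mapping[str, np.ndarray],
        chrom_sizes: Mapping[str, int],
        bin_size: int = 100,
    ) -> None:
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.bin_size = int(bin_size)
        self.chrom_sizes = dict(chrom_sizes)
        self.counts: dict[str, np.ndarray] = {}
        for chrom, size in self.chrom_sizes.items():
            n_bins = -(-size // bin_size)
            vec = np.asarray(counts.get(chrom, np.zeros(n_bins)), dtype=float)
            if len(vec) != n_bins:
                raise ValueError(
                    f"{chrom}: expected {n_bins} bins for size {size}, got {len(vec)}"
                )
            if (vec < 0).any():
                raise ValueError(f"{chrom}: negative bin counts")
            self.counts[chrom] = vec

    def n_bins(self, chrom: str) -> int:
        return len(self.counts[chrom])

    def scaled(self, factor: float) -> "BinnedTrack":
        return BinnedTrack(
            {c: v * factor for c, v in self.counts.items()},
            self.chrom_sizes,
            self.bin_size,
        )

    def all_values(self) -> np.ndarray:
        """All bin values concatenated across chromosomes (fixed chrom order)."""
        return np.concatenate([self.counts[c] for c in sorted(self.counts)])

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of counts over ``[start, end)`` with fractional edge bins.

        Counts are treated as uniformly distributed within each bin, so a
        window covering half a bin receives half of that bin's count.
        """
        if start >= end:
            return 0.0
        vec = self.counts[chrom]
        b = self.bin_size
        lo = max(0, start // b)
        hi = min(len(vec), -(-end // b))
        total = 0.0
        for i in range(lo, hi):
            bin_start, bin_end = i * b, (i + 1) * b
            frac = (min(end, bin_end) - max(start, bin_start)) / b
            total += vec[i] * frac
        return total


@dataclass
class Segmentation:
    """A chromatin-class segmentation: disjoint labelled intervals."""

    intervals: list[GenomicInterval]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.labels):
            raise ValueError("intervals and labels must have equal length")
        bad = set(self.labels) - set(CHROMATIN_CLASSES)
        if bad:
            raise ValueError(f"unknown segmentation labels: {sorted(bad)}")
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs = sorted(ivs, key=lambda i: i.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValueError(f"segmentation intervals overlap on {chrom}")

    def class_basepairs(self) -> dict[str, int]:
        """Total bp per class over the segmented genome."""
        bp = {c: 0 for c in CHROMATIN_CLASSES}
        for iv, label in zip(self.intervals, self.labels):
            bp[label] += iv.width
        return bp

    def total_basepairs(self) -> int:
        return sum(iv.width for iv in self.intervals)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_DEFAULT_XLS_COLUMNS = {
    "chrom": "chrom",
    "start": "start",
    "end": "end",
    "name": "name",
    "width": "width",
    "neg_log10_p": "neg_log10_p",
    "summit": "summit",
}


def _read_table_lines(path: str | os.PathLike) -> list[tuple[int, list[str]]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            rows.append((lineno, line.split("\t")))
    return rows


def _parse_int(value: str, what: str, path: str, lineno: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-integer {what}: {value!r}") from None


def read_peaks(
    path: str | os.PathLike,
    format: str = "narrowPeak",
    column_map: Mapping[str, str] | None = None,
) -> list[Peak]:
    """Read peaks from ``narrowPeak``, ``bed6plus`` or ``xls_table`` files.

    narrowPeak is ENCODE BED6+4 (0-based half-open; column 7 is -log10 p,
    column 10 the summit offset). ``bed6plus`` accepts any BED with >= 3
    columns; a missing summit defaults to the interval midpoint and a missing
    p-value to 0. ``xls_table`` reads a spreadsheet (xlsx via openpyxl) or
    tab/comma-separated export with a declared column map; its coordinates are
    assumed 1-based inclusive and converted, and an explicit width column is
    honored as the peak's width.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format in ("narrowPeak", "bed6plus"):
        return _read_bed_peaks(path, format)
    if format == "xls_table":
        return _read_xls_table(path, column_map or _DEFAULT_XLS_COLUMNS)
    raise ValueError(f"unknown peak format: {format!r}")


def _read_bed_peaks(path: str, format: str) -> list[Peak]:
    min_cols = 10 if format == "narrowPeak" else 3
    peaks = []
    for lineno, fields in _read_table_lines(path):
        if len(fields) < min_cols:
            raise FormatError(
                f"{path}:{lineno}: expected >= {min_cols} columns for {format}, "
                f"got {len(fields)}"
            )
        chrom = fields[0]
        start = _parse_int(fields[1], "start", path, lineno)
        end = _parse_int(fields[2], "end", path, lineno)
        if start >= end:
            raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
        name = fields[3] if len(fields) > 3 and fields[3] != "." else f"peak_{lineno}"
        score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
        width = end - start
        if format == "narrowPeak":
            neg_log10_p = float(fields[7])
            summit = _parse_int(fields[9], "summit", path, lineno)
            imputed = False
            if summit < 0:  # narrowPeak convention: -1 means no summit call
                summit, imputed = width // 2, True
        else:
            neg_log10_p, summit, imputed = 0.0, width // 2, True
        peaks.append(
            Peak(
                GenomicInterval(chrom, start, end),
                name=name,
                summit_offset=summit,
                neg_log10_p=neg_log10_p,
                score=score,
                summit_imputed=imputed,
            )
        )
    return peaks


def _read_xls_table(path: str, columns: Mapping[str, str]) -> list[Peak]:
    if path.endswith(".xls"):
        raise FormatError(
            "legacy .xls workbooks are not supported; export the sheet to "
            ".xlsx, .tsv or .csv and declare the column map"
        )
    if path.endswith(".xlsx"):
        df = pd.read_excel(path, engine="openpyxl")
    else:
        df = pd.read_csv(path, sep=None, engine="python")
    for key in ("chrom", "start", "end"):
        col = columns.get(key, key)
        if col not in df.columns:
            raise FormatError(f"{path}: required column {col!r} ({key}) missing")
    peaks = []
    for idx, row in df.iterrows():
        chrom = str(row[columns["chrom"]])
        start1 = int(row[columns["start"]])
        end1 = int(row[columns["end"]])
        if start1 > end1:
            raise FormatError(f"{path}: row {idx + 1}: start > end")
        start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
        width = end - start
        name_col = columns.get("name")
        name = (
            str(row[name_col])
            if name_col and name_col in df.columns
            else f"peak_{idx + 1}"
        )
        width_col = columns.get("width")
        declared = (
            int(row[width_col])
            if width_col and width_col in df.columns and pd.notna(row[width_col])
            else None
        )
        p_col = columns.get("neg_log10_p")
        neg_p = (
            float(row[p_col]) if p_col and p_col in df.columns and pd.notna(row[p_col]) else 0.0
        )
        summit_col = columns.get("summit")
        if summit_col and summit_col in df.columns and pd.notna(row[summit_col]):
            summit = int(row[summit_col]) - 1 - start  # absolute 1-based -> offset
            imputed = False
        else:
            summit, imputed = width // 2, True
        peaks.append(
            Peak(
                GenomicInterval(chrom, start, end),
                name=name,
                summit_offset=min(max(summit, 0), width - 1),
                neg_log10_p=neg_p,
                declared_width=declared,
                summit_imputed=imputed,
            )
        )
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str | os.PathLike, format: str = "narrowPeak") -> None:
    """Write peaks as narrowPeak (BED6+4) or BED6."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            if format == "narrowPeak":
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{int(p.score)}\t.\t"
                    f"0.0\t{p.neg_log10_p:g}\t-1\t{p.summit_offset}\n"
                )
            elif format == "bed6":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{int(p.score)}\t.\n")
            else:
                raise ValueError(f"unknown peak output format: {format!r}")


def read_transcripts(path: str | os.PathLike, format: str = "gtf") -> list[Transcript]:
    """Read transcripts from GTF, GFF3 or BED12 with mandatory strand."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format in ("gtf", "gff3"):
        return _read_gxf_transcripts(path, format)
    if format == "bed12":
        return _read_bed12_transcripts(path)
    raise ValueError(f"unknown transcript format: {format!r}")


def _read_gxf_transcripts(path: str, format: str) -> list[Transcript]:
    import gffutils

    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    transcript_types = {"transcript", "mRNA"}
    feats = [f for f in db.all_features() if f.featuretype in transcript_types]
    if not feats:  # annotation with gene records only
        feats = [f for f in db.all_features() if f.featuretype == "gene"]
    out = []
    for f in feats:
        if f.strand not in ("+", "-"):
            raise FormatError(f"{path}: transcript {f.id} lacks a +/- strand")
        tid = _first_attr(f, ["transcript_id", "ID"]) or f.id
        gid = _first_attr(f, ["gene_id", "Parent", "ID"]) or tid
        out.append(
            Transcript(
                GenomicInterval(f.seqid, f.start - 1, f.end),  # GFF is 1-based inclusive
                strand=f.strand,
                transcript_id=tid,
                gene_id=gid,
            )
        )
    return out


def _first_attr(feature, keys: list[str]) -> str | None:
    for key in keys:
        if key in feature.attributes:
            return feature.attributes[key][0]
    return None


def _read_bed12_transcripts(path: str) -> list[Transcript]:
    out = []
    for lineno, fields in _read_table_lines(path):
        if len(fields) < 6:
            raise FormatError(f"{path}:{lineno}: BED12 needs >= 6 columns")
        strand = fields[5]
        if strand not in ("+", "-"):
            raise FormatError(f"{path}:{lineno}: missing or invalid strand {strand!r}")
        out.append(
            Transcript(
                GenomicInterval(
                    fields[0],
                    _parse_int(fields[1], "start", path, lineno),
                    _parse_int(fields[2], "end", path, lineno),
                ),
                strand=strand,
                transcript_id=fields[3],
                gene_id=fields[3],
            )
        )
    return out


def write_transcripts(
    transcripts: Sequence[Transcript], path: str | os.PathLike, format: str = "gtf"
) -> None:
    """Write transcripts as GTF (1-based inclusive) or BED12 stub (6 columns)."""
    with open(path, "w") as fh:
        for t in transcripts:
            iv = t.interval
            if format == "gtf":
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{iv.chrom}\tcorepeak\ttranscript\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )
            elif format == "bed12":
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{t.transcript_id}\t0\t{t.strand}\n"
                )
            else:
                raise ValueError(f"unknown transcript output format: {format!r}")


def read_binned_track(
    path: str | os.PathLike,
    bin_size: int,
    chrom_sizes: Mapping[str, int],
    resample: bool = False,
) -> BinnedTrack:
    """Read a bedGraph into a dense :class:`BinnedTrack`.

    Every record must align to the bin grid unless ``resample`` is set, in
    which case values are distributed over bins proportionally to overlap.
    Overlapping records are rejected; uncovered regions are zero.
    """
    path = os.fspath(path)
    counts = {c: np.zeros(-(-s // bin_size)) for c, s in chrom_sizes.items()}
    covered = {c: np.zeros(-(-s // bin_size), dtype=bool) for c, s in chrom_sizes.items()}
    for lineno, fields in _read_table_lines(path):
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
        chrom = fields[0]
        if chrom not in counts:
            raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        start = _parse_int(fields[1], "start", path, lineno)
        end = _parse_int(fields[2], "end", path, lineno)
        value = float(fields[3])
        if start >= end:
            raise FormatError(f"{path}:{lineno}: start >= end")
        # the last bin may be truncated by the chromosome end
        aligned = start % bin_size == 0 and (
            end % bin_size == 0 or end == chrom_sizes[chrom]
        )
        if not aligned and not resample:
            raise FormatError(
                f"{path}:{lineno}: interval [{start},{end}) not aligned to "
                f"{bin_size} bp bins (pass resample=True to redistribute)"
            )
        lo, hi = start // bin_size, -(-end // bin_size)
        if covered[chrom][lo:hi].any():
            raise FormatError(f"{path}:{lineno}: overlapping bedGraph records")
        covered[chrom][lo:hi] = True
        if aligned:
            counts[chrom][lo:hi] = value
        else:
            for i in range(lo, hi):
                frac = (min(end, (i + 1) * bin_size) - max(start, i * bin_size)) / bin_size
                counts[chrom][i] = value * frac
    return BinnedTrack(counts, chrom_sizes, bin_size)


def write_binned_track(track: BinnedTrack, path: str | os.PathLike) -> None:
    """Write a BinnedTrack as bedGraph, merging equal-valued adjacent bins."""
    with open(path, "w") as fh:
        for chrom in sorted(track.counts):
            vec = track.counts[chrom]
            size = track.chrom_sizes[chrom]
            i = 0
            while i < len(vec):
                j = i
                while j + 1 < len(vec) and vec[j + 1] == vec[i]:
                    j += 1
                if vec[i] != 0:
                    start = i * track.bin_size
                    end = min((j + 1) * track.bin_size, size)
                    fh.write(f"{chrom}\t{start}\t{end}\t{vec[i]:g}\n")
                i = j + 1


def read_segmentation(path: str | os.PathLike) -> Segmentation:
    """Read a BED4 chromatin segmentation (name column = class label)."""
    intervals, labels = [], []
    for lineno, fields in _read_table_lines(path):
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: segmentation BED needs 4 columns")
        intervals.append(
            GenomicInterval(
                fields[0],
                _parse_int(fields[1], "start", path, lineno),
                _parse_int(fields[2], "end", path, lineno),
            )
        )
        labels.append(fields[3].upper())
    return Segmentation(intervals, labels)


def write_segmentation(seg: Segmentation, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv, label in zip(seg.intervals, seg.labels):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\n")


# ---------------------------------------------------------------------------
# Overlap engine
# ---------------------------------------------------------------------------


def _as_interval(obj) -> GenomicInterval:
    return obj.interval if hasattr(obj, "interval") else obj


def _build_trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for idx, iv in enumerate(intervals):
        iv = _as_interval(iv)
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)
    return trees


def overlap_pairs(
    set_a: Sequence[GenomicInterval | Peak],
    set_b: Sequence[GenomicInterval | Peak],
) -> list[tuple[int, int]]:
    """All index pairs ``(i, j)`` where ``set_a[i]`` and ``set_b[j]`` share >= 1 bp.

    Overlap is strict half-open intersection on the same chromosome:
    ``max(startA, startB) < min(endA, endB)``. The result is complete and
    sorted; empty inputs give an empty list.
    """
    trees = _build_trees(set_b)
    pairs = []
    for i, item in enumerate(set_a):
        iv = _as_interval(item)
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            pairs.append((i, hit.data))
    return sorted(pairs)


def overlapping_indices(
    set_a: Sequence[GenomicInterval | Peak],
    set_b: Sequence[GenomicInterval | Peak],
) -> set[int]:
    """Indices of elements of ``set_a`` overlapping at least one element of ``set_b``."""
    trees = _build_trees(set_b)
    out = set()
    for i, item in enumerate(set_a):
        iv = _as_interval(item)
        tree = trees.get(iv.chrom)
        if tree is not None and tree.overlaps(iv.start, iv.end):
            out.add(i)
    return out
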