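"""Data model invariants, format round-trips and the overlap engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_overlap_pairs, random_intervals
from corepeak.genome_model import (
    BinnedTrack,
    FormatError,
    GenomicInterval,
    Peak,
    Segmentation,
    overlap_pairs,
    read_binned_track,
    read_peaks,
    read_segmentation,
    read_transcripts,
    write_binned_track,
    write_peaks,
    write_segmentation,
    write_transcripts,
)
from conftest import make_peak, make_transcript


class TestIntervalModel:
    def test_interval_invariants(self):
        iv = GenomicInterval("chr2L", 100, 200)
        assert iv.width == 100
        with pytest.raises(ValueError):
            GenomicInterval("chr2L", 200, 200)
        with pytest.raises(ValueError):
            GenomicInterval("chr2L", -1, 200)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 200)

    def test_peak_invariants(self):
        with pytest.raises(ValueError):
            Peak(GenomicInterval("c", 0, 100), summit_offset=100)
        with pytest.raises(ValueError):
            Peak(GenomicInterval("c", 0, 100), neg_log10_p=-1.0)
        with pytest.raises(ValueError):
            Peak(GenomicInterval("c", 0, 100), neg_log10_p=float("nan"))

    def test_transcript_strand_geometry(self):
        plus = make_transcript("c", 2000, 3000, "+")
        minus = make_transcript("c", 2000, 3000, "-")
        assert (plus.tss, plus.tes) == (2000, 2999)
        assert (minus.tss, minus.tes) == (2999, 2000)
        with pytest.raises(ValueError):
            make_transcript("c", 0, 10, ".")


class TestPeakIO:
    def test_narrowpeak_field_mapping(self, tmp_path):
        path = tmp_path / "a.narrowPeak"
        path.write_text("chr2L\t1000\t1500\tp1\t100\t.\t5.0\t8.0\t6.0\t250\n")
        (peak,) = read_peaks(path, "narrowPeak")
        assert (peak.interval.start, peak.interval.end) == (1000, 1500)
        assert peak.summit_offset == 250
        assert peak.summit == 1250
        assert peak.neg_log10_p == 8.0

    def test_bed6_summit_defaults_to_midpoint(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chr2L\t100\t800\tp1\t0\t.\n")
        (peak,) = read_peaks(path, "bed6plus")
        assert peak.summit_offset == 350
        assert peak.summit_imputed

    def test_malformed_line_error_names_line_number(self, tmp_path):
        path = tmp_path / "a.narrowPeak"
        path.write_text(
            "chr2L\t1000\t1500\tp1\t100\t.\t5.0\t8.0\t6.0\t250\n"
            "chr2L\tnope\t1500\tp2\t100\t.\t5.0\t8.0\t6.0\t250\n"
        )
        with pytest.raises(FormatError, match=":2"):
            read_peaks(path, "narrowPeak")

    def test_inverted_coordinates_rejected(self, tmp_path):
        path = tmp_path / "a.narrowPeak"
        path.write_text("chr2L\t1500\t1000\tp1\t100\t.\t5.0\t8.0\t6.0\t250\n")
        with pytest.raises(FormatError, match="start >= end"):
            read_peaks(path, "narrowPeak")

    def test_unknown_format_rejected(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chr2L\t0\t10\n")
        with pytest.raises(ValueError, match="unknown peak format"):
            read_peaks(path, "wig")

    def test_spreadsheet_table_one_based_conversion(self, tmp_path):
        # 1-based inclusive table: [1001, 1500] has printed width 500
        path = tmp_path / "peaks.tsv"
        path.write_text(
            "chrom\tstart\tend\tname\twidth\tneg_log10_p\n"
            "chr2L\t1001\t1500\tgro1\t500\t12.5\n"
        )
        (peak,) = read_peaks(path, "xls_table")
        assert (peak.interval.start, peak.interval.end) == (1000, 1500)
        assert peak.width == 500
        assert peak.declared_width == 500
        assert peak.neg_log10_p == 12.5

    def test_spreadsheet_width_column_takes_precedence(self, tmp_path):
        path = tmp_path / "peaks.tsv"
        path.write_text("chrom\tstart\tend\twidth\nchr2L\t1001\t1500\t501\n")
        (peak,) = read_peaks(path, "xls_table")
        assert peak.interval.width == 500
        assert peak.width == 501  # the table's explicit width column wins

    def test_xlsx_workbook_roundtrip(self, tmp_path):
        import pandas as pd

        path = tmp_path / "peaks.xlsx"
        pd.DataFrame(
            {"chrom": ["chr3R"], "start": [11], "end": [110], "name": ["p"]}
        ).to_excel(path, index=False)
        (peak,) = read_peaks(path, "xls_table")
        assert (peak.interval.start, peak.interval.end) == (10, 110)

    def test_legacy_xls_gives_informative_error(self, tmp_path):
        path = tmp_path / "peaks.xls"
        path.write_text("binary-ish")
        with pytest.raises(FormatError, match="export the sheet"):
            read_peaks(path, "xls_table")

    def test_write_read_roundtrip(self, tmp_path):
        peaks = [
            make_peak("chr2L", 100, 900, name="a", summit=300, p=9.0),
            make_peak("chrX", 5000, 5400, name="b", p=4.0),
        ]
        path = tmp_path / "out.narrowPeak"
        write_peaks(peaks, path)
        back = read_peaks(path, "narrowPeak")
        assert [(p.chrom, p.interval.start, p.interval.end, p.name, p.summit_offset, p.neg_log10_p) for p in back] == [
            (p.chrom, p.interval.start, p.interval.end, p.name, p.summit_offset, p.neg_log10_p) for p in peaks
        ]


class TestTranscriptIO:
    def test_gtf_roundtrip_and_strand_rule(self, tmp_path):
        txs = [
            make_transcript("c", 2000, 3000, "+", "plus_tx"),
            make_transcript("c", 2000, 3000, "-", "minus_tx"),
        ]
        path = tmp_path / "genes.gtf"
        write_transcripts(txs, path)
        back = read_transcripts(path, "gtf")
        by_id = {t.transcript_id: t for t in back}
        assert by_id["plus_tx"].tss == 2000
        assert by_id["minus_tx"].tss == 2999
        assert by_id["minus_tx"].interval.start == 2000

    def test_bed12_preserves_ids(self, tmp_path):
        path = tmp_path / "genes.bed"
        path.write_text("c\t0\t100\ttx1\t0\t+\nc\t200\t400\ttx2\t0\t-\n")
        back = read_transcripts(path, "bed12")
        assert [t.transcript_id for t in back] == ["tx1", "tx2"]

    def test_missing_strand_rejected(self, tmp_path):
        path = tmp_path / "genes.bed"
        path.write_text("c\t0\t100\ttx1\t0\t.\n")
        with pytest.raises(FormatError, match="strand"):
            read_transcripts(path, "bed12")


class TestBinnedTrackIO:
    def test_dense_vector_with_zeros_elsewhere(self, tmp_path):
        path = tmp_path / "t.bedGraph"
        path.write_text("c\t0\t200\t3\nc\t200\t300\t1\n")
        track = read_binned_track(path, 100, {"c": 1000})
        assert track.n_bins("c") == 10
        assert list(track.counts["c"]) == [3, 3, 1, 0, 0, 0, 0, 0, 0, 0]

    def test_overlapping_records_rejected(self, tmp_path):
        path = tmp_path / "t.bedGraph"
        path.write_text("c\t0\t200\t3\nc\t100\t300\t1\n")
        with pytest.raises(FormatError, match="overlapping"):
            read_binned_track(path, 100, {"c": 1000})

    def test_misaligned_record_needs_resample_flag(self, tmp_path):
        path = tmp_path / "t.bedGraph"
        path.write_text("c\t50\t250\t2\n")
        with pytest.raises(FormatError, match="not aligned"):
            read_binned_track(path, 100, {"c": 1000})
        track = read_binned_track(path, 100, {"c": 1000}, resample=True)
        assert list(track.counts["c"][:3]) == [1.0, 2.0, 1.0]

    def test_roundtrip_identity(self, tmp_path, rng):
        sizes = {"c1": 2350, "c2": 900}
        counts = {
            "c1": rng.integers(0, 5, size=24).astype(float),
            "c2": rng.integers(0, 5, size=9).astype(float),
        }
        track = BinnedTrack(counts, sizes, 100)
        path = tmp_path / "t.bedGraph"
        write_binned_track(track, path)
        back = read_binned_track(path, 100, sizes)
        for chrom in sizes:
            np.testing.assert_array_equal(back.counts[chrom], counts[chrom])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            BinnedTrack({"c": np.array([1.0, -1.0])}, {"c": 200}, 100)


class TestSegmentationIO:
    def test_roundtrip_and_label_check(self, tmp_path):
        seg = Segmentation(
            [GenomicInterval("c", 0, 500), GenomicInterval("c", 500, 900)],
            ["RED", "BLACK"],
        )
        path = tmp_path / "seg.bed"
        write_segmentation(seg, path)
        back = read_segmentation(path)
        assert back.labels == ["RED", "BLACK"]
        assert back.class_basepairs()["RED"] == 500

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            Segmentation(
                [GenomicInterval("c", 0, 500), GenomicInterval("c", 400, 900)],
                ["RED", "BLACK"],
            )

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            Segmentation([GenomicInterval("c", 0, 500)], ["PURPLE"])


class TestOverlapEngine:
    def test_single_bp_overlap_counts(self):
        a = [GenomicInterval("c", 100, 200)]
        assert overlap_pairs(a, [GenomicInterval("c", 199, 300)]) == [(0, 0)]

    def test_half_open_boundary_excluded(self):
        a = [GenomicInterval("c", 100, 200)]
        assert overlap_pairs(a, [GenomicInterval("c", 200, 300)]) == []

    def test_different_chromosomes_never_overlap(self):
        a = [GenomicInterval("c1", 100, 200)]
        assert overlap_pairs(a, [GenomicInterval("c2", 100, 200)]) == []

    def test_empty_inputs(self):
        assert overlap_pairs([], [GenomicInterval("c", 0, 10)]) == []
        assert overlap_pairs([GenomicInterval("c", 0, 10)], []) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_intervals(rng, 200)
        b = random_intervals(rng, 200)
        assert overlap_pairs(a, b) == brute_overlap_pairs(a, b)

    def test_symmetry_transpose(self, rng):
        a = random_intervals(rng, 150)
        b = random_intervals(rng, 150)
        assert sorted((j, i) for i, j in overlap_pairs(a, b)) == overlap_pairs(b, a)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_overlap_predicate_matches_interval_arithmetic(self, data):
        s1 = data.draw(st.integers(0, 1000))
        w1 = data.draw(st.integers(1, 500))
        s2 = data.draw(st.integers(0, 1000))
        w2 = data.draw(st.integers(1, 500))
        a = GenomicInterval("c", s1, s1 + w1)
        b = GenomicInterval("c", s2, s2 + w2)
        expected = max(s1, s2) < min(s1 + w1, s2 + w2)
        assert (overlap_pairs([a], [b]) == [(0, 0)]) == expected
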