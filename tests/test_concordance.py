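"""Rank-overlap concordance: curve, cutoff selection, consensus, superset."""

import numpy as np
import pytest

from _oracles import brute_percent_overlap, brute_superset, random_peaks
from corepeak.concordance import (
    OverlapCurve,
    consensus_peaks,
    max_overlap_cutoff,
    percent_overlap_at_rank,
    rank_peaks,
    superset,
)
from corepeak.synthetic_data import SimulationConfig, simulate_replicate_peaks
from conftest import make_peak


def shifted(peaks, chrom="chrZ"):
    """Copies of the peaks on another chromosome (guaranteed disjoint)."""
    return [
        make_peak(chrom, p.interval.start, p.interval.end, name=p.name, p=p.neg_log10_p)
        for p in peaks
    ]


class TestRanking:
    def test_descending_significance(self):
        peaks = [
            make_peak("c", 0, 100, name="w", p=3.0),   # p = 1e-3
            make_peak("c", 200, 300, name="s", p=10.0),  # p = 1e-10
            make_peak("c", 400, 500, name="m", p=7.0),   # p = 1e-7
        ]
        assert [p.name for p in rank_peaks(peaks)] == ["s", "m", "w"]

    def test_ties_broken_by_genomic_position(self):
        peaks = [
            make_peak("c", 500, 600, name="later", p=5.0),
            make_peak("c", 100, 200, name="earlier", p=5.0),
        ]
        assert [p.name for p in rank_peaks(peaks)] == ["earlier", "later"]

    def test_idempotent_on_sorted_input(self):
        peaks = [make_peak("c", i * 1000, i * 1000 + 100, p=10.0 - i) for i in range(5)]
        assert rank_peaks(rank_peaks(peaks)) == rank_peaks(peaks)


class TestPercentOverlap:
    def test_identical_lists_give_100_at_every_rank(self):
        peaks = [make_peak("c", i * 1000, i * 1000 + 100, p=10.0 - i) for i in range(8)]
        for r in (1, 4, 8):
            assert percent_overlap_at_rank(peaks, peaks, r) == 100.0

    def test_disjoint_lists_give_0(self):
        a = [make_peak("c1", i * 1000, i * 1000 + 100, p=5.0) for i in range(5)]
        b = shifted(a)
        assert percent_overlap_at_rank(rank_peaks(a), rank_peaks(b), 5) == 0.0

    def test_rank_out_of_range_rejected(self):
        peaks = [make_peak("c", 0, 100)]
        with pytest.raises(ValueError):
            percent_overlap_at_rank(peaks, peaks, 2)
        with pytest.raises(ValueError):
            percent_overlap_at_rank(peaks, peaks, 0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_design_matches_brute_force_at_each_rank(self, seed):
        config = SimulationConfig(seed=seed, n_peaks=60, shared_fraction=0.5)
        a, b, _ = simulate_replicate_peaks(config)
        ra, rb = rank_peaks(a), rank_peaks(b)
        for r in (5, 20, 40, 60):
            assert percent_overlap_at_rank(ra, rb, r) == pytest.approx(
                brute_percent_overlap(ra, rb, r)
            )


class TestCutoffSelection:
    def test_argmax_rank_of_unimodal_curve_returned(self):
        # replicate B has two top-ranked noise peaks, so overlap rises to a
        # unique maximum at r=6 then falls as deeper noise enters both lists
        a = [make_peak("c", i * 1000, i * 1000 + 100, name=f"s{i}", p=20.0 - i) for i in range(4)]
        b = [make_peak("c", i * 1000 + 20, i * 1000 + 120, name=f"t{i}", p=20.0 - i) for i in range(4)]
        b += [make_peak("c", 70_000 + i * 1000, 70_000 + i * 1000 + 100, p=30.0 - i) for i in range(2)]
        a += [make_peak("c", 50_000 + i * 1000, 50_000 + i * 1000 + 100, p=2.0) for i in range(4)]
        b += [make_peak("c", 90_000 + i * 1000, 90_000 + i * 1000 + 100, p=1.0) for i in range(2)]
        curve = max_overlap_cutoff(a, b, rank_grid=[2, 4, 6, 8])
        assert curve.cutoff_rank == 6
        assert curve.max_percent == pytest.approx(400 / 6)
        assert list(curve.percent) == sorted(curve.percent[:3]) + [curve.percent[3]]

    def test_plateau_resolved_to_smallest_rank(self):
        peaks = [make_peak("c", i * 1000, i * 1000 + 100, p=10.0 - i) for i in range(6)]
        curve = max_overlap_cutoff(peaks, peaks, rank_grid=[2, 4, 6])
        assert curve.percent == (100.0, 100.0, 100.0)
        assert curve.cutoff_rank == 2

    def test_empty_grid_rejected(self):
        peaks = [make_peak("c", 0, 100)]
        with pytest.raises(ValueError, match="empty"):
            max_overlap_cutoff(peaks, peaks, rank_grid=[])

    def test_curve_invariants_enforced(self):
        with pytest.raises(ValueError):
            OverlapCurve((5, 3), (50.0, 60.0), 5)
        with pytest.raises(ValueError):
            OverlapCurve((3, 5), (50.0, 120.0), 5)
        with pytest.raises(ValueError):
            OverlapCurve((3, 5), (50.0, 60.0), 4)

    @pytest.mark.parametrize("shared_fraction", [0.3, 0.6, 0.9])
    def test_planted_shared_count_recovered(self, shared_fraction):
        grid = list(range(10, 201, 2))
        for seed in range(20):
            config = SimulationConfig(seed=seed, shared_fraction=shared_fraction)
            a, b, truth = simulate_replicate_peaks(config)
            curve = max_overlap_cutoff(a, b, grid)
            assert abs(curve.cutoff_rank - truth["n_shared"]) <= 0.1 * truth["n_shared"]


class TestConsensus:
    def test_identical_lists_give_top_of_reference(self):
        peaks = [make_peak("c", i * 1000, i * 1000 + 100, p=10.0 - i) for i in range(6)]
        curve = max_overlap_cutoff(peaks, peaks, rank_grid=[4])
        consensus = consensus_peaks(peaks, peaks, curve)
        assert consensus == rank_peaks(peaks)[:4]

    def test_disjoint_lists_give_empty_consensus(self):
        a = [make_peak("c1", i * 1000, i * 1000 + 100, p=5.0) for i in range(4)]
        b = shifted(a)
        curve = max_overlap_cutoff(a, b, rank_grid=[4])
        assert consensus_peaks(a, b, curve) == []

    def test_consensus_subset_of_reference_top(self):
        rng = np.random.default_rng(7)
        a, b = random_peaks(rng, 80), random_peaks(rng, 80)
        curve = max_overlap_cutoff(a, b, rank_grid=[20, 40, 60, 80])
        consensus = consensus_peaks(a, b, curve)
        top = set(
            (p.chrom, p.interval.start) for p in rank_peaks(a)[: curve.cutoff_rank]
        )
        assert all((p.chrom, p.interval.start) in top for p in consensus)

    def test_union_mode_widens_to_partner_span(self):
        a = [make_peak("c", 1000, 1200, name="a", p=9.0)]
        b = [make_peak("c", 1100, 1500, name="b", p=9.0)]
        curve = max_overlap_cutoff(a, b, rank_grid=[1])
        (merged,) = consensus_peaks(a, b, curve, mode="union")
        assert (merged.interval.start, merged.interval.end) == (1000, 1500)

    def test_planted_shared_set_recovered(self):
        grid = list(range(10, 201, 2))
        for seed in range(20):
            config = SimulationConfig(seed=seed, shared_fraction=0.6)
            a, b, truth = simulate_replicate_peaks(config)
            curve = max_overlap_cutoff(a, b, grid)
            names = {p.name for p in consensus_peaks(a, b, curve)}
            planted = set(truth["shared_names_a"])
            jaccard = len(names & planted) / len(names | planted)
            assert jaccard >= 0.9


class TestSuperset:
    def test_reference_against_itself(self):
        peaks = [make_peak("c", i * 1000, i * 1000 + 100) for i in range(5)]
        assert superset(peaks, [peaks]) == peaks

    def test_any_empty_other_list_empties_result(self):
        peaks = [make_peak("c", i * 1000, i * 1000 + 100) for i in range(5)]
        assert superset(peaks, [peaks, []]) == []

    def test_no_other_lists_rejected(self):
        with pytest.raises(ValueError):
            superset([make_peak("c", 0, 100)], [])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_filtering(self, seed):
        rng = np.random.default_rng(seed)
        ref = random_peaks(rng, 60)
        others = [random_peaks(rng, 60) for _ in range(3)]
        assert superset(ref, others) == brute_superset(ref, others)

    def test_size_monotone_nonincreasing_as_lists_added(self, rng):
        ref = random_peaks(rng, 80)
        others = [random_peaks(rng, 80) for _ in range(4)]
        sizes = [len(superset(ref, others[: k + 1])) for k in range(4)]
        assert sizes == sorted(sizes, reverse=True)
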