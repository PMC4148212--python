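# Methods

This note documents the models, conventions and design choices behind
`corepeak`: what each procedure computes, the parameters that matter, what
the synthetic-data generator does and does not emulate, and the numerical
decisions a maintainer would want written down.

## Coordinate and data model

All coordinates are 0-based half-open `[start, end)` (BED convention).
Spreadsheet peak tables read through the `xls_table` loader are declared
1-based inclusive and converted on read; when such a table carries an
explicit width column it takes precedence over `end − start` in width
statistics, so summaries match the table as printed. "Overlap" everywhere
means at least one shared base pair (`max(starts) < min(ends)` on the same
chromosome); no minimum overlap fraction is applied anywhere. Chromosome
names are matched as exact strings — no silent `chr`-prefix harmonization.
A peak's summit is an offset from its start; loaders without a summit column
impute the interval midpoint and flag the record (`summit_imputed`).

Transcripts are stranded: TSS = `start` on `+`, `end − 1` on `−`; the TES is
the opposite end. Binned tracks are dense per-chromosome vectors of
non-negative counts at a fixed bin size (default 100 bp), bin *i* covering
`[i·bin, (i+1)·bin)`.

## Replicate concordance

Peaks are ranked by descending −log10 *p* with ties broken by (chrom, start),
making the order fully reproducible. The percent overlap at rank *r* is the
symmetric mean of the two directional overlap fractions between top-*r*
sublists; both one-directional variants are available for diagnostics. The
direction convention removes list-size asymmetry; the same *r* is applied to
both lists simultaneously. The cutoff is the smallest grid rank attaining
the curve maximum (ties resolve toward the more stringent list). The default
grid is 50 evenly spaced ranks from 100 (or the list size, if smaller) to the
shorter list's length; recovery experiments with small planted shared counts
pass a finer explicit grid (`range(10, 201, 2)`), since a grid starting at
rank 100 cannot express a cutoff below 100.

Consensus peaks are reference-anchored: the top-*r\** peaks of list A that
overlap any top-*r\** peak of B, keeping A's coordinates and summit. A
union-span mode exists behind a flag. The superset operation keeps reference
peaks overlapping ≥ 1 peak in *every* other list; its size is non-increasing
as lists are added.

## Peak geometry

Width statistics report mean and median rounded to the nearest bp, the
precision such numbers are conventionally printed at. Clustering uses
nearest-edge (gap) distance — "within 5 kb of another peak" reads as gap, and
overlapping peaks have distance 0; center-to-center distance is available via
`mode="center"`. Counts are per peak (peak-pair counts are derivable by
halving the sum).

## Annotation

The nearest transcript is chosen by minimal |summit − TSS| (ties: lower
transcript id), matching the summit-centric framing of summit-to-TSS distance
histograms; nearest-by-peak-start is available via `nearest_by="start"`.
When peak and transcript intervals touch, category precedence is
`includeFeature` (peak covers the whole transcript) > `overlapStart` (peak
contains the TSS coordinate) > `overlapEnd` > `inside`; otherwise the sign of
the strand-adjusted distance picks `upstream` (negative) or `downstream`.
"TSS overlap" percentages are the `overlapStart` share of assigned peaks.

A note on symmetry: flipping the strand of a transcript *in place* moves its
TSS to the other end, so it does not simply negate distances. The true
invariant — verified in tests — is that reflecting all coordinates through a
fixed point *and* flipping strands negates every signed distance.

The distance histogram conserves mass by routing out-of-range distances into
two open-ended edge bins, but the reported modal bin is taken over the
in-range bins only; otherwise distal peaks would dominate any finite range.

## Binned signal

Upper-quantile normalization scales each track by `s_t = Q_ref / Q_t`, where
`Q_t` is the q-quantile (default 0.95) of the track's **nonzero** bins and
`Q_ref` the geometric mean of the per-track quantiles. Nonzero bins are the
default because a sparse genome's raw 0.95 quantile is frequently zero; the
all-bins mode is exposed. The geometric-mean reference is symmetric in the
samples; its one consequence is that pre-multiplying one input by *c* moves
the common reference by c^(1/n), so the invariant that holds (and is tested)
is that *ratios between normalized tracks* are unchanged, and a doubled
track's normalized output equals its partner's.

Meta-profiles are anchored at peak summits (or transcript TSSs) and
bin-centered: the window spans `2·flank/bin + 1` bins with the anchor bin at
offset 0. Anchors assigned to minus-strand transcripts are mirrored before
averaging so transcription direction always points right; anchors whose
window leaves the chromosome are dropped and counted (`n_used + n_dropped =
total`). Heatmap matrices use the same windows, rows ordered by descending
peak width (ties by position), so column means equal the meta-profile.

## RNAP II pausing

The pause ratio is density-normalized:

    PR = ((tss_count + ε) / 250) / ((body_count + ε) / body_length)

with the TSS window `[TSS, TSS+250)` in transcription direction, the gene
body from the end of that window to the TES, and ε = 1 pseudocount in both
windows. Density (counts per bp) rather than raw counts makes ratios
comparable across transcript lengths; a raw mode exists behind the
`pseudocount`/window parameters. Window sums attribute partial bins
fractionally, assuming counts uniform within a bin; consequently the
250 bp window is only exact on data whose bin size divides 250 (the worked
9.0 example in the tests uses 50 bp bins for this reason). Transcripts
shorter than 250 + 500 bp are unusable and excluded from deciles. The
pseudocount biases PR toward 1 at low coverage (≈ +7% at ~12 counts per
window, < 1% at ~100), which is why calibration checks run at realistic
depth. Deciles are assigned by PR rank with ties broken by transcript id
(balanced to ±1 even on degenerate input), and are invariant under monotone
transforms of PR. Pause analysis is per transcript isoform, not per gene.

## Chromatin classes

Each peak contributes a 100 bp window centered on its summit
(`[summit−50, summit+50)`); the window joins the class with maximal
base-pair overlap, ties resolving in the fixed order RED > YELLOW > BLUE >
GREEN > BLACK. Enrichment is the ratio of the class's share of assigned
peaks to its share of segmented base pairs. Venn counts are reported per
direction (`shared_from_a`, `shared_from_b`) because a broad peak on one
side can overlap several on the other; diagrams that collapse the two
directions lose this information.

## Synthetic data: what is emulated, and what is not

The generator plants known structure on a small two-chromosome genome
(2 × 1.5 Mb, 100 bp bins):

* **Peaks.** Each replicate holds 200 peaks; a fraction *f* (default 0.6) is
  shared, appearing in both replicates with ≤ 100 bp positional jitter.
  Widths are log-normal with μ = ln 708, σ = 0.566, i.e. median 708 bp and
  mean 831 bp — the scale of high-confidence Gro peaks in Kc167 cells. 40% of
  shared peaks are anchored at gene TSSs with the summit planted 35 bp
  downstream in transcription direction (the TSS-proximal binding mode);
  carrier genes are chosen uniformly, independent of pausing status, so
  decile-null experiments stay flat. Peaks occupy distinct 6 kb slots, so
  planted truth is unambiguous.
* **Significance.** Noise peaks draw −log10 *p* ~ Exp(scale 2); shared peaks
  add a shift of 10, putting the crossover probability at e^−5 < 1%. This is
  the regime in which rank truncation is the correct recovery mechanism for
  the concordance cutoff — and matches the orders-of-magnitude separation of
  MACS p-values between reproducible peaks and marginal calls.
* **Tracks.** Counts are Poisson per bin (no overdispersion by default,
  unlike real data). The polymerase track has background rate 1/bin, uniform
  gene-body rate 4/bin, and a paused-excess pulse in the first 200 bp (two
  bins) after the TSS carrying mass `(PR − 1) × total density × 250 bp`, so
  the planted PR is exactly the density ratio the estimator measures. Gene
  coordinates are bin-aligned for the same reason. 30% of genes are paused
  (PR 8 by default). The acetylation track (rate 10/bin) is reduced by a
  fractional dip (0.7) inside peak intervals.
* **Segmentation.** Exponential block lengths (mean 10 kb, min 1 kb) are
  assigned greedily to the class with the largest remaining base-pair
  deficit, realizing requested genome fractions (defaults RED 12%,
  YELLOW 16%, BLUE 10%, GREEN 14%, BLACK 48%) to within one block length
  (< 2%).

Everything is deterministic under the config seed (one
`numpy.random.default_rng` stream per operation). Not emulated: read-level
properties (fragment lengths, GC, mappability), overdispersion (a
negative-binomial switch would be the first extension), peak-width
correlation with significance, overlapping transcript isoforms, and any
dependence of binding on chromatin class. Passing recovery tests therefore
demonstrate correctness of the *computations* under the stated statistical
structure, not robustness to every artifact of real sequencing data.

## Problem sizes and tolerances

Recovery experiments use 200 peaks/replicate, 300 genes and 20 fixed seeds —
sizes at which planted effects are identifiable yet the full suite and the
acceptance script each run in about a minute. Tolerances: concordance cutoff
within ±10% of the planted shared count and consensus/truth Jaccard ≥ 0.9;
planted pause ratio 9 recovered within 20% (Poisson noise plus the ε bias);
uniform-coverage PR within 5% of 1; normalized upper quantiles equal to
1e-9 relative; null enrichments flat within 4 standard errors of the pooled
binomial. Degenerate inputs (empty peak lists, all-zero tracks, < 10 usable
transcripts, windows off the segmentation) raise errors rather than
returning silent defaults.

## Known limitations

* The `xls_table` loader reads xlsx/tsv/csv; legacy binary `.xls` workbooks
  must be exported first (no `.xls` reader is declared as a dependency).
* Published peak catalogues validated by the width-statistics acceptance
  check are not redistributable and must be supplied under `data/published/`.
* Pause ratios at 100 bp resolution carry the partial-bin attribution
  described above; analyses needing exact 250 bp windows should bin at 50 bp.
* No FDR modelling of concordance (IDR-style) — the rank-overlap cutoff is a
  deterministic, assumption-light procedure, which is its point.
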