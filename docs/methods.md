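# Methods

This note documents the models, numerical choices and limitations behind
damkit, in the order data flows through the pipeline.

## Coordinate system: GATC fragments

All signal lives on the tiling of each chromosome into GATC-delimited
fragments.  Internal boundaries sit at `motif_start + 2`, between GA and
TC, mirroring the blunt cut DpnI makes in fully methylated GATC; the
convention is arbitrary at ±2 bp but fixed and tested.  In memory all
coordinates are 0-based half-open; on disk GFF3 is 1-based inclusive and
bedgraph/BED/broadPeak are 0-based half-open, each format's own
convention.  `N` never matches the motif.  A chromosome with *k* motifs
has *k*+1 fragments; tilings are exact (no gaps, no overlaps), which the
suite asserts against a brute-force regex oracle.

## Synthetic experiments

The simulator emulates what the assay measures, not how a sequencer
fails.  Its defaults define the study conditions used throughout the
test suite: one 200 kb chromosome, geometric inter-motif spacing with
mean 190 bp (fly-like spacing; floored at 5 bp so motifs never collide),
40 binding fragments drawn uniformly from interior fragments,
methylation probability 0.8 at GATC sites flanking a bound fragment in
fusion samples and 0.05 everywhere else (open-chromatin background —
the assay has no published quantitative rate, so these are free
parameters of the model, chosen once as a strong-binder scenario over a
low but non-negligible background), 50,000 molecules per sample,
geometric PCR duplication with mean 1.5, ~300 bp sonication (sd 15 %),
50 nt single-end reads, and the DamID PCR primer prefixed to each insert.

Mechanistically, whole-genome copies are methylated site by site;
a fragment is *released* only between two consecutive methylated sites
(single methylated sites emit nothing, mirroring the double-cut logic of
DpnI).  "Molecules" counts released fragments, i.e. sequenced molecules:
copies are generated in batches until the requested number of molecules
exists.  Each molecule is sonicated, sequenced from one of its GATC ends
on the corresponding strand, and duplicated with a geometric copy count;
duplicates are exact copies so complexity curves have signal.  Sample
*i* of an experiment draws from `seed + 1 + i`, making samples
independent and fixtures stable.

What the generator does **not** emulate: sequencing errors and quality
decay, mappability structure and repeats, GC bias, chromatin-state
heterogeneity between cells, partial digestion, and fragment-length
bias in PCR.  Passing the recovery tests therefore shows the pipeline's
statistics behave correctly under the assay's idealized generative
model — not that any real library is this clean.

A note on spacing: a geometric distribution with mean 190 bp has median
≈ 132 bp; the generator controls the mean, and the tests check the mean.

## Read preparation

Trimming removes the 5′ DamID PCR primer `GGTCGCGGCCGAGGATC` (in full or
as a suffix overlapping the read start) and the 3′ index-adaptor stem
`AGATCGGAAGAGC…` (in full anywhere, or as a prefix overlapping the read
end), with mismatch rate ≤ 0.1 and minimum overlap 3 — the conventions
of standard read trimmers, made explicit and configurable.  Length
filtering then keeps reads of 30–50 nt inclusive.  Optional 3′ quality
trimming (Q20, BWA-style partial sums) exists but is off by default
because no threshold is part of the standard workflow.  Note that
mismatch-tolerant short-overlap matching can in principle trim a few
bases spuriously (probability ~4⁻³ per read for the 3-nt overlap); this
is inherited from the conventional matching rules, not a defect the
pipeline relies on.

## Alignment and counting

The built-in aligner is exact: a read is placed iff its sequence or
reverse complement occurs exactly once in the genome (30-mer seed index,
full verification); multimappers and misses are counted but not placed.
It exists so toy genomes need no external aligner — real data should be
aligned elsewhere and ingested as SAM text, of which only FLAG (0x4,
0x10), RNAME, POS and SEQ length are consumed.

Reads are extended to 300 bp in their strand direction (clipped at
chromosome ends; never shorter than the read) before fragment
assignment.  The default assignment is **fractional**: a read's unit
weight is split over overlapped fragments proportional to overlap, so
total weight equals the aligned read count exactly — an invariant the
suite asserts.  An `all_overlap` mode (full count to every overlapped
fragment) is available for compatibility with coverage-style counting.
Binned coverage for QC uses 500 bp bins and 150 bp extension, counting
presence (≥ 1 bp overlap) per bin.

## Tracks

RPM scaling divides weights by the aligned library size (×10⁶).  The
binding track is `log2((expRPM+ψ)/(ctrlRPM+ψ))` with ψ = 0.5 RPM.  The
pseudocount is symmetric, making the track antisymmetric under
experiment/control exchange (asserted exactly); ψ = 0.5 RPM damps
fragments with ≲ a handful of reads without visibly biasing
well-covered fragments.  This replaces the kernel-density read-count
correction of older DamID pipelines with a fully specified, testable
normalization; the robust background matching that correction provided
lives in the peak caller's median-ratio scaling instead (below).

Quantile normalization maps rank *r* of each track to the mean of the
*r*-th order statistics across tracks; ties receive the mean reference
value of their tied ranks (the standard convention).  With ties, the
exact "identical sorted multisets" property necessarily relaxes; it is
asserted exactly for tie-free data.  Dam-only (accessibility) tracks
are quantile-normalized to each other and averaged, separately from the
ratio tracks.

## Broad peak calling

Per pairwise comparison, fragment *i* is tested against a local Poisson
background:

* `λ_i = length_i × max(own control density, 1 kb, 5 kb, 10 kb window
  densities, genome-wide floor)`, each a control-weight density treating
  fragment weight as uniform over its span (evaluated by linear
  interpolation of cumulative weight — O(1) per window).
* **Control scaling.**  Rather than scaling the control purely by
  library-size ratio, the default multiplies it by the median over
  fragments of `expWeight / (lib-scaled ctrlWeight)`.  A fusion library
  spends a third or more of its reads on bound fragments, so its
  *background* runs below the library-scaled control; the median ratio
  recentres the null on the background while ignoring the minority of
  bound fragments — the same idea as the background-ratio normalization
  of established DamID pipelines.  `control_scaling="library_size"`
  restores plain scaling.
* **Overdispersion.**  PCR duplication makes counts extra-Poisson
  (a geometric copy count of mean 1.5 roughly doubles the Fano factor),
  so counts and λ are deflated by a dispersion factor φ before testing:
  `φ = median[(k − r·μ)² / (r·μ)] / median(χ²₁)`, with μ the fragment's
  scaled control weight and r the median ratio above; φ is clipped at 1
  (never sharpen below Poisson).  Medians keep the estimate blind to the
  few truly bound fragments.  `dispersion=1.0` restores the plain model.
* `p_i = P(Poisson(λ_i/φ) ≥ round(k_i/φ))`, with the far tail computed
  by a log-space series when scipy's survival function underflows —
  q-values down to −log10 FDR = 2000 stay meaningful.
* Benjamini–Hochberg runs in log10 space with enforced monotonicity.

Fragments with q ≤ 0.05 are seeds; maximal runs with q ≤ 0.1 containing
at least one seed become broad peaks.  Runs separated by interior
non-linked stretches shorter than 50 bp (the read length, below which
single-end mapping cannot resolve a gap) are bridged: GATC spacing is
roughly geometric, so sub-read-length micro-fragments occur regularly
and would otherwise split one biological binding region into two
adjacent peaks that touch but do not cover the region's center.  Peak
p/q are the −log10 of the best linked fragment; the signal value is the
mean log2 ratio over the span; the score is `min(1000, 10·(−log10 q))`.

Calibration is tested, not assumed: on simulations with
`p_bound == p_open` (and on role-swapped comparisons, Dam-only tested
against fusion controls) the fraction of fragments at q ≤ 0.05 stays at
or below 0.05.

## Consensus and reproducibility

The default threshold ladder has 41 −log10(FDR) values: 0–5 by 1, 10–100
by 10, 125–1775 by 75, then 1900 and 2000.  The printed anchors of this
conventional ladder (start 0, the 0–5 and 10–100 runs, 125, the 1900 →
2000 tail, 41 values) do not determine the interior uniquely; this
ladder satisfies all of them and is user-overridable.  At each cut-off,
records with −log10 FDR ≥ cut-off from all pairs are pooled, sorted and
merged at ≥ 1 bp overlap (`.mergePeak`).  The reproducible set keeps
consensus peaks overlapping peaks in at least 50 % of the per-pair sets
— inclusive, so exactly half counts — with the occurrence check run
against the *thresholded* per-pair sets by default (`mode="raw"` checks
against unthresholded sets instead).

## QC

* **Correlation:** Pearson over identical bins of raw binned counts
  (log-transform optional); zero-variance tracks are reported as missing
  rather than erroring.  A library is flagged iff the *median* of its
  correlations to same-type peers falls strictly below the threshold —
  0.9 within fusion or Dam-only groups, 0.8 among pairwise-ratio tracks;
  the boundary is kept.  The median needs ≥ 3 peers to isolate a single
  bad replicate; singleton groups yield "insufficient replicates".
* **Complexity:** the expected number of distinct reads in a subsample
  of size *n* without replacement is computed exactly via the
  hypergeometric expectation `Σ_u [1 − C(N−c_u, n)/C(N, n)]` (log-gamma
  arithmetic), so the curve is deterministic and testable against
  exhaustive enumeration.
* **Fingerprint:** bins ranked ascending by count; y(k) is the read
  share of the k lowest bins.  Signal-rich libraries bow toward the
  lower right; on the default simulation the fusion curve lies at or
  below the Dam-only curve for bin-rank fractions ≥ 0.9.
* **Enrichment:** tracks sampled at evenly spaced offsets within ±1 kb
  of peak centers, averaged over peaks; with an even number of
  positions the central value averages the two offsets closest to 0.
* **Pooling:** `molarity [nM] = (1500 / fragment size) × conc [ng/µL]`;
  per-library volume `(target/molarity) × (final volume / n)`; water
  tops up to the final volume.  The achieved concentration is verified
  by mass balance; plans needing more liquid than the final volume are
  rejected.

## Problem sizes

The simulation-based checks run on one 200 kb chromosome with 3 + 3
samples of 50,000 molecules (the default conditions above); pipeline
file-level tests use a 30 kb genome with 2 + 2 samples of 4,000
molecules; null-calibration checks use 50 kb genomes across three seeds.
These sizes make the whole suite reproducible on a single CPU while
leaving hundreds of reads per bound fragment, the regime the statistics
are designed for.

## Known limitations

* The exact aligner is for toy genomes only; there is no mapping-quality
  model, no gapped alignment, and BAM must be converted to SAM text
  externally.
* The quasi-Poisson dispersion is a single genome-wide factor; no
  per-fragment (edgeR/DESeq-style) dispersion shrinkage.
* Reproducibility counts binary occurrence at ≥ 1 bp overlap; no IDR.
* Execution is serial; pairwise comparisons are independent and safe to
  parallelize externally, and rerunning a configuration is byte-stable.
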