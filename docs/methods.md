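# Methods

This note records the models, conventions, parameter defaults and design
choices behind each stage, what the synthetic data do and do not emulate,
and the package's known limitations.

## Coordinates and overlap semantics

All internal coordinates are 0-based half-open (BED convention); 1-based
inputs must be converted at parse time. Overlap everywhere means ≥ 1 bp
shared: `max(starts) < min(ends)` on the same chromosome, so abutting
intervals do not overlap. Chromosome names match by exact string; a
genome-bound read warns and lists unmatched names rather than aliasing
`chr` prefixes. The overlap engine keeps per-chromosome sorted start/end
arrays; membership tests binary-search merged runs and counting uses the
line-sweep identity `#overlaps = #(start < query_end) − #(end ≤
query_start)`, which is exact for intervals on a line. Signal tracks are
sparse non-overlapping runs; absent coverage reads as zero, and values
are assumed already depth-normalized (RPM/RPKM-like) — the package never
rescales by library size.

## Rich-region (MRR / super-enhancer) calling

Peaks are stitched when the gap to the next peak is strictly below the
window (4,000 bp for H3K27me3; 12,500 bp for H3K27ac), with overlapping
or abutting peaks always merged; output regions are therefore pairwise
separated by at least the window. Each stitched region is scored
`max(0, treatment − control)` in value-bp over the whole stitched span
(gaps included, where treatment and control largely cancel). A per-bp
density mode (`score/length`) is provided because ranking by total and
by average signal are both defensible readings of rank-cutoff callers;
total is the default and the mode is recorded in output metadata.

The cutoff takes the ascending rank curve on unit-scaled axes and picks
`argmin(ŷ − x)`, the tangent point of slope 1. Ties break toward the
largest index and rich membership requires a score strictly above the
cutoff value, both deliberately conservative (fewer rich calls, and the
tangent point itself stays typical). Degenerate inputs — fewer than 3
regions or constant scores — yield no rich calls plus a warning rather
than an arbitrary split. The cutoff index is invariant under shifting or
positively scaling all scores, which the tests assert.

## Anchor states and pair enrichment

Anchors are A/R/B/Q by ≥1 bp overlap with H3K27ac-only, H3K27me3-only,
both, or neither; in the repressive mode they are MRR/T with MRR taking
precedence and unclassified anchors dropping that loop from the analysis
(count logged). Marginals are counted over anchor *slots* (each loop
contributes two), matching a homogeneous independent-pairing null; a
unique-locus alternative would weight promiscuous anchors differently
and is intentionally not the default. Expected proportions are
`2·p_s·p_t` off-diagonal and `p_s²` on the diagonal; zero-observed pairs
report an undefined (NaN) ratio rather than −∞, with no pseudocount.
Exact-coordinate duplicate loops are removed (orientation-insensitive)
before enrichment, and the removed count is logged.

## Gene–MRR looping classes

Promoters are symmetric TSS ± 2,000 bp windows (the half-width is
configurable and recorded); the TSS is the strand-aware 5′ end of the
gene body. Proximal evidence is promoter–MRR overlap *or* co-occupancy
of one loop anchor (logical OR — both flags are reported separately so
either reading can be recovered). Distal requires a loop joining an
MRR-overlapping anchor to a promoter-overlapping anchor with the MRR
staying off the promoter's anchor; internal requires proximal evidence
plus a supporting loop with both anchors inside the same MRR. Precedence
internal > proximal > distal gives one category per (gene, MRR) pair; a
gene may keep one association per MRR, and gene-level summaries take the
highest-precedence category.

Control genes are sampled after removing genes whose body touches
blacklist or H3K9me3 regions (constitutive heterochromatin) and keeping
genes whose body or promoter touches a loop anchor; the sample size is
`floor(mean(category sizes))`, drawn uniformly without replacement from
a seeded generator.

## Shuffle overlap testing

Each query region is independently re-placed uniformly on its own
chromosome, preserving chromosome and length; shuffled regions may
overlap each other or their original position (an exclusion flag exists
but is off — the randomization is the plain same-chromosome null).
Default 1000 shuffles. Two p-values are reported: a one-sided one-sample
t-test of the shuffled percentages against the observed one
(mean(expected) < actual), and the empirical rank
`(1 + #{expected ≥ actual})/(n + 1)`. The empirical p is the safer
headline: it is valid without normality but is conservative when the
overlap statistic is coarsely discrete (heavy ties with the observed
value push it upward), which matters for small target sets. Zero
variance across shuffles makes the t statistic undefined; only the
empirical p is then reported, with a warning.

## Expression specificity and state changes

Specificity uses base-2 entropy with the 0·log 0 = 0 convention and is
undefined (not zero) for all-zero vectors. Facet averaging is the
arithmetic mean of member samples; a cell line of interest enters as its
own facet, giving N = 70 with 69 reference facets. Binning: ≤ Q1 low,
≥ Q3 high, else mid, with quartiles by linear interpolation; a score
satisfying both cutoffs at once (possible only when Q1 = Q3) is neither
distinctly low nor high and lands in mid. Gene chromatin states use
body ∪ promoter overlap with precedence SE > MRR > H3K27ac > H3K27me3 —
rich regions subsume their constituent marks — and fold changes between
cell lines use a pseudocount of 1 expression unit.

## Differential 4C

Fragment identity is the exact (chrom, start, end) triple: both
conditions derive from the same restriction map, so coordinates are
comparable (a tolerance-merge flag is not needed for the synthetic data
and is left to future work). Significance is p < 0.05 per replicate;
pooling is the union across replicates with per-replicate RPMs carried
along, and mixing baits across replicates is an error. Bait distance is
midpoint-to-midpoint; trans fragments keep their status but are excluded
from all distance analytics. Tertile breakpoints are the 1/3 and 2/3
quantiles of cis distances over the comparison's union set (per-library,
since printed breakpoints do not exist for arbitrary data); distance
categories with fewer than 3 interactions are excluded from the
proportion-unchanged summary. The changed-vs-unchanged distance
comparison uses a one-sided Mann–Whitney U.

## Signal areas and integration

`signal_area` tiles a region left-to-right in `bin_size` bins (default
50 bp; the true value is data-dependent and configurable), the final bin
truncated to the region edge with its true width entering the product,
so the total area equals the region's value-bp mass at any bin size.
Per-bin `Sig` is the mean coverage over the bin (computeMatrix-style
semantics). Tertile labels check low (≤ q1/3) before high (≥ q2/3), so
degenerate all-equal cohorts land in low with a warning. TF Z-scores
standardize overlapping-peak counts per TF across regions with
population sd; constant columns get z = 0. The 4C × ChIP integration
tertiles regions on the control condition only and runs paired Wilcoxon
signed-rank tests per status group (gained, lost, unchanged, and pooled
changed), reporting NaN where a group is too small or has no nonzero
paired differences.

## Synthetic data: what it emulates, and what it does not

The generators fan one global seed into fixed per-generator substreams,
so adding a generator never perturbs another and identical
(parameters, seed) give byte-identical files.

* **Peaks + coverage** — 20 clusters of 8 peaks (gaps drawn in
  0.5–3 kb, below the 4 kb window) planted among 500 isolated peaks on
  a 10 Mb chromosome; treatment coverage is Poisson at background 1.0
  outside peaks, 10× inside cluster peaks, 10/3× inside isolated peaks,
  emitted as 10 bp bedGraph bins (exercising partial-bin proration);
  control is flat background. Units are separated by twice the stitch
  window, so stitching boundaries are unambiguous by construction.
* **Loops** — non-overlapping anchors labelled i.i.d.
  (A .35, R .25, B .15, Q .25), pair composition allocated by
  largest-remainder rounding of n× a preference matrix (like-like
  boosted 3× then renormalized), so the realized pair distribution
  matches the planted one up to rounding and randomness lives in anchor
  identity. Mark-peak files are emitted inside anchors so that
  peak-based labelling reproduces the planted states exactly.
* **Genes** — one proximal, distal, or internal configuration per
  planted cluster, round-robin, with dedicated loops for the distal and
  internal cases.
* **Expression** — per-gene Dirichlet profiles (α log-uniform in
  [10⁻², 10]) scaled by lognormal totals; the recorded truth is the
  specificity formula applied to the drawn values, so recovery is exact
  by construction and tests the plumbing, not the statistics.
* **4C** — an exponential (mean ≈ 4 kb, HindIII-like) fragment grid
  over ±3 Mb of the bait; control significance declines exponentially
  with distance, the experiment flips significance with a logistic
  probability rising from 0.05 to 0.75 around 1 Mb, p-values land below
  or above 0.05 accordingly, and RPM declines lognormally with
  distance. Replicate 1 carries the full condition-level set and
  replicate 2 resamples it at 80% agreement, so the pooled union equals
  the planted set exactly.

The full scenario places peaks and loop anchors on separate chromosomes
so neither stage's truth contaminates the other; the handful of
gene-dedicated loops carry unlabelled anchors and add < 1% quiescent
pairs to the enrichment input. None of this reproduces real-genome
features — distance-decay Hi-C backgrounds, GC/mappability structure,
assembly gaps, overlapping peak classes, read-level noise — so passing
tests demonstrate correctness of the computations under the stated
generative model, not performance on real ChIP-seq/Hi-C/4C data.

## Problem sizes

The test suite and the acceptance script run the study conditions above
(10 Mb genome, 520 stitched regions, 5,000 loops at full scale, 20,000
loops for the enrichment-recovery check, 50,000 for the homogeneous
null, 200 calibration replicates × 100 shuffles, 100 simulated 4C
libraries); the end-to-end determinism test uses a half-scale genome.
These sizes were chosen so every distributional check has comfortable
resolution while the whole suite stays interactive.

## Known limitations

* bigWig input is not implemented; bedGraph is the reference dialect.
* The shuffle null has no gap/blacklist masking and no GC awareness.
* No BAM/FASTQ handling, no loop or peak calling, no liftover — peak
  and loop calls are upstream inputs by design.
* The t-test p-value in the shuffle test assumes approximate normality
  of shuffled percentages; prefer the empirical p for small or coarse
  target sets.
* Hierarchical clustering of TF Z-score matrices is left to standard
  tooling on the exported matrix; the package only computes the matrix.
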