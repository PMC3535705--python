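# Methods

This document records the statistical models, algorithmic conventions,
parameter defaults, and known limitations of the `methylcap` package.

## Coordinate and binning conventions

All coordinates are 0-based, half-open (`[start, end)`), matching BED.
The genome is partitioned into fixed, non-overlapping bins of
`bin_size` bp (default 500); bin `i` of a chromosome covers
`[i·bin_size, (i+1)·bin_size)` and the last bin may be short. A CpG
dinucleotide "belongs" to the bin containing its C. A chromosome of
length L has `ceil(L / bin_size)` bins.

## Read processing

1. **Deduplication.** Reads sharing (chromosome, leftmost aligned
   position, strand) are collapsed to the first occurrence. Single-end
   reads carry no fragment-length information, so this triple is the
   strongest available PCR-duplicate signature; it slightly
   over-collapses at saturating depth (distinct fragments can share a
   5′ end).
2. **Fragment extension.** Each read is extended to the library fragment
   length `F` (default 150 bp): a forward read starting at `s` becomes
   `[s, s+F)`; a reverse read of length `r` becomes `[s+r−F, s+r)`.
   Extensions are clipped at chromosome bounds.
3. **Bin assignment.** Each extended fragment is assigned to exactly one
   bin — the bin of its midpoint `floor((a+b−1)/2)` — so bin counts
   conserve the number of assigned reads exactly. The alternative
   (fractional overlap weighting) spreads single fragments over bins and
   breaks count conservation; midpoint assignment keeps every downstream
   identity exact.
4. **RPM normalization.** `rpm[i] = counts[i] · 10⁶ / total_assigned`.
   Every lane's RPM vector sums to 10⁶ by construction. Replicate lanes
   of one library are RPM-normalized individually and then averaged, so
   a deep lane cannot dominate a shallow replicate.

## Quality-control metrics

- **CpG enrichment**: (CpGs inside extended fragments per fragment base)
  divided by (CpGs in the genome per genome base). Fragments are counted
  with multiplicity; a ratio ≈1 is the signature of failed capture, since
  uniform sampling reproduces the genomic CpG frequency in expectation.
- **Saturation**: the lane's unique reads are split into two random
  halves (seeded permutation), each half is binned, and the Pearson
  correlation between the two count vectors is reported. Estimates how
  reproducible the binned profile is at half the achieved depth; deeper,
  more complex libraries score higher.
- **5× CpG coverage**: the fraction of all genomic CpG sites overlapped
  by ≥5 extended fragments, computed by interval-boundary counting
  (sorted fragment starts/ends queried at CpG positions).
- **Noise**: 100 × (assigned reads in bins containing zero CpGs) /
  (total assigned reads). Not a pass/fail criterion — a directional
  diagnostic reported per sample averaged over lanes.

A lane **fails QC** if any of enrichment/saturation/coverage is strictly
below its threshold (defaults 1.4, 0.5, 0.05); equality passes. Failed
lanes are excluded from sample merging unless a lane is force-included
or exclusion is disabled to reproduce an "all samples" analysis.

## Differential methylation

Per-feature signal is the sum of mean-replicate RPM over all bins
overlapping the feature by ≥1 bp (features shorter than a bin inherit
that bin's RPM). Two groups are compared per feature with the Wilcoxon
rank-sum test on these sums:

- **Exact path** (combined n ≤ 12): the two-sided p-value is the
  fraction of all `C(n, n₁)` group assignments whose rank-sum deviates
  from its mean by at least the observed deviation (midranks for ties).
  This is exact under the permutation null, ties included.
- **Asymptotic path** (combined n > 12): normal approximation with
  midranks, tie-corrected variance `n₁n₂/12·[(n+1) − Σ(t³−t)/(n(n−1))]`,
  and a 0.5 continuity correction — numerically identical to
  `scipy.stats.mannwhitneyu(method="asymptotic")`, which the test suite
  asserts to 1e-9 relative tolerance.

Multiple testing is controlled per feature class with the
Benjamini–Hochberg step-up procedure (authored, cross-checked against
statsmodels). Note the exact-test granularity: with 3 vs 3 samples the
smallest attainable two-sided p is 2/20 = 0.1, and with 5 vs 5 it is
2/252 ≈ 0.0079 — too coarse to clear FDR 0.05 over hundreds of features.
Cohorts of at least ~8 per group are needed for BH-significant calls;
this is a property of the statistics, not of the implementation.

## Global methylation indicator (GMI)

Bins are stratified by CpG count `c = 1 … c_max` (default 25; denser
bins pool into the top class). Zero-CpG bins are excluded — their signal
is noise by definition. The class mean is the mean RPM over *all* bins
of the class, including zero-RPM bins; GMI is the sum of class means
(area under the density–RPM curve on the unit-spaced class grid).
Because RPM is depth-normalized and class means average over a fixed bin
population, GMI is invariant to sequencing depth and comparable across
samples on the same genome. It is a *relative* indicator: its scale
depends on the genome's CpG landscape and the binning, so only
within-study comparisons are meaningful.

## Spike-in model

A fully methylated construct present at fixed copy number per genome
competes with genomic fragments for MBD binding, so its captured read
share decreases as native global methylation rises. Construct reads are
counted from the raw alignments with duplicates *retained* (the
construct is a single short sequence, so genuinely independent fragments
are expected to collide) and normalized per million **raw** reads.
Sample-level validation is an OLS regression of GMI on 1/(construct
RPM), fit with `scipy.stats.linregress`; it requires ≥3 samples and
non-constant predictor, and is only informative when global methylation
varies across the cohort.

## Simulator

The generator is a first-class component: it produces data *and* the
complete truth needed to verify every downstream estimate by direct
counting.

**Genome.** A single chromosome (default 2 Mb) in three strata: CpG
islands (default 200 islands of 1 kb at CpG rate 0.08), CpG-sparse
background (rate 0.008, organized in 1-kb chunks), and CpG-free
territory (default 10% of the genome). CpG positions are *planted* on a
random backbone whose natural CG dimers are destroyed, so the planted
set equals the scanned set exactly and per-CpG truth is unambiguous. A
separate spike-in construct (5.3 kb) is built the same way.

**Methylation.** Methylation state is drawn per *region* (whole island
or 1-kb background chunk, all-or-none) with probability equal to the
sample's global methylation level; per-island probabilities can be
overridden to plant differential regions. Region-level states mirror the
coherent methylation domains that make enrichment sequencing work;
per-CpG independent states would average out within fragments and
under-represent between-sample variance.

**Reads.** Every genomic and construct position contributes a candidate
fragment with weight `1 + k·(methylated CpGs in the fragment)` (default
k = 1; weight 1 ≡ unmethylated). `reads_per_lane` fragments (default
100,000) are drawn in one multinomial pass over genome and construct
jointly — the construct *competes* for capture, which is what makes its
read share informative. Strand is random; the read is the first 36 bp of
the fragment. Modes: `captured` (weighted draw), `failed` and `input`
(k forced to 0, i.e. uniform). PCR duplicates are injected by resampling
already-emitted reads with probability `duplicate_rate` (default 0.05).
The truth log records fragment origins, duplicate flags, expected unique
reads, and construct read counts.

**Realism and limits.** The simulator reproduces the phenomena the
analysis measures: CpG enrichment ≈ 2.3 for captured lanes vs ≈ 1.0 for
failed ones, noise concentrated in CpG-free territory, GMI and spike-in
RPM monotone in the true methylation level, and power/FDR behavior of
DMR calling. It deliberately omits sequencing errors, base qualities,
mappability variation, GC/PCR amplification bias beyond uniform
duplication, paired-end fragments, and copy-number structure. The linear
capture weight was chosen for analytic tractability of expectations; a
saturating alternative (MBD binding saturates at high CpG density) would
compress the top of the GMI curve but not change any rank-based result.

## Determinism and numerics

Every stochastic step takes an explicit seed (`numpy.random.default_rng`;
no wall-clock seeding), and `(config, seed) → outputs` is a pure
function: rerunning the pipeline reproduces byte-identical TSVs. Counts
use 64-bit integers; normalizations are exact up to float64 rounding
(asserted at 1e-12 relative tolerance in tests). TSVs are written
atomically (temp file + rename) with `%.6g` float formatting.

## Limitations

- Single-end reads only; fragment length is a per-library constant from
  the manifest, not estimated.
- Deduplication by (chromosome, position, strand) over-collapses at
  saturating depth.
- The exact/asymptotic Wilcoxon cutover at combined n = 12 means
  p-values are granular for small cohorts (see above).
- GMI is relative to the genome/binning and not comparable across
  genomes.
- QC thresholds (1.4 / 0.5 / 0.05) are conventions tuned for
  human-scale MBD-capture libraries; other protocols may need
  recalibration.
- The spike-in regression assumes a shared construct copy number across
  samples; pipetting variation is not modeled or corrected.
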