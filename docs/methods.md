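# Methods

`spermcnv` implements the downstream interval statistics used when copy
number variation (CNV) is called from single-sperm sequencing and compared
against segmental duplications (SegDups), repeat annotation, and a diploid
family-trio reference. This note records the models, parameter choices and
numerical conventions, and what the synthetic data does and does not
emulate.

## Coordinates and interval algebra

All internal coordinates are 0-based half-open `[start, end)`; VCF (1-based
inclusive) and GFF (1-based inclusive) coordinates are converted only at
format boundaries, so a VCF record with `POS=101, END=200` becomes
`[100, 200)` of length 100 bp.

Region merging joins intervals that overlap, are book-ended, or are
separated by at most `gap` bp (`gap=0` by default, preserving the union
measure). "Neighboring" pairwise SegDup fragments are merged with `gap=0`;
the gap is exposed because the original merge tolerance used to produce
published region counts is not recoverable. Fragment deduplication for the
"unique nonredundant fragments" count is exact-coordinate; a
reciprocal-overlap deduplication mode exists but is off by default.

Flanks of width *w* are constructed per region on each side, clipped at
chromosome bounds, and — under the default policy — any overlap with *any*
input region is subtracted, so flank metrics never re-count target
footprint. Flank metrics downstream use the merged flank set, consistent
with all footprint denominators being unions, never sums.

## SV filtering

Calls are read from single-sample SV VCFs carrying `SVTYPE`, `END`,
`SVLEN`, `PE` (paired-end support) and `SR` (split-read support), the
dialect emitted by paired-end/split-read callers. Two filters apply:

* **Length**: DEL/DUP kept iff 50 bp ≤ length ≤ 5 Mb, bounds inclusive
  (the conventional CNV size range); INV/BND are never length-filtered.
* **Support**: at sample fold-coverage *c*, a call passes iff
  `PE > 0.75·c and SR > 1` **or** `SR > 0.75·c and PE > 3`. All
  comparisons are strict and `0.75·c` is kept real-valued (no rounding).
  The underlying published rule is ambiguous about which signal carries the
  coverage-scaled threshold; this implementation reads it as
  "either signal may be primary, the other must clear its secondary
  minimum", and exposes `coverage_fraction`, `secondary_sr_min` and
  `secondary_pe_min` so alternative readings are one-line changes.

The support filter applies to all four SV types; the length filter only to
DEL/DUP. Filters are idempotent and commute. Group tallies report counts,
summed lengths (kb) and genome-covered fractions; covered fractions use
merged footprints over a configurable denominator genome (pass an autosome
subset to get autosome-based coverage).

## Repeat content and permutation enrichment

For a target region set and a repeat class, the metrics are `length_bp`
(bp of repeat intersecting the merged target; a partially overlapping
repeat contributes only its overlapped bp), `count` (features touching the
target, once each), `avg_length = length_bp/count`,
`length_pct = 100·length_bp/footprint`, and
`count_per_mb = count/(footprint/1e6)`. An empty target yields zeros with
a warning, not NaNs.

Significance is a permutation test: each of `n_iter` iterations (default
1,000) re-draws the target at random genomic positions matched on region
count and on mean/SD of region length, and recomputes the metric.
Lengths are drawn from a normal distribution truncated at ≥ 50 bp via
inverse-CDF sampling (a mode that resamples the observed lengths is also
available); chromosomes are chosen proportional to length; starts are
uniform such that the region fits; random regions may overlap each other
(no mutual-avoidance constraint), and an optional `exclude` set (e.g.
assembly gaps) is honored by rejection sampling with at most 1,000 retries
per region, failing loudly if infeasible.

The enrichment p-value is the fraction of null values **strictly greater**
than the observed value, so ties favor significance and the smallest
attainable p is 0 (reported as `< 1/n_iter`); a +1 correction is
deliberately not applied, to match the convention of reporting
`p < 0.001` at 1,000 iterations. A strictly-less depletion p is reported
alongside. Iteration *i* uses a sub-seed derived from the master seed, so
results are reproducible and trivially parallelizable.

## Chromosome-arm positional analysis

Cattle autosomes are acrocentric, so each chromosome is one arm; an
event's relative position is `midpoint / chromosome_length` (BND events
use their single breakend). Positions are binned into 20 half-open 5%
bins.

The terminal-enrichment test excludes the terminal 5% of each chromosome
at both ends (assembly ends are artifact-prone), takes the next 5 Mb
inward on each side as "end windows", and the remainder as interior.
End-window vs interior event densities (events/Mb — densities, not raw
counts, because window sizes differ) are compared across chromosomes with
a paired two-sided Wilcoxon signed-rank test; a pooled unpaired
Mann-Whitney over per-window densities is reported as a secondary
statistic. Chromosomes shorter than `2·(terminal + window)` are skipped
with a warning; if every paired difference is zero the p-value is defined
as 1. Which Wilcoxon variant the original analysis used is not
recoverable; the paired test is the default because it respects
per-chromosome pairing.

## Sharing analysis

Filtered DEL/DUP calls from all samples are clustered into events by
single-linkage under an overlap rule (default ≥ 1 bp same-type overlap; a
50% reciprocal mode is provided, the common alternative in CNV
literature). A cluster with exactly one member call is a singleton —
"occurred only once in one sample" — and is removed regardless of group;
a variant seen in two sperm cells of one bull is therefore *not* a
singleton. Surviving events are assigned to the 7 Venn categories over
{Sample1-sperms, Sample2-sperms, Sample1-trio}, with event counts,
percentages, and lengths per category. Because the length-accounting
convention behind published category length-percentages is not stated,
both conventions are reported: the union footprint of member calls
(default) and the sum of member lengths.

## Annotation enrichment

Regions are intersected (≥ 1 bp) with GFF3/GTF gene features (transcript,
exon, CDS, UTRs, start/stop codon) through `gffutils`. Term enrichment is
generic over any term→item map (GO, KEGG, QTL traits...): per term a 2×2
table (in/out of target × with/without term) is tested with a two-sided
Fisher exact test and corrected by Benjamini–Hochberg, flagging adjusted
p < 0.05. No live ontology or QTL databases are bundled or queried.

## The synthetic-data generator

The generator emulates the study design — two groups of haploid sperm
cells (8 and 6 deep-coverage cells at 4× each) from two bulls plus a
diploid trio (proband 40×, sire 10×, dam 20×) — and plants known
structure:

* **Genome**: 29 autosomes drawn uniformly from 42–158 Mb by default.
* **Repeats**: per-class densities (defaults LINE 23%, SINE 15%, LTR 4%,
  DNA 2%, satellite 2%, roughly mammalian-like); features are placed one
  per slot so within-class features never overlap and realized density
  tracks the request to well within ±10% relative.
* **SegDup pairs**: fragment lengths log-normal around 2 kb, identity
  normal (truncated to (0, 1]), orientation and interchromosomal flags
  Bernoulli with study-like defaults (63% reversed, 60% interchromosomal).
* **Sharing profile**: the default plants the worked example's 433
  non-singleton DEL/DUP events across the 7 Venn categories
  (18/45/158/18/123/56/15). Shared events receive identical coordinates
  in every carrying sample (a configurable jitter stresses the overlap
  rule); single-group events are planted in two samples of that group so
  they are non-singletons. All planted events are mutually
  non-overlapping, so clustering recovers the planted categories exactly
  when jitter is 0.
* **Event lengths**: log-uniform on [50 bp, 5 Mb] by default so both
  filter bounds are exercised. Tests that emulate realistic single-sperm
  CNVs use 50 bp–20 kb: the worked example's 433 events span 1,736.6 kb,
  i.e. ≈ 4 kb per event, so multi-Mb events are atypical of this data.
* **Distal bias**: with probability `distal_bias` an event midpoint is
  placed uniformly in the distal zone of a chromosome — the terminal
  `terminal_frac` (5%) **plus** `distal_window_bp` (default 5 Mb) further
  inward. The extension is deliberate: the terminal test excludes the
  strict terminal 5% as artifact, so a generator that confined distal
  events to that excluded sliver would produce data in which the observed
  subtelomeric enrichment is undetectable by construction. Setting
  `distal_window_bp=0` recovers strict terminal-fraction placement.
* **Satellite co-location**: with probability `satellite_colocation_prob`
  a (non-distal) event midpoint is placed inside a random satellite block.
* **Support counts**: shared events always receive filter-passing PE/SR
  (they model confidently detected variants); background singletons pass
  with probability `support_pass_fraction` (default 0.9), with failing
  draws guaranteed to fail both filter branches at any coverage.

Randomness comes from sub-streams of one master seed keyed by (stage,
sample), so outputs are byte-identical across runs and adding a sample
does not shift earlier draws. A per-event and a per-call truth table
record Venn category, singleton status, distal/satellite placement, both
length conventions, and filter pass flags.

**What the generator does not emulate**: read-level data (FASTQ),
amplification bias and uneven coverage of whole-genome-amplified single
cells, aneuploidy, caller-specific artifacts (breakpoint imprecision
beyond the jitter knob, genotype errors), repeat families with realistic
sequence, or linkage between repeats and SegDups. Passing tests therefore
demonstrate the *statistics* behave correctly on data with known
structure, not that the upstream caller is accurate on real sperm data.

## Problem sizes in the statistical suites

The calibration and power suites use deliberately small study conditions
chosen once: a 50 Mb toy genome (5 × 10 Mb; LINE 10%, satellite 2%) for
permutation calibration (200 repetitions × 200 iterations, 100 regions of
mean 5 kb ± 2 kb) and satellite-recovery (50 runs, ~200 planted CNVs at
co-location 0.8); the full 29-chromosome genome for the terminal test
(50 runs × ~1,000 events at distal bias 0.6 and 0). The worked-example
summaries run at the published table sizes (27,560 pairs; 433 events).

## Known limitations

* The segmental-duplication *detection* step is out of scope; pairwise
  fragment tables are consumed, not produced.
* The support-rule reading, merge tolerance, Wilcoxon variant, sharing
  overlap rule, and length-accounting convention are all published
  ambiguously; each is parameterized, defaults documented above.
* Headline study-scale numbers that require raw reads and external
  callers (total SV counts, genome-wide SegDup coverage, absolute
  enrichment folds on the real assembly) are not reproducible from
  summaries and are not claimed; the package reproduces every
  count-derived percentage and all qualitative/statistical behaviors.
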