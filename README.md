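# spermcnv

Downstream interval statistics for copy-number-variation (CNV) call sets
from single-sperm sequencing, built for the cattle setting: two groups of
haploid sperm cells from two bulls compared against the diploid
family-trio of one of them, with segmental duplications (SegDups) and
repeat annotation as the genomic context.

The package is for analysts who already have structural-variant calls
(LUMPY-style VCFs with `SVTYPE`, `END`, `PE`, `SR`), a pairwise SegDup
fragment table, a RepeatMasker-style repeat annotation and a gene/QTL
annotation, and need the downstream statistics:

* **SV filtering** — length filter (50 bp ≤ ℓ ≤ 5 Mb for DEL/DUP) and a
  coverage-scaled support filter: at fold-coverage *c* a call passes iff
  (PE > 0.75·c ∧ SR > 1) ∨ (SR > 0.75·c ∧ PE > 3); per-group tallies of
  counts, kb, and genome fraction covered.
* **Region toolkit** — merge/subtract/flank interval algebra (0-based
  half-open), nonredundant SegDup fragments, per-chromosome summaries,
  and pairwise-SegDup identity/orientation/interchromosomal percentages.
* **Repeat enrichment** — Length%, Count/Mb and Average Length of each
  repeat class in a target set and its 5 kb / 20 kb flanks, with an
  empirical permutation test: *n* random region sets matched on count and
  mean ± SD length, p = #{null > observed} / n_iter.
* **Positional analysis** — relative arm positions (midpoint / chromosome
  length; cattle autosomes are acrocentric single arms), 5% bins, and a
  paired Wilcoxon test of event density in 5 Mb chromosome-end windows
  (after excluding the terminal 5%) vs chromosome interiors.
* **Sharing analysis** — single-linkage clustering of same-type calls
  across samples, singleton removal, and Venn sharing percentages over
  the three groups.
* **Annotation enrichment** — ≥ 1 bp gene-feature overlap (GFF3/GTF) and
  generic two-sided Fisher exact term enrichment with Benjamini–Hochberg
  correction.
* **Synthetic data** — a generator that emulates the study design
  (sharing profile, distal bias, satellite co-location, per-sample
  coverage) with full truth tables, so every statistic is testable
  without any sequencing data.

See `docs/methods.md` for models, parameter defaults and conventions.

## Worked example

The published pairwise-SegDup tallies and the 433-event CNV sharing
profile ship as composition targets; all percentages below are computed by
the package's summarizers, not stored:

```python
from spermcnv.demo import segdup_pairs_matching_counts, demo_sharing_venn
from spermcnv.segdup import summarize_segdup_pairs

s = summarize_segdup_pairs(segdup_pairs_matching_counts(seed=0))
print(f"identity > 80%: {s.pct_identity_gt[0.8]}%   > 90%: {s.pct_identity_gt[0.9]}%")
print(f"reversed: {s.pct_reversed}%   interchromosomal: {s.pct_interchromosomal}%")

venn = demo_sharing_venn(seed=1)
print(venn[["category", "n_events", "pct_events", "pct_length_union"]]
      .to_string(index=False))
```

prints

```
identity > 80%: 44.99%   > 90%: 12.24%
reversed: 63.41%   interchromosomal: 60.31%

                                  category  n_events  pct_events  pct_length_union
                            Sample1-sperms       123       28.41             26.60
               Sample1-sperms&Sample1-trio        45       10.39             14.63
Sample1-sperms&Sample1-trio&Sample2-sperms        18        4.16              6.07
             Sample1-sperms&Sample2-sperms       158       36.49             28.60
                              Sample1-trio        15        3.46              6.72
               Sample1-trio&Sample2-sperms        18        4.16              7.98
                            Sample2-sperms        56       12.93              9.38
```

Of the 433 non-singleton DEL/DUP events, 4.16% are seen in all three
groups, 51.04% in exactly two (10.39% sperm1∩trio, 36.49% sperm1∩sperm2),
and 28.41% / 12.93% / 3.46% are private to sperm1 / sperm2 / the trio —
the sharing structure the pipeline is designed to quantify. The
`demo_sharing_venn` example runs the whole path: simulated call sets →
length + support filters → clustering → singleton removal → Venn summary.

## Command line

```sh
spermcnv run-all --config config.yaml --seed 7 --out-dir out/
```

Subcommands `simulate`, `filter`, `segdup-summarize`, `enrich`, `arms`,
`share`, `annotate`, `run-all` and `validate-config` write per-stage TSVs
under `out-dir/<stage>/` plus a `manifest.json` (config snapshot, input
checksums, seeds, row counts) that fully determines a deterministic
re-run. With no config, a built-in demo simulation runs end to end.

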