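# varsieve

Characterization and hard filtering of false-positive variant calls in
haploid (bacterial) VCFs.

`varsieve` implements a full benchmarking-and-filtering loop:

- **`vcf_model`** — parse VCF 4.x (multi-allelic splitting, FILTER
  preservation), normalize calls (left-alignment, MNP decomposition),
  classify SNP/INS/DEL/MNP/COMPLEX, and extract nine per-call positional
  characteristics (QUAL, quality-by-depth, variant allele frequency, depth,
  variant-supporting reads, distance to nearest SNP/indel, strand and
  mapping-direction balance) across configurable caller *tag dialects*.
  Unavailable is a first-class state, never conflated with zero.
- **`truth_builder`** — build truth sets: pileup-consensus soft-masking
  (strict `< 99 %` rule), discordant-call masking, and the
  consensus/ambiguous partition of whole-genome-alignment call sets into a
  truth VCF plus confident-region BED; also a sweep-grid enumerator.
- **`comparator`** — label PASS calls TP/FP against the truth inside
  confident regions (exact chrom/pos/ref/alt matching on a haploid genome)
  and compute precision/recall/F-score per variant type.
- **`filter_engine`** — `value <= threshold` hard filters with the default
  SNP (9 filters) and indel (6 filters) sets; *independent* mode for
  efficacy tables and *sequential* mode that applies proximity "thinning"
  last, with distances recomputed over surviving calls.
- **`efficacy_stats`** — per-filter removal percentages, unique-detection
  counts, the OR-combined row and the value-added ratio (%FP removed per
  %TP removed), plus TP-vs-FP histogram summaries.
- **`synth_data`** — seeded generator for references, planted truth sets
  and pipeline VCFs containing TPs, FNs and two FP classes
  (data-deficient and data-surfeit), with FPs preferentially clustered
  near indels. Everything is testable offline.

## CLI

```sh
# generate a synthetic fixture suite (reference, truth, per-pipeline VCFs)
varsieve simulate --config sim.toml --out fixtures/

# intersect alignment VCFs into a truth set
varsieve build-truth --vcf a.vcf --vcf b.vcf --fai ref.fa.fai --out-prefix truth

# label a query VCF TP/FP and write metrics
varsieve compare --query pipe.vcf --truth-vcf truth.vcf \
    --confident-bed confident.bed --fai ref.fa.fai --out-prefix cmp

# per-filter efficacy tables (independent or sequential/thinning mode)
varsieve efficacy --query pipe.vcf --truth-vcf truth.vcf \
    --confident-bed confident.bed --fai ref.fa.fai \
    --mode independent --out-prefix eff

# enumerate alignment-sweep parameter grids
varsieve sweep --grid 25:200:25 --mode lockstep
```

A simulation config is a single TOML file:

```toml
seed = 11
n_snps = 100
n_indels = 20
p_near = 0.5            # FP clustering probability near truth indels

[contigs]
chr1 = 50000

[[profiles]]
pipeline_id = "pipe"
dialect = "generic"     # or "gatkish", "lean", or a custom INI dialect
recall_snp = 0.95
fp_snps = 200
```

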