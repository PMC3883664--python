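# Methods

## Analysis model

The pipeline treats a cohort of tumor/normal pairs profiled three ways from
the same tumor tissue: exome capture after whole-genome amplification (WGA,
multiple-displacement type), exome capture of unamplified DNA (a different
capture design), and RNA-seq. All comparisons operate on bi-allelic SNV calls;
indels, MNVs and symbolic alleles are skipped at read time with a logged
count, never silently dropped. The match key everywhere is
`(chrom, pos, alt)` — matching on position alone would count discordant
alleles as concordant. Multi-allelic records are decomposed into one call per
alternate allele present in the genotype.

Coordinates follow the source standards: variants are 1-based (VCF),
intervals 0-based half-open (BED). A variant at position `p` lies in interval
`(s, e)` iff `s < p <= e`; this conversion appears in exactly one place
(`IntervalSet.contains`) and is property-tested against a brute-force
enumerator.

### Thresholds

All cutoffs live in `ThresholdConfig`:

| parameter | default | meaning |
|---|---|---|
| `min_call_depth` | 11 | calling filter "coverage > 10" as a strict inequality |
| `min_call_qual` | 30 | phred quality must exceed 30 |
| `low_cov_threshold` | 10 | rescue "coverage < 10" ⇒ depth ≤ 9 |
| `het_hom_exclusion` | 3.0 | het/hom ratio above this excludes the sample |
| `minor_allele_min` | 0.20 | minor allele fraction floor for bi-allelic expression (inclusive) |
| `fpkm_min` | 1.0 | FPKM floor for the expressed-gene rule |
| `fpkm_transcript_min` | 2.8 | FPKM threshold for transcripts entering the bi-allelic comparison |
| `expressed_quantile` | 0.75 | expressed genes = top 75% by FPKM |

Both the calling rule (depth > 10) and the rescue rule (depth < 10) are
strict, so depth exactly 10 satisfies neither. Rather than silently absorbing
that gap into one side, rescue reports it as a separate `cov_gap` class; the
four-way classification (low-coverage / gap / supported / unsupported) is
checked to be exhaustive and exclusive on every input.

The exclusion threshold 3.0 sits between the het/hom ratio clusters observed
in practice (usable samples ≤ ~2.2, anomalous samples ≥ ~4.5) and is
configurable. Ts/Tv is implemented as transitions (A↔G, C↔T) over
transversions — exome-wide values near 3 are only obtainable with this
orientation.

### Denominator conventions

Partition percentages are reported under two conventions because both are in
common use: `union` (each class over WGA-only + shared + unamplified-only) and
`method_specific` (each unique class over its own method's total, shared over
the union). The report names the convention in its header; `union` is the
default for cohort averages. Percentages round half-away-from-zero (Python's
built-in banker's rounding would, e.g., turn a mean of 35.75 into 35.7).

### Somatic identification

A tumor call is a somatic candidate iff its key is absent from the matched WGA
normal *and* the normal covered the position with depth ≥ 11. The coverage
gate prevents allelic dropout in the normal from manufacturing mutations —
precisely the failure mode the comparison is designed to expose. Somatic
calls and their confirmation against unamplified data are restricted to the
shared target space so capture-design differences do not deflate the
confirmation rate. A consequence of deriving the somatic set from WGA tumor
calls is that the unamplified-only concordance class can never contain somatic
keys; its mutation fraction is structurally 0 and is reported for
completeness.

### RNA validation

The expressed-gene rule is implemented as rank-then-filter: genes ranked by
FPKM descending, ranks ≤ ceil(0.75·N) kept, then the FPKM ≥ 1 floor applied
(the alternative — filtering before ranking — is a defensible reading; the
implemented one is documented here and deterministic, with rank ties broken by
gene id). The transcript threshold FPKM > 2.8 *compounds* with the
expressed-gene rule in the bi-allelic analysis rather than replacing it.
"Minor allele of all transcripts" is operationalized per variant as
min(VAF, 1−VAF) from RNA alt/total depths, the only quantity computable from
call-level data; the 20% floor is inclusive.

## The simulator

`synth_cohort` generates the statistical structure the analysis assumes, on a
compressed toy genome, in exactly the formats the pipeline reads. Defaults
(all in `CohortConfig`) are the study conditions:

* 16 patients, 11 with RNA; 2 chromosomes × 1 Mb; 375 genes of 400 bp
  (150 kb coding space).
* 12,000 germline SNVs per patient, het fraction 0.65 (het/hom ≈ 1.9),
  transition probability 0.75 (Ts/Tv ≈ 3); 1,500 somatic het SNVs, disjoint
  from germline by construction; an optional purity knob scales somatic VAF.
* Two capture designs as 500 bp intervals over gene loci, 360 and 345
  intervals with 90% locus overlap; WGA assays are captured with design A,
  unamplified with design B; the comparison space is coding ∩ A ∩ B.
* Depth per base is negative-binomial with `var = mu + d·mu²`: WGA mean 60 at
  dispersion d = 1.0 (the heavy low-coverage tail that drives discordance),
  unamplified mean 74 at d = 0.3 (a realistic but far lighter tail). RNA depth
  per gene scales with FPKM (10× FPKM at dispersion 0.2).
* Allelic dropout in WGA assays only: each het site is lost with probability
  `dropout_prob/2` (= 0.025) and converted to homozygous-alternate with
  `dropout_prob/2`, independently per assay (tumor and normal are amplified
  separately).
* False positives in WGA assays only: Poisson with mean `wga_fp_rate` per Mb
  of capture target, placed uniformly on adequately covered non-variant
  positions, as low-VAF (0.15–0.35) het calls whose quality passes the filter
  by construction — they must survive filtering to be discoverable by the
  rescue analysis. The toy genome is ~200× smaller than a real exome target,
  so the default rate (8,000/Mb) is the per-Mb equivalent of realistic
  per-patient counts (~1,400 per assay), not a biological per-Mb rate.
* Expression: 40% of genes expressed (log-normal FPKM, μ=1.3, σ=1.2 on the
  log scale; silent genes uniform below 0.5); 60% of expressed genes
  mono-allelic. Mono-allelic het sites express one haplotype (fair coin per
  site, unphased truth): the reference haplotype leaves no variant evidence,
  the alternate haplotype presents as a homozygous-looking call — either way
  the gene cannot qualify as bi-allelic.
* Quality is `40 + 0.5·alt_depth + N(0, 5)` floored at 1 and rounded to one
  decimal (htslib stores QUAL as float32; one decimal survives the
  round-trip). At deep coverage real variants essentially never fail the
  quality filter, so the deterministic bias-free limit (dropout 0, FP rate 0,
  deep equal coverage) reproduces the identity partition exactly.

Observed call sets are the truth passed through depth sampling, dropout, the
calling filter and FP injection; *evidence* files additionally contain every
site with ≥ 1 variant-supporting read regardless of depth/quality — the
stand-in for unfiltered alignments in the rescue analysis. One seed drives
everything through spawned per-patient generators; identical seeds give
byte-identical output trees.

### What the simulator does and does not emulate

It reproduces the mechanisms the analysis measures: over-dispersed WGA
coverage causing low-coverage discordance, dropout causing unamplified-only
calls with no WGA evidence, filter-passing FPs causing WGA-only calls that
are unsupported in well-covered unamplified data and that survive normal
subtraction as spurious "mutations". It does not model read-level errors,
GC-driven capture efficiency, mapping artifacts, subclonal VAF structure,
linked (haplotype-phased) dropout, splice-aware RNA coordinates, or
contaminated/anomalous samples (the exclusion rule is exercised in tests by
constructing anomalous call sets directly). Variant density is ~200×
compressed along with the genome; consequently per-gene variant counts are
high and the fraction of bi-allelic genes containing a shared DNA variant is
near its ceiling. Passing tests therefore demonstrate correctness of the
statistical machinery under the modeled mechanisms, not calibration of any
particular real instrument.

## Problem sizes

The default cohort (16 patients × ~13.5k variants × 4 assays plus per-base
coverage over ~190 kb of target per assay) simulates in ~25 s and analyzes in
~25 s on one CPU; `scripts/acceptance.py` runs the full chain in about a
minute. Tests use `CohortConfig.small()` (2 patients, 800 germline sites,
~18 kb coding) except where statistical recovery requires 10⁴ sites, and the
parameter-recovery acceptance runs 10 fixed seeds at n = 10⁴ with deep
low-dispersion coverage so each configured parameter (het fraction, transition
probability, dropout probability, FP rate) is identifiable from a single
mechanism and compared within 3 sampling SDs of its estimator.

## Numerical choices

* Percent and ratio rounding: half-away-from-zero at the precision of each
  report column (whole percents for partition classes, 1 decimal for rescue /
  somatic / RNA percentages, 2 decimals for QC ratios).
* `vaf_r2` requires ≥ 3 shared calls and nonzero variance on both axes;
  otherwise nan, flagged in the log. Least-squares slope/intercept are
  reported alongside R².
* Empty classes/sets (no somatic candidates, no bi-allelic genes, empty
  partition classes) yield nan rows flagged in the log; cohort averages are
  taken over non-missing entries only, and the Average row is re-derived from
  the per-patient rows at report time as a consistency assertion.
* A coverage track answers depth 0 for absent positions, but a whole missing
  contig is a hard error in rescue — a truncated track must not silently read
  as zero coverage.
* With zero WGA-unique calls the false-positive indicator is reported as 0
  (no calls are flagged), while low-coverage percentages of an empty class
  stay undefined.

## Known limitations

Single-base SNVs only; genotype-level concordance (het vs hom at the same
key) is not classified; no statistical test accompanies the rescue
interpretation (it is descriptive by design); FPKM values are inputs, never
estimated; the simulator's independence assumptions (per-site dropout,
per-position depth) understate the spatial correlation of real amplification
bias.
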