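# Methods

This note records the models, rules and numerical choices behind atavlite,
what the synthetic-data generator does and does not emulate, and the known
limitations.

## Coverage codec

Read depth is stored at bin resolution only: a [0–9], b [10–19], c [20–29],
d [30–49], e [50–199], f [≥200], run-length encoded as `<run><letter>`
tokens inside fixed 1000-bp blocks anchored at 0-based multiples of 1000
per chromosome. Tokens are maximal runs, which makes the encoding of any
bin sequence unique; the decoder rejects non-maximal and malformed input.
Consequences of the lossy contract:

* Depth-threshold queries are only answered for thresholds that are bin
  lower bounds (0, 10, 20, 30, 50, 200). Any other threshold raises a
  validation error rather than silently approximating — 10 is the one the
  workflows use, and the bins were designed so that it is exact.
* Sites absent from a sample's depth input inside an otherwise covered
  block are encoded as depth 0 (depth tools omit zero-coverage sites);
  whole blocks with no input do not exist in the table and queries there
  return a distinct "no data" state. Trailing partial blocks are allowed.
* Compression is measured, never assumed: `compression_report` compares
  the per-site three-column text size against the stored RLE bytes. Long
  homogeneous segments give ratios in the hundreds-to-thousands; per-site
  bin alternation can make the encoding larger than the input, and the
  report says so.

## Variant normalization

All calls are keyed by a canonical spelling: shared-suffix trimming
(fetching the preceding reference base whenever an allele would empty,
which shifts indels left through repeats), then shared-prefix trimming,
keeping the VCF anchor-base convention. The operation is idempotent and
maps every representation of the same haplotype edit to the same
`chrom-pos-ref-alt` id; the test suite verifies this against an oracle
that enumerates all representations of a random edit and picks the
minimal-length, minimal-position one. Multi-allelic records are decomposed
per alt before normalization. Left-alignment that would run off the
supplied reference window raises an explicit error instead of returning a
partially shifted variant.

## Store semantics

* A sample enters the store once; re-ingesting the same sample id is an
  error (idempotent pipelines should drop and re-add).
* Region/gene queries return, for every variant, a partition of the query
  cohort into called / coverage-inferred hom-ref / no-data. Hom-ref
  inference requires bin ≥ b (depth ≥ 10), the same threshold the trio
  logic uses.
* Internal allele frequency is AF = (het + 2·hom_alt) / (2·informative),
  where informative = called + inferred hom-ref. With zero informative
  samples AF is undefined (reported as null), never zero.
* FILTER is stored per call; samples may disagree about a variant's
  filter status and both values are kept.
* Every analysis writes an audit log (tool version, store content digest,
  full parameter set, sample-list digest, output digests). Re-running with
  a logged configuration against the same store reproduces outputs
  byte-identically; this is tested.

## Qualifying-variant filters

A (sample, variant) genotype qualifies iff it passes every configured
filter; unset filters pass everything. Per-genotype: FILTER PASS (on by
default), and minima on QUAL, GQ, QD, MQ, VQSLOD — a genotype missing a
metric that has a configured minimum fails it. Per-variant: allowed
effects, internal MAF cap (computed on the analysis cohort, independent of
the filter configuration — this is what makes collapsing-lite exact),
external MAF cap, and named score thresholds against attached annotation
tables. Two asymmetric null conventions, both deliberate: a variant absent
from the external AF table counts as frequency 0 (novelty is the signal),
while a variant with no value for a configured score fails that score
filter (an unscored variant cannot demonstrate deleteriousness). A score
name that no attached table provides is a configuration error, never a
silent pass.

## Coverage harmonization

Two site-level tests between cases and controls, run before QV selection:
absolute difference of covered proportions (default max 0.07) and an exact
two-sided binomial test of "number of covered individuals who are cases"
against the cohort case fraction (default alpha 0.05), with the R-style
tie convention (sum of point probabilities ≤ observed × (1 + 1e-7)). A
site with zero covered individuals is kept with an undefined p and a
logged warning — it contributes no calls anyway. Defaults are
configurable and logged.

## Association tests

Fisher's exact test is two-sided on the carrier 2×2 table; odds ratios are
the unconditional ad/bc with 0/∞ at empty margins and NaN for 0/0; genes
with no carriers at all are flagged uninformative with p = 1. A Bonferroni
threshold 0.05/n_genes accompanies the table; no FDR, matching collapsing
practice. Firth regression maximizes the Jeffreys-penalized likelihood by
Newton iteration on the modified score with step-halving; convergence is
max |U*| < 1e-10 within 100 iterations, non-convergence raises an error
carrying the last iterate and gradient norm. The reported p is the
penalized LRT of the carrier coefficient (χ²₁), chosen over Wald for its
behavior in sparse tables; a constant carrier column is flagged and not
fitted.

## Permutation inflation factor

Labels are permuted preserving the case count (n_perm ≥ 100 enforced, seed
mandatory and logged). Carrier counts per gene are invariant under
permutation, so per-round Fisher p-values come from a per-gene
hypergeometric lookup (identical to the per-gene test values; asserted in
tests). expected_p[i] is the mean i-th order statistic over rounds, and
λ is the ratio of median χ²₁ quantiles of observed vs expected p. When
either median quantile is exactly 0 — which happens on small gene panels
where most two-sided p equal 1 — λ is undefined and reported as 1 with a
warning rather than as a spurious 0 or ∞. The estimator is meaningful for
large panels: at 500 genes the null spread is roughly ±10–15% around 1
(the calibration test uses 500 genes × 200 samples × 1000 permutations),
and at a few dozen genes the median of discrete p-values makes λ
essentially uninformative — a limitation of the statistic, not of the
implementation.

## Collapsing-lite

A previous run's QV table carries every annotation, quality metric and the
(configuration-independent) internal MAF needed to re-apply filters, so a
stricter configuration can be re-run without touching the store. Strictness
is a partial order checked filter-by-filter (minima may rise, caps may
fall, effect sets may shrink, score thresholds may be added or tightened);
any widened filter is rejected with its name. Equivalence with a full run
under the strict configuration is property-tested over random config
pairs. The collapsing model (dominant/recessive) may change between runs —
it is a matrix rule, not a filter.

## Trio diagnostics

Genotype states per site are "ref" (no call), het, hom-alt; parental
coverage states are covered (bin ≥ b), low (bin a) and no-data. The
classifier: child het with both parents uncalled is de novo — confirmed
when both absences are backed by sufficient coverage, possible otherwise;
any carrying parent means inherited. Child hom-alt is newly homozygous
when both parents are consistent with het carriers — a called het parent
with sufficient coverage confirms, an uncalled parent with thin coverage
leaves ambiguity (possible), a confidently hom-ref or a hom-alt parent
excludes the category. A comp-het pair is confirmed when one parent
carries exactly the first variant and the other exactly the second
(trans); a parent carrying both makes the pair in-phase and excluded;
unobservable parental genotypes (absence over thin coverage) downgrade
only the affected pair to possible, not the whole gene. All of this is
verified against brute-force classifiers that enumerate every genotype ×
coverage combination. Mosaic transmission is flagged when a transmitted
variant's parental alternate-allele fraction is below 0.20 with ≥ 3 alt
reads and AD-depth ≥ 10 (thresholds configurable and logged; sites without
AD are skipped and counted). Affected children without two genotyped
parents fall back to singleton mode (filter-only prioritization) with a
notice; controls that share a family with any analyzed case are excluded
from control-frequency denominators. The report surfaces candidates with
genotypes, coverage bins and clinical-annotation tiers; it deliberately
does not assign ACMG classes — that is a human review step.

## KnownVar annotation

Clinical assertions are plain TSVs at variant and gene level. Lookup
returns three labeled tiers: exact variant; same site, different alt; and
proximity — all records within ±window bp (default 10) excluding exact
matches, so the proximity tier with window 0 coincides with the same-site
tier. Sources are reported side by side; no precedence is imposed when
ClinVar-style and HGMD-style rows disagree.

## Synthetic-data generator

The generator is the package's test bed and defines the conditions every
calibration claim refers to. Cohorts: per gene and sample, carrier
indicators are Bernoulli at the baseline rate (default 0.10 for file-based
cohorts, 0.05 for matrix-level calibration runs); case enrichment
multiplies the baseline odds, so multiplier 1 is the exact null. Carriers
receive one het (10% hom-alt) SNV at a random site of the gene, with
plausible quality metrics and a 5% rate of failing GQ to exercise filters;
20% of sites (configurable) get a common external allele frequency to
exercise external-MAF filters. Depth profiles are homogeneous segments
with geometric run lengths (mean 150 bp) and normal depth (mean 60),
emitted as BED runs. Trios are Mendelian except the planted events;
mosaic plants draw the parental alternate fraction near 0.10, inside the
detection box. Reference sequences embed homopolymer/STR runs so that
left-alignment is actually exercised. Outputs are byte-identical per seed,
and a truth manifest records every planted carrier and event so recovery
can be scored exactly.

What the generator does **not** emulate: linkage disequilibrium, realistic
site-frequency spectra, multi-nucleotide and structural variants, batch
effects in quality metrics, sequencing-platform coverage biases, and
population structure/relatedness beyond declared pedigrees. Passing tests
therefore demonstrate the correctness of the algorithms and their
calibration under the stated statistical model, not performance on real
cohort artifacts — in particular, the related-sample pruning and ancestry
adjustment that real collapsing studies perform with external tools are
out of scope here.

## Problem sizes used in tests

Deliberately desk-scale: the cohort fixture is 50 samples × 10 genes, the
calibration fixtures up to 500 genes × 200 samples × 1000 permutations,
exact-test enumeration covers all 2×2 tables with total ≤ 30, and the
codec round-trip runs 10,000 random blocks. These sizes make the full
suite run in well under a minute of compute per heavy test while keeping
every estimator in the regime where its calibration claims are testable.
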