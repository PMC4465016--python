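# Methods

## Model

Allelic imbalance (AI) at a heterozygous SNP is modelled at the level of one
sample × SNP cell. Each sequenced fragment covering the SNP carries exactly
one allele, so with `n = ref + alt` informative fragments the reference count
is `k ~ Binomial(n, p)` where `p` is the (unknown) expressed reference
fraction. The null hypothesis of balanced expression is `p = p₀` with
`p₀ = 0.5`, or a cell/SNP-specific `p₀` when mapping bias has been measured.
Fragments are treated as independent draws; the model carries no
overdispersion term (no beta-binomial), no haplotype aggregation across SNPs,
and no phasing — each SNP × sample cell is tested on its own.

Counts of the two nucleotides that are neither ref nor alt are excluded from
`n`. They are reported separately (`other_count`) as a sequencing/mapping
error diagnostic; a high value flags a problem cell rather than entering the
test.

## Tests

**Exact binomial.** Two-sidedness follows the minimum-likelihood rule:
`p = Σᵢ P(X = i)` over all `i` with `P(X = i) ≤ P(X = k)`, `X ~ Binomial(n, p₀)`.
Point probabilities are compared with a relative slack of 1e−7 so that exact
pmf ties (e.g. the symmetric pairs at `p₀ = 0.5`) are not split by
floating-point noise; this matches the convention of the classical exact-test
implementations. The test is discrete and therefore conservative: at depth 50
and α = 0.05 its realized type-I error is near 0.03.

**Chi-square.** The 1-df goodness-of-fit statistic
`X² = (k − np₀)²/(np₀) + ((n−k) − n(1−p₀))²/(n(1−p₀))` without continuity
correction, upper-tail p-value. No correction is applied because the exact
test covers small `n`, and the uncorrected statistic has a clean closed form.
The gap between the two tests' p-values is of the order of the binomial pmf
at the observed count, ≈ √(2/πn) in the worst case — about 0.056 at n = 200
and under 0.02 only from n ≈ 1600 — so agreement between them is a large-`n`
property, verified in the suite at depth 2000.

**Gating.** Cells with `n < min_depth` (default 10) are missing, never
p = 1. By default only heterozygous cells are tested (`het_only=True`), since
AI is undefined for homozygotes; heterozygosity comes from provided genotypes
(VCF GT) where available, otherwise from count-based inference.

**Adjustment.** Benjamini–Hochberg or Bonferroni, applied jointly over all
non-missing cells of a result matrix; missing cells stay missing.

## Genotype inference and MAF

Where genotypes are not provided, a cell is called heterozygous when
`n ≥ 10` and the minor-of-(ref, alt) fraction is ≥ 0.10; homozygous for the
majority allele when the minor fraction falls below the band; no-call below
the depth gate. At depth 30 a truly balanced het cell falls below the 0.10
band with probability ≈ 9 × 10⁻⁷, so inference is essentially error-free at
the depths where testing is meaningful. Provided genotypes always override
inferred ones.

MAF is computed from diploid genotype calls across samples:
`f = (2·hom_ref + het) / (2·called)`, `MAF = min(f, 1−f)`; no-calls leave the
denominator, and `maf_filter` keeps variants with MAF strictly greater than
the threshold (0.1 by default). Computing MAF from genotypes rather than from
pooled raw counts is a deliberate choice: pooled counts would fold expression
imbalance itself into the frequency estimate.

## Counting

Counting takes one single-base pileup per variant through the htslib engine
with all engine-side filtering disabled; admission is decided per record by
the package's own filter (MAPQ ≥ 20, base quality at the SNP ≥ 10, proper
pairs required for paired data, duplicates and secondary/supplementary
alignments dropped — all inclusive thresholds, all overridable). These
defaults are conventional for allele-specific expression work; they are
deliberately not tuned per dataset.

A fragment is one observation of one allele: when both mates of a pair
overlap the SNP, the first-encountered mate by query name wins and the second
is recorded as mate-deduplicated. Bases only count when the alignment places
a real base on the SNP — deletions, reference skips and soft clips contribute
nothing, as do non-ACGT base calls.

Strand assignment is declared, never auto-detected. For the dUTP
(fr-firststrand) protocol the second-in-pair read maps in the transcript's
orientation; fr-secondstrand is the mirror image; single-end reads are
treated as read1. For stranded data the `both` slice is maintained as
plus + minus; unstranded counts live entirely in `both`.

## Mapping-bias handling

Two complementary mechanisms:

1. `set_expected_from_counts` estimates per-SNP expected reference ratios
   from material whose truth is 1:1 — simulated reads distributed equally
   over both alleles, or genomic DNA. The estimate is the pooled
   ref/(ref+alt) across samples, clamped to [0.05, 0.95] (an expected ratio
   of exactly 0 or 1 would make the test degenerate), with a 0.5 fallback
   for SNPs under the pooled depth gate (default 10).
2. `mask_reference` rewrites the reference FASTA with `N` at every known SNV
   position so realignment penalizes neither allele. Only SNVs are masked;
   indels/MNVs are skipped and counted. Soft-masked lowercase bases become
   uppercase `N` since aligners treat `N` uniformly. Masking is idempotent,
   length-preserving, and verified base-by-base by `verify_masking`.

## Synthetic data

The simulator emits a uniform-random ACGT genome, SNVs with per-sample
genotypes (VCF 4.2), one coordinate-sorted indexed BAM per sample, and a
truth TSV of realized per-cell allele and strand counts. For each
heterozygous cell, exactly `depth` fragments are drawn with
`ref ~ Binomial(depth, fraction)`; alternative-allele fragments are then
dropped independently with probability `ref_bias` — an abstract model of
alignment loss, which drives the realized null fraction to
`f/(f + (1−f)(1−b))`. Fragments become proper FR pairs (all-match CIGAR,
MAPQ 60, constant base quality 40) whose flags encode the declared
strandedness protocol; a per-base substitution `error_rate` (default 0)
leaks counts onto the other nucleotides.

SNP positions are kept one fragment length from chromosome ends and two
fragment lengths apart so each fragment overlaps exactly one SNP, making the
truth table exact by construction at `error_rate = 0` — the closure property
(`recount_equals_truth`) that anchors the whole counting stack. Reads are
emitted pre-aligned: the package tests counting and statistics, not
alignment, and `ref_bias` stands in for alignment loss abstractly. The
generator therefore does not emulate splicing, indels, quality-score
profiles, position-dependent error, or genuine mapping ambiguity; tests that
pass on it validate the bookkeeping and the statistics, not robustness to
those real-data artefacts.

Defaults are chosen as ordinary bulk RNA-seq working values: depth 50
fragments per SNP (a practical testing depth), 2 × 75 bp reads on 120 bp
fragments (so mates overlap and exercise fragment deduplication), balanced
true fraction 0.5, no bias, no errors.

## Calibration experiments (problem sizes)

The suite and `scripts/acceptance.py` measure, at fixed seeds:

* type-I error and power on 2000 heterozygous cells at depth 50 (binomial
  ≈ 0.03 at α = 0.05 by discreteness; chi-square ≈ 0.06; power ≈ 0.79
  against a true fraction of 0.7);
* mapping-bias correction on 1000 cells at depth 200 with `ref_bias = 1/3`
  (realized null fraction 0.6): testing against 0.5 rejects ~70% of null
  cells, testing against ratios learned from a disjoint null simulation
  restores ≈ 0.05. Depth 200 is used here because a 0.6-vs-0.5 shift is a
  small effect — at depth 50 the exact test has only ~21% power against it
  and the experiment would measure noise;
* counting equality against a brute-force per-read oracle on 50 synthetic
  BAMs (with randomly degraded MAPQ/flags/base qualities so the filters have
  observable effect), simulation closure over 10 seeds, exact-binomial
  agreement with rational-arithmetic enumeration over all n ≤ 60 at
  p₀ ∈ {0.3, 0.5, 0.7}, masking exactness on 20 random genomes, and fraction
  recovery over 500 SNPs at depth 100.

## Numerical and design notes

* Coordinates are 1-based, fully closed, everywhere user-facing (VCF/GTF
  convention); region subsetting includes both endpoints.
* The nucleotide axis is exactly (A, C, G, T); `top_alleles` resolves
  missing ref/alt as the two most-counted nucleotides with alphabetical
  tie-break (determinism over biological priors), flagging zero-count
  variants low-confidence.
* Missing values (under-depth fractions, ungated p-values) are NaN in
  arrays and `NA`/`.` in TSVs, never silently 0 or 1.
* P-value annotations on plots print three decimals down to 0.001 and
  scientific notation below ("nd" when missing).
* SVG output is deterministic (fixed hash salt, no embedded date); tests
  assert plot structure from element ids in the vector output, not pixels.
* Phenotypes are stored per sample as free-form key→value metadata; no
  phenotype–AI association modelling is in scope.

## Known limitations

* No overdispersion model: genuine biological/technical extra-binomial
  variance will inflate rejection rates on real data.
* Strandedness is trusted as declared; a wrong protocol declaration silently
  swaps the strands.
* Mate deduplication keeps the first-encountered mate's base; with
  sequencing errors the two mates can disagree at the SNP, and the choice is
  positional, not quality-weighted.
* The masking step does not run any aligner; measuring the realized
  bias-reduction of an N-masked realignment is outside the package.
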