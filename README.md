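# asekit

Detect, manage and visualize **allelic imbalance (AI)** in RNA sequencing data.

When an individual is heterozygous at a SNP inside an expressed gene, the reads
covering that SNP can be assigned to one chromosome copy or the other. Under
balanced expression the two alleles contribute reads in a 1:1 ratio; a
regulatory variant acting in *cis* skews that ratio, and the skew is detectable
in a single individual. `asekit` covers the whole desk-side workflow:

* **count** alleles over heterozygous SNPs from coordinate-sorted, indexed BAM
  files, with quality/flag filtering, per-fragment deduplication of overlapping
  mates, and strand assignment for dUTP-style stranded libraries;
* **manage** the counts in `ASEDataset`, a sample × SNP × nucleotide × strand
  tensor with genotypes, phenotypes, region/sample subsetting, allele-fraction
  and minor-allele-frequency accessors;
* **test** each SNP × sample cell for imbalance with an exact binomial or a
  1-df chi-square test, against 1:1 or against expected allele ratios estimated
  from balanced control material (mapping-bias correction), with
  Benjamini–Hochberg or Bonferroni adjustment;
* **mask** known SNP positions in a reference genome with `N` so realignment
  penalizes neither allele;
* **plot** per-SNP count/fraction barplots, dual-strand barplots ((+) strand
  up, (−) strand down, p-values beneath), and region-wide location plots;
* **simulate** complete synthetic experiments (FASTA + VCF + aligned BAM +
  truth table) with configured allele ratios, depth, strandedness protocol,
  reference bias and error rate.

## The statistics

At a heterozygous SNP with `k` reference reads out of `n = ref + alt`, the null
of balanced expression is `k ~ Binomial(n, p₀)`:

* **Exact binomial test** — two-sided by the minimum-likelihood rule:
  `p = Σ P(X = i)` over all `i` with `P(X = i) ≤ P(X = k)`.
* **Chi-square test** — `X² = (k − np₀)²/(np₀) + ((n−k) − n(1−p₀))²/(n(1−p₀))`,
  1 df, no continuity correction.

`p₀ = 0.5` by default. Because reads carrying the non-reference allele
mismatch the reference and map less often, the realized null ratio can exceed
0.5 (*mapping bias*); `set_expected_from_counts` estimates per-SNP expected
ratios from material with known 1:1 truth, and `mask_reference` produces an
N-masked genome for bias-reducing realignment. Cells below the depth gate, or
not heterozygous, are reported as missing — never as p = 1.

## Worked example

Simulate three liver samples with a true reference-allele fraction of 0.65
over four heterozygous SNPs, count, and test:

```sh
asekit simulate --out-dir sim --seed 11 --n-snps 4 \
    --samples liver1,liver2,liver3 --depth 60 --fraction 0.65
asekit count --bam liver1=sim/liver1.bam --bam liver2=sim/liver2.bam \
    --bam liver3=sim/liver3.bam --variants sim/variants.vcf \
    --min-mapq 0 --min-baseq 0 --out counts.tsv
asekit test --dataset counts.tsv --method binom --min-depth 10 \
    --adjust benjamini-hochberg --out results.tsv
```

which logs

```
asekit: Allelic imbalance test (binom), strand=both, min_depth=10, het_only=True
samples: 3  variants: 4
cells tested: 12 of 12
significant at alpha=0.05: 9
significant after benjamini-hochberg adjustment: 9
```

and writes one row per SNP × sample cell:

```
sample  chrom  pos   id    ref_count  alt_count  fraction  expected  p_value      p_adjusted
liver1  chr1   753   snp1  44         16         0.733     0.5       0.000394     0.00118
liver1  chr1   4325  snp2  44         16         0.733     0.5       0.000394     0.00118
liver1  chr1   5197  snp3  46         14         0.767     0.5       4.22e-05     0.000507
liver1  chr1   6241  snp4  34         26         0.567     0.5       0.366        0.400
```

`fraction` is the observed reference fraction k/n; snp1–snp3 show the
simulated imbalance clearly (p ≪ 0.05 against the 1:1 null) while snp4's draw
happened to land near balance. The same dataset drives the plots
(`asekit plot bar|dualbar|location`) and the per-variant summary
(`asekit report`). The library API mirrors the CLI:

```python
from asekit import count_alleles, binom_test_matrix, CountFilter, read_variants

variants = read_variants("sim/variants.vcf")
ds, report = count_alleles({"liver1": "sim/liver1.bam"}, variants, CountFilter())
result = binom_test_matrix(ds.assign_top_alleles(), expected=0.5, min_depth=10)
print(result.summary())
```

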