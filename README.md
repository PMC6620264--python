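# cohortqc

Sample-level quality control for sequencing cohorts.

Genetic studies built on whole-exome or whole-genome sequencing are
routinely compromised by *sample-level* problems that no read-level QC
can see: swapped or mislabelled samples (sex mismatch), DNA
contamination, duplicated libraries, cryptic relatedness between
"unrelated" subjects, and discordant ancestry (population outliers).
Left in place, these samples distort association results downstream.
Detecting them from genotypes alone is hard in typical sequencing
studies because both the sample count and the variant count are small
compared to array-based GWAS.

`cohortqc` addresses this by merging the study cohort with a **benchmark
reference panel** — samples of known population, sex and pairwise
relationship drawn from the four major continental populations (AFR,
EAS, EUR, SAS) — before computing any statistic. The benchmark stabilizes
allele-frequency estimates, anchors the inbreeding-coefficient
distribution, and supplies labelled training data for the two
classifiers. The package ships a synthetic-benchmark generator with the
same composition (4 populations, ~20 pedigrees each, 8 known related
pairs: 4 parent–offspring, 2 full-sibling, 2 half-sibling/avuncular), so
everything runs without any external download.

## The five checks

Run sequentially; samples flagged at one step are removed before the
next.

1. **Missing rate** — flag study samples with missing-call fraction
   > 0.1 over the merged variant set.
2. **Sex check** — on non-pseudo-autosomal X variants, compute the
   inbreeding coefficient F = (O(hom) − E(hom)) / (m − E(hom)). Females
   are diploid on X (F ≈ 0); males are hemizygous, called homozygous
   (F ≈ 1). Predict female if F ≤ 0.2, male if F ≥ 0.8, ambiguous
   otherwise; flag contradictions with the self-report.
3. **Inbreeding check** — same F on LD-pruned autosomes, referenced to
   study + matched-population benchmark samples. Flag |F − mean| > 5 SD.
   Contamination produces a large *negative* F (excess heterozygosity).
4. **IBD check** — method-of-moments estimates of the IBD-sharing
   probabilities (k0, k1, k2) for every sample pair from genome-wide
   identity-by-state counts, with kinship φ = k1/4 + k2/2. A
   linear-kernel SVM trained on the benchmark's known pairs labels each
   pair (DU/PO/FS/HF/UN); non-UN calls with φ ≥ 0.08 are related, and
   the member with the higher missing rate is removed.
5. **Population outlier check** — PCA on LD-pruned autosomes
   (genotypes centered by 2p̂ and scaled by √(2p̂(1−p̂))); a linear SVM
   trained on the benchmark's top-4 eigenvectors predicts each study
   sample's ancestry; flag disagreement with the self-report (a report
   of ASN matches either EAS or SAS).

Outputs: a problematic-sample list (TSV, one row per removal with step
and reason), one metric table per step, and a self-contained HTML report
with one plot per step.

## Worked example

Simulate a cohort with known planted defects, then QC it:

```bash
cohortqc simulate --seed 7 --out sim
cohortqc run --vcf sim/study.vcf --bed sim/capture.bed \
    --annotation sim/samples.tsv --benchmark sim/benchmark.cqst \
    --population EUR --out qc
```

which prints `8 problematic sample(s); report: qc/report.html`, and
`qc/problem_samples.tsv` contains:

```
sample_id  failed_step  reason                                                                    metric
S0009      sex          predicted male (F_x = 1) but self-reported female                         1
S0010      sex          predicted male (F_x = 1) but self-reported female                         1
S0006      inbreeding   inbreeding coefficient -1.444 beyond 5 SD of mean (-0.007892 +/- 0.1334)  -1.444042758
S0000      ibd          predicted PO with S0001 (kinship = 0.2634)                                0.2634176703
S0002      ibd          predicted FS with S0003 (kinship = 0.26)                                  0.2599632437
S0004      ibd          predicted DU with S0005 (kinship = 0.5)                                   0.5
S0007      population   predicted population AFR discordant with self-reported EUR
S0008      population   predicted population EAS discordant with self-reported EUR
```

Reading it: the two sex mismatches are hemizygous-male genotypes
(F_x = 1) annotated as female; the contaminated sample shows the
excess-heterozygosity signature (F = −1.44, far beyond 5 SD); the
cryptic parent–offspring and full-sibling pairs and the duplicate sit at
their expected kinship values (0.25, 0.25, 0.5) and lose one member
each; and the two planted ancestry outliers are caught by the PCA/SVM
step. This is exactly the defect set the seed-7 simulation planted —
see `sim/truth_samples.tsv`.

The same analysis is available per step (`cohortqc step ibd ...`), and a
real study runs from your own `study.vcf.gz` + capture BED + annotation
TSV against a benchmark store built with `cohortqc make-benchmark` from
any annotated multi-sample VCF with a pedigree table.

## Scope notes

The package detects second-degree and closer relatedness; first-cousin
and weaker relationships are out of scope, as are admixed-population
cohorts (the benchmark carries no admixed reference samples) and any
variant-level filtering beyond the bi-allelic-SNV/capture-region input
restriction. See `docs/methods.md` for the statistical details and
design decisions.
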