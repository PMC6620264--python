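# Methods

This note records the statistical procedures, the defaults and why they
were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions.

## Data model and merging

Genotypes are alt-allele counts {0, 1, 2} with a missing code, restricted
to bi-allelic SNVs. Only variants present in the benchmark panel are
used; study variants absent from the benchmark are discarded. A
benchmark variant absent from the study VCF is imputed homozygous
reference for every study sample **only when it lies inside the capture
regions** — inside capture, a modern caller that emits no record implies
hom-ref; outside capture the assay could not have observed the site, so
the genotype is set missing rather than fabricated. Variant identity is
the exact tuple (chrom, pos, ref, alt) after stripping any `chr` prefix;
sites where the two cohorts disagree on the allele pair (ref/alt swaps,
strand flips) are dropped rather than rescued, since both inputs are
expected on one reference build. Half-calls and non-diploid GT fields
become missing: every estimator below is defined on diploid codes.

The binary store packs genotypes at 2 bits/cell plus zlib, with sample
and variant metadata in a JSON header and an embedded format-version
string. A flat single-file layout was chosen over HDF5 so that identical
cohorts serialize to byte-identical files (HDF5 headers embed
timestamps), which makes simulation outputs and QC runs reproducible at
the byte level.

## Estimators

**Allele frequency.** p̂ = (Σ genotype codes) / (2 · n called), always
over an explicit reference subset: study samples plus benchmark samples
of the matched population (a study population of ASN matches both EAS
and SAS) for the sex and inbreeding checks; the full merged cohort for
IBD and PCA.

**Inbreeding coefficient.** F = (O_hom − E_hom) / (m − E_hom) with
E_hom = Σᵢ (1 − 2pᵢ(1−pᵢ)) over the sample's called, polymorphic sites.
No finite-sample frequency correction is applied (the m/(m−1)-style
correction used by some toolchains changes F by O(1/m) at merged-cohort
sizes); comparisons against such tools should allow a small offset.
The X-chromosome version first removes pseudo-autosomal intervals
(GRCh37 defaults X:60001–2,699,520 and X:154,931,044–155,260,560,
overridable in the config — the benchmark's coordinate system is
GRCh37-based, but study builds vary); fewer than 50 usable X variants
triggers a warning since the F estimate becomes unstable.

**Exact Hardy–Weinberg test.** Two-sided conditional exact test: given
the allele counts, the probability of every attainable heterozygote
count is accumulated via the adjacent-count ratio recurrence, and the
p-value is the total probability of tables no more likely than the one
observed. The test suite checks it against an exact-rational enumeration
for every table with up to 50 samples (max |Δ| ≈ 6e−16).

**LD pruning.** Greedy left-to-right positional scan per chromosome:
a variant is dropped when its squared pairwise-complete genotype
correlation with any already-kept variant within the window exceeds the
threshold. Defaults r² = 0.2, window 500 kb — the conventional values of
the GWAS-QC toolchain this procedure descends from. The scan is
deterministic given variant order; pruning is performed once per merged
cohort (the pruned set is a variant-level property recorded on the
variants) while per-step metrics are recomputed on the samples surviving
each step.

**Method-of-moments IBD.** For each pair, genome-wide counts of the
three identity-by-state classes are equated to their expectations under
Hardy–Weinberg as functions of allele frequencies, solved in cascade for
k̂0, k̂1, k̂2, then truncated to [0,1] and renormalized onto the simplex;
kinship φ = k1/4 + k2/2 and PI_HAT = k1/2 + k2 are derived. All pairs
are computed with dense matrix products (IBS class counts and
pair-specific expectation sums are each one n×m by m×n multiply), so the
full pairwise table for a few hundred samples takes seconds. The
truncation makes boundary estimates slightly biased (unrelated pairs
average k0 ≈ 0.97 rather than 1.0 at 5,000 variants, kinship ≈ +0.01);
this is intrinsic to bounded moment estimators and far below the 0.08
decision gate. Fewer than 100 usable variants raises an error.

**PCA.** Genotype columns are centered by 2p̂ and scaled by
√(2p̂(1−p̂)); missing entries are zeroed after centering; the sample
eigenvectors come from an SVD of the standardized matrix. Eigenvector
signs are fixed (largest-magnitude loading positive) so output is
invariant to sample order up to machine precision.

## Classifiers

Both classifiers are linear-kernel SVMs with C = 1, one-vs-one for
multi-class, with standardized inputs (zero mean, unit variance fitted
on the training rows). Standardization matters: eigenvector entries
scale like 1/√n and the unrelated class outnumbers each related class by
three orders of magnitude, so on raw features the C = 1 objective
prefers sacrificing a rare class to paying for a margin.

*IBD:* features are exactly (k0, k1) — k2 is linearly dependent.
Training pairs are all benchmark–benchmark pairs labelled by the known
pedigree (unlabelled pairs are UN), **plus each benchmark sample paired
with itself as a duplicate exemplar**: the panel contains no duplicate
pairs, yet the classifier must be able to call DU, and a self-pair is a
genuine duplicate whose (k0, k1) = (0, 0) is computed, not asserted. The
kinship ≥ 0.08 gate applies to every non-UN call. Within a related
study–study pair the higher-missing-rate member is flagged (ties break
to the lexicographically larger ID, for determinism); in study–benchmark
pairs the study member is always flagged, keeping the panel immutable.

*Population:* the eigen-decomposition uses all samples; training uses
only benchmark samples, excluding every member of a known related pair
so family structure cannot masquerade as population structure. Flagging
is strict discordance, with ASN matching either EAS or SAS.

The inbreeding outlier rule is two-sided (|F − mean| > 5 SD): negative
extremes indicate contamination, positive extremes consanguinity — both
are quality problems. The mean and SD include the study samples
themselves; a single grossly contaminated sample inflates the SD but
cannot mask itself (its own |F − mean| grows with |F| while 5·SD grows
only with |F|/√n).

## Synthetic data

The generator exists so that every pipeline claim can be tested against
known truth without external data.

* **Population structure** is the Balding–Nichols F-model: ancestral
  frequency p ~ U(0.05, 0.5) per variant, population frequency
  ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with F = FST = 0.1 by default —
  continental-scale differentiation. The Hudson FST of the generated
  frequencies is verified against the target in the tests.
* **Benchmark composition** mirrors the reference panel the pipeline is
  designed around: 22 + 22 + 21 + 22 samples across AFR/EAS/EUR/SAS with
  eight known related pairs (AFR: 2 PO + 1 FS; EAS: 1 FS + 1 HF; EUR:
  1 HF; SAS: 2 PO), all variants filtered to empirical MAF > 0.01 in at
  least one population.
* **Relatedness** is gene-dropping: a PO child receives one parental
  allele and one population allele; full siblings share two simulated
  parents; half-siblings share one; a duplicate is an exact copy.
* **Contamination** pools the ten allele copies of five donors and
  calls the genotype from the pool (hom only when the pool is
  monomorphic, het otherwise), as the reads of a DNA mixture would be
  called. A literal "draw two alleles from the pool" construction was
  considered and rejected: drawing with replacement yields E[F] = +0.1
  and drawing without replacement E[F] = 0, i.e., no excess
  heterozygosity — the opposite of what real contamination produces and
  undetectable by the inbreeding check. The pooled call reproduces the
  established strongly negative F signature.
* **X chromosome**: females diploid, males hemizygous emitted as
  homozygous diploid calls. Defaults: 100 study samples, 10,000
  autosomal + 500 X variants (a realistic LD-pruned exome-scale set),
  per-sample missing rates U(0, 0.05), one duplicate, one contaminant,
  two sex mismatches, two population outliers, one PO and one FS pair.

Not emulated: within-population LD (variants are independent given
frequencies — pruning correctness is tested on separately constructed
correlated columns), admixture, batch effects, genotyping error, and
X-pedigree consistency for simulated children (children's X genotypes
are drawn from population frequencies by sex; no check uses X
relatedness). Passing tests therefore demonstrate the decision rules and
estimators under clean population-genetic signal, not robustness to
platform artifacts.

## Numerical conventions

Thresholds follow the documented conventions exactly: missing rate
flagged on strict `>` 0.1; sex calls female at F ≤ 0.2 and male at
F ≥ 0.8 with the open interval ambiguous; inbreeding outliers strictly
beyond 5 SD; kinship gate inclusive at ≥ 0.08. Ambiguous sex with a
known self-report is flagged (only a concordant prediction counts as
clean; the sample needs manual review either way). The F statistic is
undefined (error) when no called site has 0 < p < 1. SD uses the n−1
denominator. All pipeline outputs are deterministic for fixed inputs,
config and seed; step tables are written at %.17g so reloading them
reproduces the plotted values bit-exactly.

## Problem sizes in the test suite

The acceptance-style tests run twenty seeded full-scale simulations
(100 study samples, 87 benchmark, ~10.5k variants; about 4 s each), and
the unit suites use 50-sample / 5,000-variant cohorts; estimator
recovery uses 100 gene-dropped pairs per relationship at 5,000 variants.
These sizes were chosen to keep the full suite under a few minutes while
leaving each statistic's sampling error an order of magnitude below the
decision thresholds it feeds.

## Known limitations

Admixed cohorts cannot be handled (no admixed benchmark population, and
the frequency model assumes discrete source populations). First-cousin
and weaker relatedness is intentionally out of scope — the benchmark
contains no training pairs for it. The hom-ref imputation assumes the
study VCF reports every polymorphic capture-region site; sparse
single-sample VCFs inflate apparent hom-ref calls at benchmark variants.
PLINK-corroboration thresholds (PI_HAT ≥ 0.125, F ∈ [0.2, 0.8]) are
reported in the pair tables for comparability but are not decision
rules here.
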