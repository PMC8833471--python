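# Methods

## Polygenic risk score

The score is a plain weighted allele count, `PGRS_s = Σ_j ln(OR_j)·d_sj`,
with no covariate adjustment, ancestry correction, LD clumping or weight
shrinkage: it assumes an additive log-odds model over a small, curated
panel of approximately independent lead/proxy SNPs. Two weight sources are
supported:

* **literature** — the panel table's published odds ratios, taken at face
  value for the declared risk allele;
* **in_sample** — per-locus allele-count odds ratios re-estimated between
  two user-named cohort strata (which strata define "case" and "control"
  is an explicit parameter, never guessed).

ORs are stored with respect to the declared risk allele and never
re-polarized; an OR < 1 is a protective risk-labelled allele and
contributes a negative weight. This keeps score differences interpretable
as log-odds differences and makes the allele-label flip an exact symmetry:
relabelling (risk, other, OR) → (other, risk, 1/OR) shifts every sample's
score by the constant −2·Σ ln OR and leaves all rank-based comparisons
unchanged.

**Missing genotypes** (default `impute_frequency`): a missing dosage is
replaced by 2× the cohort-wide risk-allele frequency at that locus, which
keeps scores comparable across samples with different missingness;
`omit_locus` (contribute 0) and `omit_sample` are available. The number of
imputed loci is recorded per sample.

**Allele harmonization.** Each panel locus is classified against the
genotype file's REF/ALT pair as matched, swapped (risk allele = REF),
strand-flipped (reverse-complement matches), ambiguous (palindromic A/T or
C/G — dropped by default because strand cannot be resolved without allele
frequency heuristics, and the panel is small enough that losing a locus is
cheaper than a silent polarity error; `allow_ambiguous` keeps them matched
by ID), or not found. Multiallelic records are treated as not found: the
panel is strictly biallelic. The report partitions the panel, so every
exclusion is visible.

**Association.** In-sample ORs use allele counts (two per diploid sample),
not genotype counts, matching the score's allele-count additivity.
Zero cells get the Haldane–Anscombe +0.5 on all four cells for the point
estimate only (flagged `corrected`); Fisher's exact p is always computed
on the raw table. A stratum with zero non-missing genotypes at a locus
yields an undefined OR with a warning, not an exception.

**Group comparison.** Kruskal–Wallis across all requested groups plus all
pairwise two-sided Mann–Whitney tests. The exact null distribution is
enumerated when both groups have ≤ 10 samples and no ties; otherwise the
normal approximation with tie correction is used, and the chosen method is
recorded per pair. Pairwise p values are unadjusted by default (a
Bonferroni flag exists) because the score comparison is a small, planned
family.

## Expression filter

Normalization: `RPKM = count·10⁹/(gene length · library size)` and
`TPM = rate·10⁶/Σ rate` with `rate = count/length`; TPM sums to one
million per sample by construction (checked to 10⁻³). Gene length, not
transcript length, is the denominator. The expression floor (mean
≥ 2 RPKM across all samples, boundary inclusive) defines the expressed
universe before testing.

A gene is called differentially expressed iff **all three** hold:

| criterion | default | notes |
|---|---|---|
| max group mean | > 2 | strict inequality, same normalized units as the floor |
| fold change | ≥ 1.5 | linear scale, larger mean over smaller; a zero smaller mean gives +∞ (passes) rather than a pseudocount-distorted ratio |
| FDR | q < 0.05 | Benjamini–Hochberg across the tested genes |

The per-gene p uses Welch's unequal-variance t on log2(x+1) by default,
with a rank-sum alternative behind a flag; the pass rule is
threshold-driven, so the test choice mainly affects borderline genes.
Lowering any threshold never removes a passing gene (monotonicity is
tested).

Baseline subtraction is exact set difference (exposure hits minus baseline
hits) with full size bookkeeping. PCA QC runs on log2(x+1) of
floor-passing genes (gene-centered); a sample is flagged when its distance
to its group centroid in the first k = 2 components exceeds
median + 3·MAD of within-group distances. Flags are reported only —
excluding a sample always requires an explicit decision, mirroring named
exclusions in study reports.

## Enrichment

Over-representation is the upper-tail hypergeometric probability of the
observed overlap, drawing the DE list from the expressed-gene universe.
The directional score `z = (n_up − n_down)/√(n_up + n_down)` over a set's
DE members is a deliberately transparent stand-in for proprietary
pathway-activation scores: it preserves the decision structure (p < 0.05
and |z| ≥ 2, with p-only judgment where z is undefined) without any causal
knowledge base, and its numeric values are not comparable to commercial
tools'. −log p is reported base 10. No multiple-testing correction is
applied across gene sets by default (raw p < 0.05 is the convention the
overlap tables use); BH across sets is available behind a flag. Overlap
tables are symmetric in the designated pair and idempotent on identical
inputs; cells for pathways absent from an experiment are marked NA.

## Synthetic data

The genotype generator draws dosages as Binomial(2, f) per group and locus
(Hardy–Weinberg), independently across loci — appropriate for a sparse
lead-SNP panel, and deliberately free of LD, population structure and
genotyping error. The default cohort is 19 EA/BE, 44 EA-only, 10 BE-only
and 730 controls at a fixed 30-SNP panel with distinct ORs between 0.65
and 1.60 and control frequencies between 0.10 and 0.60; the case group's
frequency at each locus is set so the true allelic OR versus all other
groups equals the published OR (the regime where literature weights are
exactly right), which implies an expected case-control score separation of
about 0.9 natural-log units. Default missing rate: 2%.

The count generator is gamma-Poisson: negative binomial with
Var = μ + φμ² (φ the dispersion; φ = 0 is Poisson). Per-gene baseline
means are log-normal around 100 (σ = 1) so the expression floor has a
realistic spread to act on; planted effects multiply one condition's mean
by a fold change. Default dispersion is 0.1 for patient-tissue designs;
the demonstration pipeline uses 0.01 for the cultured-fibroblast matrix,
reflecting the much lower biological variability of clonal cultures, with
a planted acid-response fold change of 4 (acid exposure is a drastic
perturbation) and constitutive patient-versus-control effects planted in
both exposed and unexposed conditions so the baseline subtraction has
genuine work to do.

What passing tests on these data do **not** show: robustness to LD between
panel SNPs, ancestry confounding, batch effects, length biases or outlier
samples in real RNA-seq, or agreement with knowledge-base-driven pathway
tools. The generators validate the arithmetic and the decision rules, not
the biology.

## Problem sizes and numerics

The test suite and the acceptance pipeline run at desk scale by design:
the genetics properties use the study's group sizes (803 samples, 30 loci,
200 replicates where power is asserted), expression properties use
2,000–10,000 genes with 10 samples per condition, and the demonstration
pipeline uses 4,000 genes, 25 pathways of 40 genes, an 11-vs-10 biopsy
contrast and 3-per-condition fibroblast contrasts. All generators are pure
functions of (config, seed); every CLI run logs its seed, and identical
seeds reproduce outputs byte for byte. Hypergeometric p values are clamped
to (0, 1]; Mann–Whitney exact enumeration is capped at group sizes of 10;
Welch tests on zero-variance genes report p = 1 rather than NaN.

## Known limitations

* The DE filter is not a dispersion-modelling DE framework; with few
  replicates it is conservative, and its test choice is a pragmatic
  default rather than a claim of optimality.
* The enrichment z is directionless about effect magnitude and ignores
  gene–gene dependence; it exists to make the significance convention and
  overlap bookkeeping reproducible, not to rank pathways biologically.
* In-sample OR weighting reuses the cohort twice (weight estimation and
  scoring), which inflates apparent separation; the package exposes it
  because it is part of the workflow being reproduced, and the
  case/control strata used for weighting are always explicit in the
  output.
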