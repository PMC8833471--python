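# barrisk

Adults born with esophageal atresia (EA) develop Barrett's esophagus (BE)
far more often, and far younger, than the general population, raising the
question of whether known BE/esophageal-cancer risk variants and
reflux-primed inflammatory programs contribute to that susceptibility.
`barrisk` packages the computational core of such a case-control study for
reuse: genotype harmonization and additive polygenic risk scoring over a
literature-curated SNP panel, per-SNP allele association between patient
subgroups, a threshold-based differential-expression filter with
exposure-versus-baseline gene-set subtraction, and cross-experiment
pathway-overlap reporting — together with a synthetic-data generator so
every stage is testable without access to individual-level patient data.

## The methods

**Polygenic risk score.** For sample *s* over a panel of risk loci *j*,

```
PGRS_s = Σ_j ln(OR_j) · d_sj
```

where `d_sj ∈ {0,1,2}` counts risk alleles (after harmonizing each locus
against the genotype file's REF/ALT orientation, with palindromic A/T and
C/G pairs dropped by default) and `OR_j` is the per-locus odds ratio.
Weights come either from the literature or are re-estimated *in sample*
from allele-count 2×2 tables: `OR = ad/bc` with the Haldane–Anscombe +0.5
correction when a cell is empty, and Fisher's exact p on the raw counts.
An OR below 1 is a protective risk-labelled allele and enters as a
negative weight. Score distributions are compared with a Kruskal–Wallis
omnibus test plus pairwise two-sided Mann–Whitney tests (exact for small
tie-free groups).

**Expression filter.** Counts are normalized to RPKM and TPM; genes with
mean ≥ 2 RPKM are "expressed". A gene is differentially expressed between
two conditions iff all three hold: max group mean > 2, fold change ≥ 1.5
(linear, direction-symmetric), and Benjamini–Hochberg q < 0.05 (Welch's t
on log2(x+1) by default). Genes also responding in a baseline contrast can
be subtracted from an exposure contrast's hit list.

**Enrichment and overlap.** Gene sets (GMT) are scored by the upper-tail
hypergeometric probability, with a directional score
`z = (n_up − n_down)/√(n_up + n_down)`; a set is significant when p < 0.05
and |z| ≥ 2 (p-only mode where z is undefined). Enrichment tables from two
experiments are joined into a wide pathway × experiment overlap table with
the designated pair's intersection.

## Worked example

```python
from barrisk import PolygenicScoreModel, default_genotype_config, simulate_genotypes

cohort, truth = simulate_genotypes(default_genotype_config(seed=1))
res = PolygenicScoreModel(cohort, or_source="in_sample",
                          case_group="EA/BE", control_group="control").fit(
    compare=["EA/BE", "EA-only", "BE-only", "control"])
print(res.summary())
```

```
Polygenic risk score results
  OR source:      in_sample
  loci used:      30
  samples scored: 803

  median score by group:
    BE-only         2.444  (range -0.36 to 5.95)
    EA-only         2.440  (range -0.85 to 6.03)
    EA/BE           5.425  (range 2.17 to 9.31)
    control         2.616  (range -3.37 to 7.39)

  Kruskal-Wallis H = 29.047, p = 2.189e-06
  pairwise Mann-Whitney (two-sided):
    EA/BE vs EA-only: U = 726.0, p = 4.122e-06 [normal-approximation-with-tie-correction]
    EA/BE vs BE-only: U = 160.0, p = 0.003082 [normal-approximation-with-tie-correction]
    EA/BE vs control: U = 11934.0, p = 7.935e-08 [normal-approximation-with-tie-correction]
    EA-only vs BE-only: U = 218.0, p = 0.9734 [normal-approximation-with-tie-correction]
    EA-only vs control: U = 15590.0, p = 0.7444 [normal-approximation-with-tie-correction]
    BE-only vs control: U = 3526.0, p = 0.8541 [normal-approximation-with-tie-correction]
```

The simulated cohort (19 EA/BE, 44 EA-only, 10 BE-only, 730 controls at a
30-SNP panel) plants elevated risk-allele frequencies only in the EA/BE
group; the fitted scores recover that separation — the case group's median
score is ~2.8 natural-log-odds units above every other group, the omnibus
test is strongly significant, and every pairwise test involving the case
group is significant while the unaffected pairs are not.

The same objects run from the shell:

```sh
barrisk simulate --seed 1 --out sim/            # cohort + counts + GMT fixtures
barrisk pgrs --risk-table sim/risk_table.tsv --genotypes sim/dosages.tsv \
       --group-map sim/group_map.tsv --case-group EA/BE --control-group control \
       --compare "EA/BE,EA-only,BE-only,control" --out pgrs/
barrisk demo --seed 1 --out demo/               # full pipeline in one shot
```

Subcommands: `pgrs`, `assoc`, `de`, `subtract`, `enrich`, `overlap`,
`simulate`, `demo`; each writes its tables plus a `run_log.json` with the
arguments, thresholds and seed needed to reproduce the run.

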