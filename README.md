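# mb17q

Analysis toolkit for medulloblastoma cohorts with isodicentric chromosome
17 — `i17q`, formally idic(17)(p11.2) — the most common cytogenetic
abnormality in this tumor. The package is aimed at researchers who work
with amplification-based targeted sequencing of FFPE tumor material and
with expression microarray cohorts annotated by molecular subgroup
(WNT, SHH, group 3, group 4) and i17q status.

It provides four analysis stages plus a synthetic-cohort generator:

1. **Stringent variant filtering** for amplicon/FFPE data. FFPE fixation
   causes cytosine deamination, and PCR "jackpotting" can push an
   early-cycle artifact to a high allele fraction in a single
   amplification replicate. The retention rule is therefore:
   caller thresholds (quality ≥ 30, mapping quality ≥ 30, alternate
   allele fraction ≥ 0.20 on the pooled, multi-replicate data), removal
   of synonymous/intronic calls and of polymorphisms documented at > 1%
   population allele frequency, and finally *replicate concordance*: a
   pooled call survives only if an individual amplification replicate
   shows the same variant at allele fraction **strictly** > 5%.
2. **Chromosome-17 dosage analysis.** In i17q tumors, 17p telomeric to
   the 17p11.2 breakpoint is hemizygous (expected fold-expression
   ≈ 0.5 relative to i17q-negative tumors) and the rest of chromosome
   17 is duplicated (≈ 1.5). For a focal gene *g* in the hemizygous
   compartment the excess-dysregulation test asks whether its fold
   `f_g = 2^(mean log2 x_pos − mean log2 x_neg)` falls below the
   compartment's background distribution: a z-score against the
   background mean/SD, and a Welch t-test of the focal gene's
   per-sample normalized folds against the background per-feature
   folds, Bonferroni-corrected by the compartment size.
3. **Subgroup expression comparison**: probe-count normalization,
   per-gene one-way ANOVA across the four molecular subgroups, and
   Welch two-group tests for any binary grouping (i17q status, sex, or
   an i17q contrast restricted to group 4).
4. **Survival stratification**: Kaplan–Meier product-limit curves,
   two-group log-rank tests, and the combined molecular-risk rule
   (high = chromatin-remodeling gene mutation **or** i17q) over the
   OS/DFS × standard-risk/all-patients grid.

The synthetic module generates variant-call replicates (replicate-
consistent true variants vs replicate-independent C→T/G→A-biased
artifacts), expression cohorts with the dosage structure above, and
exponential-hazard survival cohorts, all deterministic given a seed.
A packaged fixture carries the 13-row mutation table of a 57-tumor
sequencing cohort (MLL3, KDM6A, GPS2 mutations).

## Worked example

```python
from mb17q import (SimConfig, gen_expression_cohort, focal_excess_test,
                   load_table1_fixture, summarize_mutation_table)

# 1. summarize the packaged 57-tumor mutation table
s = summarize_mutation_table(load_table1_fixture(), cohort_size=57)
print(f"{s['n_mutations']} mutations in {s['n_patients']} patients "
      f"({s['patient_fraction_pct']}% of cohort); "
      f"MLL3 {s['gene_fraction_pct']['MLL3']}%, "
      f"missense {s['function_class_fraction_pct']['nonsynonymous']}%")

# 2. simulate an i17q expression cohort with 1 log2 unit of excess TP53
#    suppression on top of the hemizygous dosage effect, and test it
cfg = SimConfig(seed=1, n_samples=60, i17q_fraction=0.5,
                noise_sd=0.25, focal_excess_log2=1.0,
                n_features=625, n_chr17_features=625)
cohort = gen_expression_cohort(cfg, hemizygous_feature_fraction=0.8)
res = focal_excess_test(cohort, focal_gene="TP53", breakpoint=20_000_000)
print(f"TP53 fold = {res.focal_fold:.3f} vs background "
      f"{res.background_mean:.3f} +/- {res.background_sd:.3f} "
      f"(z = {res.focal_z:.1f}); corrected p = {res.p_corrected:.3g} "
      f"over {res.n_tests} hemizygous features; flagged = {res.flagged}")
```

prints

```
13 mutations in 10 patients (18% of cohort); MLL3 85%, missense 69%
TP53 fold = 0.263 vs background 0.500 +/- 0.021 (z = -11.2); corrected p = 5.55e-21 over 500 hemizygous features; flagged = True
```

The first line is the mutation-table summary: 13 reportable mutations
across 10 of 57 patients, dominated by *MLL3* missense changes. The
second line shows the dosage test recovering the planted signal: the
hemizygous background sits at fold 0.5 (pure dosage), while TP53 —
simulated with an extra two-fold suppression — sits ~11 SD below it and
is flagged after Bonferroni correction over the 500-feature
compartment.

A command-line interface mirrors the stages (`mb17q simulate`,
`filter-variants`, `summarize`, `dosage-test`, `compare`, `survival`,
`run-all`); `mb17q run-all --seed 0 --out demo_out` runs the whole
chain on self-generated synthetic data and writes all reports.

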