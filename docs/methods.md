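# Methods

This note records the models implemented in `mb17q`, the parameter
choices behind them, what the synthetic generators do and do not
emulate, and the numerical conventions used.

## Variant retention model

Input is the output of a variant caller run on pooled (compiled)
amplification replicates of each FFPE tumor sample, plus the caller
output of each individual replicate. A pooled call is retained iff

1. `qual >= 30`, `mapq >= 30`, `af >= 0.20` — the caller minima are
   read as **inclusive** bounds;
2. its functional class is not synonymous or intronic (splice-site
   calls are retained), and its maximum documented population allele
   frequency across dbSNP / 1000 genomes / 6500 exomes is not
   **strictly above** 1% (a variant at exactly 1% is kept; a variant
   absent from all three databases is treated as novel and kept).
   Where the databases disagree we take the maximum — the most
   conservative resolution, since it removes a variant that any one
   database considers common;
3. at least one individual (non-pooled) replicate of the same sample
   shows the identical `(chrom, pos, ref, alt)` at allele fraction
   **strictly greater** than 0.05. The pooled run itself never counts
   as the confirming replicate; using the pooled evidence to confirm a
   pooled call would make the concordance check circular and would not
   remove single-replicate jackpotting events.

Variant identity is `(chrom, pos, ref, alt)` with 1-based, left-aligned
coordinates throughout. Damage-predictor tallies (SIFT, PolyPhen, LRT,
MutationTaster) are input annotations carried through; the package never
computes them. Filter performance against a labeled truth set is
sensitivity = retained true / all true and specificity = rejected
artifacts / all artifacts; either rate is reported as undefined (with a
flag) when its denominator is empty rather than silently coerced to 0
or 1.

Summary percentages for report output are integer-rounded half away
from zero, the convention of printed clinical tables (10/57 → 18%).

## Dosage model and the focal-gene test

For gene expression on the log2 scale, i17q changes copy number from 2
to 1 (17p telomeric to the breakpoint) or 3 (the rest of chromosome
17). Under a pure dosage model every feature in a compartment shifts by
the same fold; the defaults are 0.5 and 1.5, the naive copy-ratio
expectations. Fold-expression per feature is the ratio of class
geometric means, `2^(mean log2 over i17q-positive − mean log2 over
i17q-negative)` — geometric rather than arithmetic because microarray
log-scale noise is approximately symmetric on the log scale and the
ratio of arithmetic means is not invariant to which scale the mean is
taken on.

The breakpoint partition puts chromosome-17 features with
`pos < breakpoint` in the hemizygous compartment and `pos >= breakpoint`
in the duplicated one. The default breakpoint is 20,000,000 (1-based),
a round coordinate inside 17p11.2 where the mediating low-copy repeats
(REPA/REPB) lie; the band, not a base-pair coordinate, is what defines
the rearrangement, so the coordinate is configurable everywhere it
appears.

The focal-gene excess test asks whether a hemizygous gene (TP53 by
default) is suppressed beyond dosage. Two quantities are reported:

- **focal z**: the focal fold standardized against the mean and SD of
  the background (all other hemizygous-compartment per-feature folds),
  with an indicator for z < −2;
- **a Welch two-sample t-test**. The default `per_sample` mode
  contrasts the focal gene's per-i17q-sample normalized folds (each
  positive sample's log2 value minus the gene's negative-class mean,
  exponentiated) against the background per-feature folds. A
  `per_feature` mode contrasts the focal per-sample folds against the
  pooled background per-sample folds instead. The comparison units are
  genuinely ambiguous for this design — the per-sample mode weights the
  focal gene's biological and technical variance across tumors, the
  per-feature mode weights the background's across genes — so both are
  exposed and the mode is recorded on the result. Neither mode is
  claimed to reproduce any particular published p-value; that would
  require the original 103-tumor microarray data.

Bonferroni correction multiplies the raw p by the number of
hemizygous-compartment features (the family actually searched for
excess suppression), not by all chromosome-17 features; the factor is
configurable and reported. The corrected p is capped at 1.

Degenerate inputs: a noiseless background has SD ≈ 1e-16 from float
round-off; spreads below `1e-9 × max(1, |mean|)` are treated as exactly
degenerate, giving z = 0 (focal at background) or ±∞, and t = 0 / p = 1
when all compared values are identical.

The p53 pathway panel profile applies the same fold + Welch test per
panel gene with Bonferroni factor = panel size and star levels at
corrected p < 0.05 / < 0.01. Panel membership (core regulators,
chIP-seq targets, signal transducers) is an input list, not computed.

## Subgroup comparisons

Probe-count normalization divides each feature's value by its number of
array probes, making expression levels comparable across genes; the
operation is a pass-through scaling when values are already aggregated
and is idempotent (the output metadata records one probe). The subgroup
comparison is a one-way fixed-effects ANOVA over WNT/SHH/group 3/
group 4; subgroups with fewer than two samples are excluded with a
warning recorded on the result. Two-group tests default to Welch
(unequal variance) with a pooled-variance option; per-gene p-values are
reported unadjusted, matching single-gene reporting practice, and
multi-gene screens can correct externally.

## Survival

The Kaplan–Meier estimator and the two-group log-rank test are
implemented directly (they are part of the analysis contract, and the
test suite cross-checks both against lifelines to 1e-12 on random tied
cohorts). Conventions: at tied times events precede censorings, so a
subject censored at an event time remains in that event's risk set; the
log-rank uses the hypergeometric variance at each distinct event time,
no continuity correction, and a chi-square reference with 1 df —
the defaults of the standard survival packages. Log-rank analyses of
"all patients" are unstratified by clinical risk group.

The combined molecular-risk rule is the disjunction: high iff
mutation-positive (MLL3/KDM6A/GPS2/ZMYM3) or i17q-positive. The grid
runner evaluates OS and DFS, within standard-risk patients and across
all patients, for the mutation, i17q and combined stratifiers.

## Synthetic cohorts

The generators produce data with the statistical structure the analyses
assume, at sizes chosen to mirror the study design they emulate:

- **Variant cohorts** (default 57 samples × 2 replicates): true somatic
  variants arrive at 0.23 per sample (≈ 13 per 57-sample cohort),
  appear in every replicate with allele fraction uniform on
  [0.2, 0.6], carry protein-altering annotations and no population
  frequency — the profile of genuine somatic panel mutations. That
  construction makes 100% filter sensitivity a designed property of the
  true-variant regime, which is exactly what the concordance filter is
  supposed to preserve. Artifacts arrive independently per replicate at
  rate 5, with substitutions 80% deamination-type (C→T/G→A) where the
  reference base allows, allele fractions from a right-skewed scaled
  Beta(1, 4) on (0, 0.3] — so most artifacts fail the pooled 0.20
  threshold but some would pass absent the concordance rule — and mixed
  annotations including filterable classes and occasional documented
  population frequencies. Annotation is assigned once per distinct
  variant, so recurrent artifacts are consistently annotated. The
  pooled call set is the per-sample union with AF recomputed as the
  read-weighted mean over all replicates (zero-AF coverage for
  replicates that did not call the variant), which is why a
  single-replicate artifact's pooled AF is roughly halved. The panel
  spans 48,000 positions (≈ 192 amplicons × 250 bp), giving a per-site
  two-replicate artifact co-occurrence probability of ~1e-8.
- **Expression cohorts**: log2 values = feature baseline N(8, 1.5²) +
  dosage term + focal excess + N(0, noise_sd²) noise, noise_sd default
  0.25 — a typical between-array residual SD for exon arrays. A
  deterministic fraction (default 0.55) of chromosome-17 features sits
  below the breakpoint, reflecting the higher feature density of 17p on
  exon arrays. TP53 (17p, position 7,668,402) and PPM1D/WIP1 (17q,
  58,700,000) are placed at their genomic coordinates. i17q-positive
  samples are assigned to group 4 with probability 0.85 (else group 3);
  negative samples follow the subgroup mix of published 103-tumor
  cohorts after removing the i17q share. Sex is male with probability
  0.84 in i17q-positive samples and 0.60 otherwise.
- **Survival cohorts**: exponential event times with per-stratum
  hazards. Defaults 0.0025/month (standard risk) and 0.0153/month
  (high risk) correspond to ~86% and ~40% five-year overall survival;
  administrative censoring at 120 months. DFS adds an independent
  relapse clock so the DFS hazard is 1.6× the death hazard and
  DFS time ≤ OS time by construction.

What the generators do **not** emulate: read-level sequencing error,
amplicon coverage heterogeneity, probe-level microarray physics,
correlated expression between neighboring genes, subgroup-specific
expression programs beyond the i17q dosage structure, and informative
censoring. Passing tests therefore demonstrate that the analysis chain
recovers the structure it targets under its stated assumptions — not
that it is robust to every artifact of real FFPE or microarray data.

All generators are deterministic given the config seed (independent
seed streams per generator), and simulator defaults are illustrative
for the artifact regime: the true artifact burden of FFPE amplicon
panels varies widely and is not calibrated here.

## Calibration and power checks

The focal-gene test is calibrated by simulation: under pure dosage
(focal excess 0; 500 hemizygous features, 30+30 samples, noise 0.25)
the Bonferroni-corrected test flags the focal gene in well under 5% of
seeds; with 1.0 log2 of excess suppression it flags in ~100% of seeds
and the focal fold sits > 2 SD below the hemizygous background. The
log-rank engine shows a uniform null p-value distribution and high
power at hazard ratio 5 with n = 60. These simulation sizes (500 null /
200 power seeds for dosage, 100 seeds for survival) give binomial
standard errors of ≤ 1–2 percentage points on the reported rates.

Published per-patient survival p-values for this kind of cohort cannot
be recomputed without the underlying clinical table, and single-gene
expression p-values require the original microarray cohort; the package
validates the corresponding machinery by the oracle cross-checks and
calibration simulations above instead.

## Known limitations

- The concordance filter requires replicate data for every pooled
  sample and errors otherwise; partially replicated cohorts must be
  subset first.
- Fold-expression assumes the matrix is on a log2 scale; data on other
  scales must be transformed upstream.
- The focal test's background treats per-feature folds as exchangeable;
  strong local correlation (e.g. co-regulated clusters on 17p) would
  shrink the effective background size and make the SD optimistic.
- Survival machinery is limited to what the analyses need: no Cox
  regression, stratified log-rank, or competing risks.
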