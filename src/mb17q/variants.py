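"""Stringent variant retention for amplification-based FFPE sequencing.

The pipeline has three stages applied to caller output on pooled
(compiled-replicate) data:

1. caller thresholds — quality >= 30, mapping quality >= 30, alternate
   allele fraction >= 0.20 (all inclusive: stated as minima);
2. annotation filters — drop synonymous and intronic (non-splice-site)
   changes and documented polymorphisms with population allele frequency
   strictly above 1% in any of dbSNP / 1000 genomes / 6500 exomes (the
   maximum across databases is carried as ``pop_af``; variants absent
   from all databases are treated as novel and retained);
3. replicate concordance — a pooled call is kept only if at least one
   individual amplification replicate of the same sample shows the same
   variant at allele fraction strictly greater than 5%, which removes
   single-replicate "jackpotting" artifacts.

Variant identity is (chrom, pos, ref, alt), 1-based left-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VALID_FUNCTION_CLASSES",
    "apply_call_thresholds",
    "apply_annotation_filters",
    "apply_concordance_filter",
    "run_filter_pipeline",
    "summarize_mutation_table",
    "evaluate_filter_performance",
    "records_from_calls",
    "FilterReport",
]

VALID_FUNCTION_CLASSES = frozenset(
    {
        "nonsynonymous",
        "stopgain",
        "frameshift",
        "splice_site",
        "synonymous",
        "intronic",
        "other",
    }
)

VARIANT_KEY = ["sample_id", "chrom", "pos", "ref", "alt"]


@dataclass
class FilterReport:
    """Stage-wise retention counts and, when truth is known, accuracy."""

    stage_counts: dict[str, int] = field(default_factory=dict)
    sensitivity: float | None = None
    specificity: float | None = None
    sensitivity_defined: bool = True
    specificity_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "stage_counts": dict(self.stage_counts),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "sensitivity_defined": self.sensitivity_defined,
            "specificity_defined": self.specificity_defined,
        }


def apply_call_thresholds(
    calls: pd.DataFrame,
    min_qual: float = 30.0,
    min_mapq: float = 30.0,
    min_af: float = 0.20,
) -> pd.DataFrame:
    """Retain calls with qual, mapq and allele fraction at or above the minima."""
    if min_qual < 0 or min_mapq < 0 or min_af < 0:
        raise ValueError("thresholds must be non-negative")
    if calls.empty:
        return calls.copy()
    keep = (
        (calls["qual"] >= min_qual)
        & (calls["mapq"] >= min_mapq)
        & (calls["af"] >= min_af)
    )
    return calls.loc[keep].copy()


def apply_annotation_filters(
    calls: pd.DataFrame, max_pop_af: float = 0.01
) -> pd.DataFrame:
    """Drop synonymous/intronic changes and documented common polymorphisms.

    The population-frequency rule is strictly exclusive: a variant at
    exactly ``max_pop_af`` is retained. Missing ``pop_af`` means the
    variant is undocumented and is retained.
    """
    if calls.empty:
        return calls.copy()
    bad = set(calls["function_class"].dropna().unique()) - VALID_FUNCTION_CLASSES
    if bad:
        raise ValueError(
            f"unknown function_class values: {sorted(bad)}; "
            f"expected one of {sorted(VALID_FUNCTION_CLASSES)}"
        )
    keep = ~calls["function_class"].isin(("synonymous", "intronic"))
    pop = pd.to_numeric(calls["pop_af"], errors="coerce")
    keep &= ~(pop > max_pop_af)  # NaN compares False, i.e. retained
    return calls.loc[keep].copy()


def apply_concordance_filter(
    pooled_calls: pd.DataFrame,
    replicate_calls: pd.DataFrame,
    min_replicate_af: float = 0.05,
) -> pd.DataFrame:
    """Keep pooled calls confirmed in an individual replicate at AF > 5%.

    Confirmation requires the identical (chrom, pos, ref, alt) in at
    least one non-pooled replicate of the same sample at allele fraction
    strictly greater than ``min_replicate_af``.
    """
    if pooled_calls.empty:
        return pooled_calls.copy()
    reps = replicate_calls[replicate_calls["replicate_id"] != "pooled"]
    missing = set(pooled_calls["sample_id"]) - set(reps["sample_id"])
    if missing:
        raise ValueError(
            f"samples present in pooled calls but lacking replicate data: "
            f"{sorted(missing)}"
        )
    confirmed = (
        reps.loc[reps["af"] > min_replicate_af, VARIANT_KEY]
        .drop_duplicates()
        .assign(_confirmed=True)
    )
    merged = pooled_calls.merge(confirmed, on=VARIANT_KEY, how="left")
    keep = merged["_confirmed"].eq(True).to_numpy()
    return pooled_calls.loc[keep].copy()


def run_filter_pipeline(
    pooled_calls: pd.DataFrame,
    replicate_calls: pd.DataFrame,
    min_qual: float = 30.0,
    min_mapq: float = 30.0,
    min_af: float = 0.20,
    max_pop_af: float = 0.01,
    min_replicate_af: float = 0.05,
) -> tuple[pd.DataFrame, FilterReport]:
    """Run all three stages in order and record stage-wise counts."""
    report = FilterReport()
    report.stage_counts["input"] = len(pooled_calls)
    s1 = apply_call_thresholds(pooled_calls, min_qual, min_mapq, min_af)
    report.stage_counts["call_thresholds"] = len(s1)
    s2 = apply_annotation_filters(s1, max_pop_af)
    report.stage_counts["annotation_filters"] = len(s2)
    s3 = apply_concordance_filter(s2, replicate_calls, min_replicate_af)
    report.stage_counts["replicate_concordance"] = len(s3)
    return s3, report


def records_from_calls(retained: pd.DataFrame) -> pd.DataFrame:
    """Shape retained pooled calls into the reportable mutation table.

    One record per (sample, chrom, start, obs); synonymous / intronic
    calls must already have been filtered out.
    """
    if retained.empty:
        return pd.DataFrame(
            columns=["sample_id", "gene", "function_class", "chrom", "start", "ref", "obs"]
        )
    leftover = retained["function_class"].isin(("synonymous", "intronic"))
    if leftover.any():
        raise ValueError("records contain synonymous/intronic calls; filter first")
    rec = retained.rename(columns={"pos": "start", "alt": "obs"})
    cols = ["sample_id", "gene", "function_class", "chrom", "start", "ref", "obs"]
    if "damaging_tally" in rec.columns:
        cols.append("damaging_tally")
    rec = rec[cols].drop_duplicates(subset=["sample_id", "chrom", "start", "obs"])
    return rec.reset_index(drop=True)


def summarize_mutation_table(records: pd.DataFrame, cohort_size: int) -> dict:
    """Summarize a mutation table: counts, patient fraction, per-gene and
    per-function-class fractions.

    Percentages are integer-rounded for report output (half away from
    zero, the convention of printed clinical tables).
    """
    n_mutations = len(records)
    n_patients = records["sample_id"].nunique() if n_mutations else 0
    if cohort_size < n_patients:
        raise ValueError(
            f"cohort size {cohort_size} smaller than number of mutated "
            f"patients {n_patients}"
        )

    def pct(num: float, den: float) -> int:
        if den == 0:
            return 0
        return int(np.floor(100.0 * num / den + 0.5))

    by_gene = (
        records.groupby("gene").size().sort_values(ascending=False)
        if n_mutations
        else pd.Series(dtype=int)
    )
    by_class = (
        records.groupby("function_class").size().sort_values(ascending=False)
        if n_mutations
        else pd.Series(dtype=int)
    )
    return {
        "n_mutations": int(n_mutations),
        "n_patients": int(n_patients),
        "cohort_size": int(cohort_size),
        "patient_fraction_pct": pct(n_patients, cohort_size),
        "gene_counts": {g: int(c) for g, c in by_gene.items()},
        "gene_fraction_pct": {g: pct(c, n_mutations) for g, c in by_gene.items()},
        "function_class_counts": {f: int(c) for f, c in by_class.items()},
        "function_class_fraction_pct": {
            f: pct(c, n_mutations) for f, c in by_class.items()
        },
    }


def evaluate_filter_performance(
    retained: pd.DataFrame,
    truth: pd.DataFrame,
    stage_counts: dict[str, int] | None = None,
) -> FilterReport:
    """Score retained calls against a truth table.

    sensitivity = retained true variants / all true variants;
    specificity = rejected artifacts / all artifacts. A degenerate
    denominator (no true variants, or no artifacts) leaves the
    corresponding rate undefined, flagged on the report.
    """
    truth_keyed = truth.set_index(VARIANT_KEY)["label"]
    if truth_keyed.index.duplicated().any():
        raise ValueError("truth table has duplicate variant keys")
    if retained.empty:
        retained_keys = pd.Index([], tupleize_cols=False)
        labels = pd.Series(dtype=object)
    else:
        retained_keys = pd.MultiIndex.from_frame(
            retained[VARIANT_KEY].drop_duplicates()
        )
        unknown = retained_keys.difference(truth_keyed.index)
        if len(unknown):
            raise ValueError(
                f"{len(unknown)} retained variants absent from the truth table, "
                f"e.g. {list(unknown[:3])}"
            )
        labels = truth_keyed.loc[retained_keys]

    n_true = int((truth_keyed == "true").sum())
    n_artifact = int((truth_keyed == "artifact").sum())
    kept_true = int((labels == "true").sum()) if len(labels) else 0
    kept_artifact = int((labels == "artifact").sum()) if len(labels) else 0

    report = FilterReport(stage_counts=dict(stage_counts or {}))
    if n_true == 0:
        report.sensitivity, report.sensitivity_defined = None, False
    else:
        report.sensitivity = kept_true / n_true
    if n_artifact == 0:
        report.specificity, report.specificity_defined = None, False
    else:
        report.specificity = (n_artifact - kept_artifact) / n_artifact
    return report
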