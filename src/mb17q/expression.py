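"""Subgroup and two-group expression comparisons.

Gene-level values are probe-count normalized so expression is
comparable across genes with different numbers of array probes. The
one-way ANOVA compares a gene across the four consensus medulloblastoma
molecular subgroups (WNT, SHH, group 3, group 4); the two-group test is
a Welch t-test on log2 values for any binary sample grouping (i17q
status, sex, or an i17q contrast restricted to group 4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import SUBGROUPS, ExpressionCohort

__all__ = [
    "probe_normalize",
    "subgroup_anova",
    "two_group_test",
    "pooled_proportion",
    "GroupComparisonResult",
]


def pooled_proportion(numerators, denominators) -> float:
    """Pool count ratios from several cohorts into one overall proportion.

    ``sum(numerators) / sum(denominators)`` — e.g. pooling the male
    fractions of i17q-positive cases reported by independent studies.
    """
    num = np.asarray(list(numerators), dtype=float)
    den = np.asarray(list(denominators), dtype=float)
    if num.shape != den.shape or len(num) == 0:
        raise ValueError("numerators and denominators must be equal-length, non-empty")
    if (num < 0).any() or (den <= 0).any() or (num > den).any():
        raise ValueError("counts must satisfy 0 <= numerator <= denominator")
    return float(num.sum() / den.sum())


@dataclass
class GroupComparisonResult:
    gene: str
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    F_statistic: float | None = None
    p_anova: float | None = None
    t_statistic: float | None = None
    p_ttest: float | None = None
    direction: str | None = None  # sign of (first group - second group)
    excluded_groups: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def probe_normalize(cohort: ExpressionCohort) -> ExpressionCohort:
    """Divide each feature's values by its probe count.

    With probe-level values summed per feature this yields the per-probe
    mean; with already-aggregated values it is a pass-through scaling.
    Features with a zero or missing probe count are rejected.
    """
    n_probes = pd.to_numeric(cohort.feature_meta["n_probes"], errors="coerce")
    bad = cohort.feature_meta.index[~(n_probes >= 1)]
    if len(bad):
        raise ValueError(f"features with zero/missing probe count: {list(bad[:5])}")
    mat = cohort.matrix.div(n_probes, axis=0)
    meta = cohort.feature_meta.copy()
    meta["n_probes"] = 1  # normalization is idempotent
    return ExpressionCohort(mat, meta, cohort.sample_meta)


def _gene_values(cohort: ExpressionCohort, gene: str) -> pd.Series:
    return cohort.matrix.loc[cohort.feature_for_gene(gene)]


def subgroup_anova(cohort: ExpressionCohort, gene: str) -> GroupComparisonResult:
    """One-way fixed-effects ANOVA of a gene across molecular subgroups.

    Subgroups with fewer than two samples are excluded (with a warning,
    recorded on the result); at least two eligible subgroups are
    required.
    """
    values = _gene_values(cohort, gene)
    labels = cohort.sample_meta["subgroup"]
    groups, excluded = {}, []
    for g in SUBGROUPS:
        v = values[labels[labels == g].index].to_numpy()
        if len(v) >= 2:
            groups[g] = v
        elif len(v) > 0 or g in set(labels):
            excluded.append(g)
    if len(groups) < 2:
        raise ValueError(
            f"need >=2 subgroups with >=2 samples, got {len(groups)} for {gene!r}"
        )
    if excluded:
        warnings.warn(
            f"subgroups excluded from ANOVA for {gene!r} (<2 samples): {excluded}",
            stacklevel=2,
        )
    arrays = list(groups.values())
    if np.ptp(np.concatenate(arrays)) == 0:
        # all observations identical: no variance anywhere, F = 0 by convention
        F, p = 0.0, 1.0
    else:
        F, p = stats.f_oneway(*arrays)
    return GroupComparisonResult(
        gene=gene,
        group_means={g: float(v.mean()) for g, v in groups.items()},
        group_sds={g: float(v.std(ddof=1)) for g, v in groups.items()},
        group_ns={g: int(len(v)) for g, v in groups.items()},
        F_statistic=float(F),
        p_anova=float(p),
        excluded_groups=excluded,
    )


def two_group_test(
    cohort: ExpressionCohort,
    gene: str,
    grouping: str | pd.Series = "i17q_status",
    within_subgroup: str | None = None,
    equal_var: bool = False,
) -> GroupComparisonResult:
    """Two-group test of a gene's log2 expression for a binary grouping.

    ``grouping`` names a sample-metadata column (``i17q_status``,
    ``sex``) or is an explicit per-sample label series with exactly two
    levels. ``within_subgroup`` restricts the contrast to one molecular
    subgroup (the group-4-only i17q comparison). Welch by default;
    ``equal_var=True`` gives the pooled-variance test.
    """
    if within_subgroup is not None:
        mask = cohort.sample_meta["subgroup"] == within_subgroup
        if not mask.any():
            raise ValueError(f"no samples in subgroup {within_subgroup!r}")
        cohort = cohort.subset_samples(mask)
    values = _gene_values(cohort, gene)
    labels = (
        cohort.sample_meta[grouping]
        if isinstance(grouping, str)
        else grouping.reindex(cohort.matrix.columns)
    )
    levels = sorted(pd.unique(labels.dropna()), key=str, reverse=True)
    if len(levels) != 2:
        raise ValueError(f"grouping must have exactly 2 levels, got {levels}")
    a = values[labels[labels == levels[0]].index].to_numpy()
    b = values[labels[labels == levels[1]].index].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"degenerate class sizes for {gene!r}: "
            f"{levels[0]}={len(a)}, {levels[1]}={len(b)}"
        )
    if np.ptp(np.concatenate([a, b])) == 0:
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    diff = a.mean() - b.mean()
    return GroupComparisonResult(
        gene=gene,
        group_means={str(levels[0]): float(a.mean()), str(levels[1]): float(b.mean())},
        group_sds={
            str(levels[0]): float(np.std(a, ddof=1)),
            str(levels[1]): float(np.std(b, ddof=1)),
        },
        group_ns={str(levels[0]): int(len(a)), str(levels[1]): int(len(b))},
        t_statistic=float(t),
        p_ttest=float(p),
        direction="up" if diff > 0 else ("down" if diff < 0 else "none"),
    )
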