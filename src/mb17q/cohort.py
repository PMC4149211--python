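"""The in-memory expression cohort container.

An :class:`ExpressionCohort` bundles a log2 expression matrix
(features x samples) with feature metadata (gene symbol, chromosome,
1-based position, probe count) and sample metadata (molecular subgroup,
i17q status, sex). It is the shared input type of the dosage and
subgroup-comparison analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

SUBGROUPS = ("WNT", "SHH", "group3", "group4")

FEATURE_META_COLUMNS = ("gene", "chrom", "pos", "n_probes")
SAMPLE_META_COLUMNS = ("subgroup", "i17q_status", "sex")


@dataclass
class ExpressionCohort:
    """Expression matrix plus aligned feature and sample metadata.

    Parameters
    ----------
    matrix
        Features x samples, log2 scale. Index = feature identifiers,
        columns = sample identifiers.
    feature_meta
        One row per feature, indexed like ``matrix``; columns
        ``gene, chrom, pos, n_probes``.
    sample_meta
        One row per sample, indexed like ``matrix.columns``; columns
        ``subgroup, i17q_status, sex``.
    """

    matrix: pd.DataFrame
    feature_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.matrix.index.duplicated().any():
            dups = self.matrix.index[self.matrix.index.duplicated()].unique()
            raise ValueError(f"duplicate feature identifiers: {list(dups)[:5]}")
        if not self.matrix.index.equals(self.feature_meta.index):
            raise ValueError(
                "feature metadata does not match matrix rows: "
                f"matrix has {self.matrix.shape[0]} features, "
                f"metadata has {self.feature_meta.shape[0]}"
            )
        if not self.matrix.columns.equals(self.sample_meta.index):
            missing = self.matrix.columns.difference(self.sample_meta.index)
            if len(missing):
                raise ValueError(
                    f"samples missing from sample metadata: {list(missing)[:5]}"
                )
            raise ValueError(
                "sample metadata does not match matrix columns: "
                f"matrix has {self.matrix.shape[1]} samples, "
                f"metadata has {self.sample_meta.shape[0]}"
            )
        for col in FEATURE_META_COLUMNS:
            if col not in self.feature_meta.columns:
                raise ValueError(f"feature metadata lacks column {col!r}")
        for col in SAMPLE_META_COLUMNS:
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def i17q_mask(self) -> pd.Series:
        """Boolean sample mask, True for i17q-positive samples."""
        return self.sample_meta["i17q_status"].astype(int) == 1

    def feature_for_gene(self, gene: str) -> str:
        """Return the feature id carrying ``gene``; error if absent/ambiguous."""
        hits = self.feature_meta.index[self.feature_meta["gene"] == gene]
        if len(hits) == 0:
            raise KeyError(f"gene {gene!r} not present in cohort")
        if len(hits) > 1:
            raise KeyError(f"gene {gene!r} maps to multiple features: {list(hits)}")
        return hits[0]

    def subset_samples(self, mask: pd.Series) -> "ExpressionCohort":
        keep = self.matrix.columns[mask.reindex(self.matrix.columns).astype(bool)]
        return ExpressionCohort(
            matrix=self.matrix[keep],
            feature_meta=self.feature_meta,
            sample_meta=self.sample_meta.loc[keep],
        )
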