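"""Readers and writers for the package's file formats.

Variant calls travel as VCF (one file per sample/replicate, allele
fraction and depth in FORMAT fields ``AF``/``DP``, mapping quality and
annotations in INFO) or as an equivalent TSV dialect with explicit
headers. Expression cohorts are a features x samples TSV with sidecar
feature- and sample-metadata TSVs. Clinical tables are TSV. All
coordinates are 1-based (VCF convention).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .cohort import ExpressionCohort

__all__ = [
    "write_variant_vcf",
    "write_variant_tsv",
    "read_variant_file",
    "read_variant_files",
    "write_expression_bundle",
    "read_expression_bundle",
    "read_clinical_table",
    "write_clinical_table",
    "write_json",
]

VARIANT_COLUMNS = [
    "sample_id",
    "replicate_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "qual",
    "mapq",
    "af",
    "depth",
    "function_class",
    "pop_af",
    "gene",
]

_CONTIG_LENGTHS = {
    "chr7": 160_000_000,
    "chrX": 156_000_000,
    "chr17": 84_000_000,
    "panel": 1_000_000,
}


def _vcf_header(sample_label: str, contigs: list[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for c in contigs:
        header.contigs.add(c, length=_CONTIG_LENGTHS.get(c, 250_000_000))
    header.info.add("MQ", 1, "Float", "Mapping quality")
    header.info.add("FUNC", 1, "String", "Functional annotation class")
    header.info.add("POPAF", 1, "Float", "Max documented population allele frequency")
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.formats.add("AF", 1, "Float", "Alternate allele fraction")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.add_sample(sample_label)
    return header


def write_variant_vcf(calls: pd.DataFrame, path: str | Path) -> None:
    """Write one sample/replicate call set as an uncompressed VCF.

    The VCF sample column is named ``<sample_id>__<replicate_id>`` so a
    round-trip recovers both identifiers.
    """
    path = Path(path)
    if calls.empty:
        raise ValueError("refusing to write an empty VCF without sample identity")
    samples = calls["sample_id"].unique()
    reps = calls["replicate_id"].unique()
    if len(samples) != 1 or len(reps) != 1:
        raise ValueError("write_variant_vcf takes calls of one sample/replicate")
    label = f"{samples[0]}__{reps[0]}"
    contigs = sorted(calls["chrom"].unique())
    header = _vcf_header(label, contigs)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for _, row in calls.sort_values(["chrom", "pos"]).iterrows():
            rec = vcf.new_record(
                contig=row["chrom"],
                start=int(row["pos"]) - 1,  # pysam is 0-based internally
                alleles=(row["ref"], row["alt"]),
                qual=float(row["qual"]),
            )
            rec.info["MQ"] = float(row["mapq"])
            rec.info["FUNC"] = str(row["function_class"])
            if pd.notna(row["pop_af"]):
                rec.info["POPAF"] = float(row["pop_af"])
            rec.info["GENE"] = str(row["gene"])
            rec.samples[label]["AF"] = float(row["af"])
            rec.samples[label]["DP"] = int(row["depth"])
            vcf.write(rec)


def write_variant_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    calls[VARIANT_COLUMNS].to_csv(path, sep="\t", index=False)


def _read_vcf(path: Path) -> pd.DataFrame:
    with pysam.VariantFile(str(path)) as vcf:
        if "AF" not in vcf.header.formats:
            raise ValueError(
                f"{path}: FORMAT field 'AF' (allele fraction) missing from header"
            )
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise ValueError(f"{path}: expected exactly one sample column")
        label = samples[0]
        sample_id, _, replicate_id = label.partition("__")
        replicate_id = replicate_id or "pooled"
        rows = []
        for i, rec in enumerate(vcf, start=1):
            try:
                af = rec.samples[label].get("AF")
                if af is None:
                    raise ValueError("FORMAT AF value absent")
                rows.append(
                    dict(
                        sample_id=sample_id,
                        replicate_id=replicate_id,
                        chrom=rec.chrom,
                        pos=rec.pos,  # pysam .pos is 1-based
                        ref=rec.ref,
                        alt=rec.alts[0],
                        qual=float(rec.qual),
                        mapq=float(rec.info.get("MQ", np.nan)),
                        af=float(af),
                        depth=int(rec.samples[label].get("DP") or 0),
                        function_class=rec.info.get("FUNC", "other"),
                        pop_af=float(rec.info["POPAF"])
                        if "POPAF" in rec.info
                        else np.nan,
                        gene=rec.info.get("GENE", ""),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}: malformed record at line ~{i}: {exc}")
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def _read_tsv_calls(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: variant TSV missing columns {missing}")
    return df[VARIANT_COLUMNS]


def read_variant_file(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read one variant file (VCF or TSV) into the VariantCall frame."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"variant file not found: {path}")
    if dialect is None:
        dialect = "VCF" if path.suffix.lower() == ".vcf" else "TSV"
    if dialect.upper() == "VCF":
        return _read_vcf(path)
    if dialect.upper() == "TSV":
        return _read_tsv_calls(path)
    raise ValueError(f"dialect must be VCF or TSV, got {dialect!r}")


def read_variant_files(paths, dialect: str | None = None) -> pd.DataFrame:
    frames = [read_variant_file(p, dialect) for p in paths]
    if not frames:
        return pd.DataFrame(columns=VARIANT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def write_expression_bundle(
    cohort: ExpressionCohort,
    expr_path: str | Path,
    feature_meta_path: str | Path,
    sample_meta_path: str | Path,
) -> None:
    cohort.matrix.to_csv(expr_path, sep="\t", index_label="feature_id")
    cohort.feature_meta.to_csv(feature_meta_path, sep="\t", index_label="feature_id")
    cohort.sample_meta.to_csv(sample_meta_path, sep="\t", index_label="sample_id")


def read_expression_bundle(
    expr_path: str | Path,
    feature_meta_path: str | Path,
    sample_meta_path: str | Path,
) -> ExpressionCohort:
    """Load and validate a matrix + feature-metadata + sample-metadata trio."""
    matrix = pd.read_csv(expr_path, sep="\t", index_col="feature_id")
    feature_meta = pd.read_csv(feature_meta_path, sep="\t", index_col="feature_id")
    sample_meta = pd.read_csv(sample_meta_path, sep="\t", index_col="sample_id")
    if matrix.shape[0] != feature_meta.shape[0]:
        raise ValueError(
            f"dimension mismatch: matrix has {matrix.shape[0]} features, "
            f"feature metadata has {feature_meta.shape[0]}"
        )
    if matrix.shape[1] != sample_meta.shape[0]:
        raise ValueError(
            f"dimension mismatch: matrix has {matrix.shape[1]} samples, "
            f"sample metadata has {sample_meta.shape[0]}"
        )
    return ExpressionCohort(matrix, feature_meta, sample_meta)


CLINICAL_COLUMNS = [
    "patient_id",
    "risk_group",
    "mutation_positive",
    "i17q_positive",
    "os_time",
    "os_event",
    "dfs_time",
    "dfs_event",
]


def write_clinical_table(records: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in CLINICAL_COLUMNS if c in records.columns]
    records[cols].to_csv(path, sep="\t", index=False)


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: clinical table missing columns {missing}")
    for col in ("mutation_positive", "i17q_positive", "os_event", "dfs_event"):
        df[col] = df[col].astype(bool)
    if (df["dfs_time"] > df["os_time"] + 1e-9).any():
        raise ValueError(f"{path}: DFS time exceeds OS time for some patients")
    return df


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default, sort_keys=True))
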