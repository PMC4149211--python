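"""Synthetic cohorts with the statistical structure the analyses assume.

Three generators produce (1) per-replicate and pooled variant call sets
with replicate-consistent true variants and replicate-independent FFPE
deamination artifacts, (2) expression cohorts with hemizygous/duplicated
chromosome-17 dosage compartments in i17q-positive samples and an
optional focally over-suppressed gene, and (3) survival cohorts with
stratum-specific exponential hazards. A packaged fixture provides the
13-row mutation table of the 57-tumor sequencing cohort.

All generators are deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .config import CHR17_LENGTH, ConfigError, SimConfig

__all__ = [
    "gen_variant_replicates",
    "gen_expression_cohort",
    "gen_survival_cohort",
    "load_table1_fixture",
    "REPORTABLE_CLASSES",
    "FILTERABLE_CLASSES",
]

# annotation classes that survive the functional-annotation filter
REPORTABLE_CLASSES = ("nonsynonymous", "stopgain", "frameshift", "splice_site")
# classes the filter removes
FILTERABLE_CLASSES = ("synonymous", "intronic")

_BASES = np.array(list("ACGT"))

# amplicon panel layout: position ranges (1-based, inclusive) per gene,
# expressed as fractions of the panel, with a carrier chromosome for VCF
# emission. MLL3 dominates the panel as it dominates the target set.
_PANEL_GENES = (
    ("MLL3", "chr7", 0.00, 0.60),
    ("KDM6A", "chrX", 0.60, 0.75),
    ("ZMYM3", "chrX", 0.75, 0.90),
    ("GPS2", "chr17", 0.90, 1.00),
)

_MEAN_SITE_DEPTH = 600


def _panel_gene_of(pos: np.ndarray, n_positions: int) -> tuple[np.ndarray, np.ndarray]:
    """Map 1-based panel positions to (gene, chrom) arrays."""
    frac = (pos - 1) / n_positions
    genes = np.empty(pos.shape, dtype=object)
    chroms = np.empty(pos.shape, dtype=object)
    for gene, chrom, lo, hi in _PANEL_GENES:
        m = (frac >= lo) & (frac < hi)
        genes[m] = gene
        chroms[m] = chrom
    return genes, chroms


def gen_variant_replicates(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate per-replicate call sets, a pooled call set and a truth table.

    True somatic variants appear in every replicate of their sample with
    allele fraction drawn from ``true_af_range``; artifact calls arise
    independently per replicate with substitutions biased toward C>T/G>A
    (FFPE deamination) and right-skewed low allele fractions. The pooled
    set is the per-sample union with AF recomputed as the read-weighted
    mean across all replicates (AF 0 where the variant was not called).

    Returns
    -------
    replicates, pooled, truth : DataFrame
        ``replicates`` and ``pooled`` carry the VariantCall columns
        (sample_id, replicate_id, chrom, pos, ref, alt, qual, mapq, af,
        depth, function_class, pop_af, gene); ``truth`` labels every
        distinct (sample, chrom, pos, ref, alt) as ``true`` or
        ``artifact``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    n_pos = config.n_target_positions
    # fixed reference base per panel position
    ref_base = _BASES[rng.integers(0, 4, size=n_pos)]

    rows: list[dict] = []
    rep_ids = [f"r{i + 1}" for i in range(config.n_replicates_per_sample)]
    lo_af, hi_af = config.true_af_range
    a, b, scale = config.artifact_af_beta

    for si in range(config.n_samples):
        sample = f"S{si + 1:03d}"
        # --- true variants: shared across replicates ---
        n_true = rng.poisson(config.true_variant_rate)
        true_pos = rng.choice(n_pos, size=min(n_true, n_pos), replace=False) + 1
        for pos in true_pos:
            ref = ref_base[pos - 1]
            alt = rng.choice(_BASES[_BASES != ref])
            for rep in rep_ids:
                rows.append(
                    dict(
                        sample_id=sample,
                        replicate_id=rep,
                        pos=int(pos),
                        ref=ref,
                        alt=alt,
                        af=rng.uniform(lo_af, hi_af),
                        qual=rng.uniform(45.0, 60.0),
                        mapq=60.0,
                        depth=int(rng.poisson(_MEAN_SITE_DEPTH)) + 1,
                        is_true=True,
                    )
                )
        # --- artifacts: independent per replicate ---
        for rep in rep_ids:
            n_art = rng.poisson(config.artifact_rate)
            art_pos = rng.integers(1, n_pos + 1, size=n_art)
            for pos in art_pos:
                ref = ref_base[pos - 1]
                if ref in ("C", "G") and rng.random() < 0.8:
                    alt = "T" if ref == "C" else "A"  # deamination
                else:
                    alt = rng.choice(_BASES[_BASES != ref])
                rows.append(
                    dict(
                        sample_id=sample,
                        replicate_id=rep,
                        pos=int(pos),
                        ref=ref,
                        alt=alt,
                        af=float(np.clip(scale * rng.beta(a, b), 1e-4, scale)),
                        qual=rng.uniform(20.0, 55.0),
                        mapq=60.0 if rng.random() < 0.85 else rng.uniform(10.0, 40.0),
                        depth=int(rng.poisson(_MEAN_SITE_DEPTH)) + 1,
                        is_true=False,
                    )
                )

    columns = [
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
        "is_true",
    ]
    if not rows:
        empty = pd.DataFrame(columns=columns)
        truth = pd.DataFrame(
            columns=["sample_id", "chrom", "pos", "ref", "alt", "label"]
        )
        return empty.drop(columns="is_true"), empty.drop(columns="is_true"), truth

    df = pd.DataFrame(rows)
    genes, chroms = _panel_gene_of(df["pos"].to_numpy(), n_pos)
    df["gene"] = genes
    df["chrom"] = chroms

    # an artifact colliding with a true variant of the same sample at the
    # same site is absorbed by the true call
    df = df.sort_values("is_true", ascending=False, kind="stable")
    df = df.drop_duplicates(
        subset=["sample_id", "replicate_id", "chrom", "pos", "ref", "alt"],
        keep="first",
    )

    # annotation is a property of the variant, not of the observation:
    # assign function class and population frequency once per distinct
    # (chrom, pos, ref, alt), consistently across samples and replicates
    keys = (
        df[["chrom", "pos", "ref", "alt", "is_true"]]
        .drop_duplicates(subset=["chrom", "pos", "ref", "alt"])
        .sort_values(["chrom", "pos", "ref", "alt"])
        .reset_index(drop=True)
    )
    ann_rng = np.random.default_rng([config.seed, 102])
    func = np.empty(len(keys), dtype=object)
    pop = np.full(len(keys), np.nan)
    is_true_key = keys["is_true"].to_numpy()
    # true somatic variants in the panel genes are protein-altering and
    # absent from the population databases by construction
    n_true_keys = int(is_true_key.sum())
    func[is_true_key] = ann_rng.choice(
        REPORTABLE_CLASSES, p=[0.69, 0.12, 0.08, 0.11], size=n_true_keys
    )
    n_art_keys = int((~is_true_key).sum())
    func[~is_true_key] = ann_rng.choice(
        ["nonsynonymous", "synonymous", "intronic", "stopgain", "splice_site", "other"],
        p=[0.35, 0.20, 0.20, 0.05, 0.05, 0.15],
        size=n_art_keys,
    )
    has_pop = ann_rng.random(n_art_keys) < 0.15
    pop_art = np.full(n_art_keys, np.nan)
    pop_art[has_pop] = 10 ** ann_rng.uniform(-4.0, -0.7, size=int(has_pop.sum()))
    pop[~is_true_key] = pop_art
    keys = keys.assign(function_class=func, pop_af=pop).drop(columns="is_true")

    df = df.merge(keys, on=["chrom", "pos", "ref", "alt"], how="left")

    # --- pooled set: union per sample, read-weighted mean AF ---
    pool_rng = np.random.default_rng([config.seed, 103])
    grouped = df.groupby(
        ["sample_id", "chrom", "pos", "ref", "alt"], sort=True, as_index=False
    )
    pooled_rows = []
    n_reps = config.n_replicates_per_sample
    for (sample, chrom, pos, ref, alt), g in grouped:
        called_depth = g["depth"].sum()
        alt_reads = (g["af"] * g["depth"]).sum()
        # replicates not calling the variant still contribute coverage
        n_missing = n_reps - len(g)
        missing_depth = int(pool_rng.poisson(_MEAN_SITE_DEPTH * max(n_missing, 0))) + (
            1 if n_missing > 0 else 0
        )
        total_depth = called_depth + missing_depth
        pooled_rows.append(
            dict(
                sample_id=sample,
                replicate_id="pooled",
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                qual=float((g["qual"] * g["depth"]).sum() / called_depth),
                mapq=float((g["mapq"] * g["depth"]).sum() / called_depth),
                af=float(alt_reads / total_depth),
                depth=int(total_depth),
                function_class=g["function_class"].iloc[0],
                pop_af=g["pop_af"].iloc[0],
                gene=g["gene"].iloc[0],
                is_true=bool(g["is_true"].iloc[0]),
            )
        )
    pooled = pd.DataFrame(pooled_rows, columns=columns)

    truth = (
        pooled[["sample_id", "chrom", "pos", "ref", "alt", "is_true"]]
        .assign(label=lambda t: np.where(t["is_true"], "true", "artifact"))
        .drop(columns="is_true")
        .reset_index(drop=True)
    )

    replicates = df.drop(columns="is_true").reset_index(drop=True)
    pooled = pooled.drop(columns="is_true")
    return replicates, pooled, truth


# fixed-coordinate marker genes on chromosome 17: TP53 on 17p (hemizygous
# in i17q), PPM1D/WIP1 on 17q (duplicated in i17q)
_NAMED_CHR17_GENES = (("TP53", 7_668_402), ("PPM1D", 58_700_000))

_NEGATIVE_SUBGROUP_PROBS = {  # subgroup mix among i17q-negative tumors
    "WNT": 0.11,
    "SHH": 0.45,
    "group3": 0.33,
    "group4": 0.11,
}


def gen_expression_cohort(config: SimConfig, hemizygous_feature_fraction: float = 0.55):
    """Simulate a log2 expression cohort with i17q dosage structure.

    Per feature and sample, log2 expression = gene baseline + dosage term
    + noise, where the dosage term for i17q-positive samples is
    ``log2(hemizygous_fold)`` on chr17 below the breakpoint and
    ``log2(duplicated_fold)`` at or above it, zero otherwise. The focal
    gene receives an additional ``focal_excess_log2`` suppression in
    i17q-positive samples. The hemizygous compartment deliberately
    carries more features than 17q, mirroring exon-array feature density
    on 17p.

    Parameters
    ----------
    hemizygous_feature_fraction
        Fraction of chromosome-17 features placed below the breakpoint
        (the count is deterministic: ``round(fraction * n_chr17_features)``).
    """
    from .cohort import ExpressionCohort

    config.validate()
    if not 0.0 <= hemizygous_feature_fraction <= 1.0:
        raise ConfigError("hemizygous_feature_fraction must be in [0, 1]")
    named = [(g, p) for g, p in _NAMED_CHR17_GENES]
    focal_pos = dict(named).get(config.focal_gene)
    if focal_pos is not None and config.breakpoint <= focal_pos:
        raise ConfigError(
            f"breakpoint {config.breakpoint} places focal gene "
            f"{config.focal_gene} outside the hemizygous compartment"
        )
    rng = np.random.default_rng([config.seed, 201])

    n17 = config.n_chr17_features
    if n17 < len(named):
        raise ConfigError("n_chr17_features must cover the named marker genes")
    n_hemi = int(round(hemizygous_feature_fraction * n17))
    named_below = sum(1 for _, p in named if p < config.breakpoint)
    n_hemi_unnamed = int(np.clip(n_hemi - named_below, 0, n17 - len(named)))
    n_dup_unnamed = n17 - len(named) - n_hemi_unnamed

    chr17_pos = [p for _, p in named]
    if config.breakpoint > 1 and n_hemi_unnamed:
        chr17_pos += list(rng.integers(1, config.breakpoint, size=n_hemi_unnamed))
    elif n_hemi_unnamed:
        raise ConfigError("breakpoint leaves no room for hemizygous features")
    if n_dup_unnamed:
        chr17_pos += list(
            rng.integers(config.breakpoint, CHR17_LENGTH + 1, size=n_dup_unnamed)
        )
    genes17 = [g for g, _ in named] + [
        f"GENE17_{i + 1:04d}" for i in range(n17 - len(named))
    ]

    n_other = config.n_features - n17
    other_chroms = rng.choice(
        [f"chr{c}" for c in list(range(1, 17)) + list(range(18, 23))], size=n_other
    )
    other_pos = rng.integers(1, 100_000_000, size=n_other)
    other_genes = [f"GENE_{i + 1:04d}" for i in range(n_other)]

    feature_meta = pd.DataFrame(
        {
            "gene": genes17 + other_genes,
            "chrom": ["chr17"] * n17 + list(other_chroms),
            "pos": np.asarray(chr17_pos + list(other_pos), dtype=np.int64),
            "n_probes": rng.integers(1, config.max_probes + 1, size=config.n_features),
        },
        index=[f"feat_{i + 1:05d}" for i in range(config.n_features)],
    )

    # samples: deterministic i17q-positive count, shuffled assignment
    n = config.n_samples
    n_pos = int(np.clip(round(n * config.i17q_fraction), 1, n - 1))
    status = np.array([1] * n_pos + [0] * (n - n_pos))
    rng.shuffle(status)
    subgroup = np.empty(n, dtype=object)
    sex = np.empty(n, dtype=object)
    neg_groups = list(_NEGATIVE_SUBGROUP_PROBS)
    neg_probs = list(_NEGATIVE_SUBGROUP_PROBS.values())
    for i in range(n):
        if status[i]:
            subgroup[i] = "group4" if rng.random() < config.group4_prob else "group3"
            sex[i] = "M" if rng.random() < 0.84 else "F"
        else:
            subgroup[i] = neg_groups[rng.choice(len(neg_groups), p=neg_probs)]
            sex[i] = "M" if rng.random() < 0.60 else "F"
    sample_meta = pd.DataFrame(
        {"subgroup": subgroup, "i17q_status": status.astype(int), "sex": sex},
        index=[f"T{i + 1:03d}" for i in range(n)],
    )

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_features)
    is17 = (feature_meta["chrom"] == "chr17").to_numpy()
    below = feature_meta["pos"].to_numpy() < config.breakpoint
    dosage = np.zeros(config.n_features)
    dosage[is17 & below] = np.log2(config.hemizygous_fold)
    dosage[is17 & ~below] = np.log2(config.duplicated_fold)
    focal_term = np.zeros(config.n_features)
    focal_mask = feature_meta["gene"].to_numpy() == config.focal_gene
    focal_term[focal_mask] = -config.focal_excess_log2

    effect = (dosage + focal_term)[:, None] * status[None, :]
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_features, n))
    matrix = pd.DataFrame(
        baseline[:, None] + effect + noise,
        index=feature_meta.index,
        columns=sample_meta.index,
    )
    return ExpressionCohort(matrix, feature_meta, sample_meta)


def _resolve_strata(
    risk_assignment,
    patients: pd.DataFrame,
) -> np.ndarray:
    """Resolve per-patient hazard stratum labels from a flexible spec."""
    n = len(patients)
    if risk_assignment is None or risk_assignment == "risk_group":
        return patients["risk_group"].to_numpy()
    if callable(risk_assignment):
        return np.array([risk_assignment(row) for row in patients.to_dict("records")])
    if isinstance(risk_assignment, str):
        if risk_assignment == "mutation":
            flags = patients["mutation_positive"].to_numpy()
        elif risk_assignment == "i17q":
            flags = patients["i17q_positive"].to_numpy()
        elif risk_assignment == "combined":
            flags = (
                patients["mutation_positive"] | patients["i17q_positive"]
            ).to_numpy()
        else:
            raise ConfigError(
                "risk_assignment must be None, 'risk_group', 'mutation', "
                "'i17q', 'combined', a callable or a sequence of labels"
            )
        return np.where(flags, "high", "low")
    labels = np.asarray(list(risk_assignment), dtype=object)
    if len(labels) != n:
        raise ConfigError(
            f"risk_assignment sequence length {len(labels)} != n_samples {n}"
        )
    return labels


def gen_survival_cohort(config: SimConfig, risk_assignment=None) -> pd.DataFrame:
    """Simulate a clinical table with exponential stratum-specific hazards.

    Event times are exponential with the hazard of the patient's
    stratum (``hazard_by_group``, events per month); disease-free
    survival adds an independent relapse clock so that the DFS hazard is
    ``dfs_hazard_multiplier`` times the death hazard and the DFS time
    never exceeds the OS time. Both endpoints are administratively
    censored at ``censor_time``.

    ``risk_assignment`` selects the hazard stratum per patient: ``None``
    uses the clinical risk group, the strings ``"mutation"``, ``"i17q"``
    and ``"combined"`` stratify by molecular flags (strata named
    ``high``/``low``), or pass a callable / explicit label sequence.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 301])
    n = config.n_samples
    n_hr = int(np.clip(round(n * config.hr_fraction), 0, n))
    risk = np.array(["HR"] * n_hr + ["SR"] * (n - n_hr), dtype=object)
    rng.shuffle(risk)
    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(n)],
            "risk_group": risk,
            "mutation_positive": rng.random(n) < 0.18,
            "i17q_positive": rng.random(n) < 0.30,
        }
    )
    strata = _resolve_strata(risk_assignment, patients)
    unknown = set(strata) - set(config.hazard_by_group)
    if unknown:
        raise ConfigError(
            f"strata {sorted(unknown)} have no entry in hazard_by_group "
            f"(known: {sorted(config.hazard_by_group)})"
        )
    hazards = np.array([config.hazard_by_group[s] for s in strata])

    os_raw = rng.exponential(1.0 / hazards)
    mult = max(config.dfs_hazard_multiplier, 1.0)
    if mult > 1.0:
        relapse = rng.exponential(1.0 / (hazards * (mult - 1.0)))
    else:
        relapse = np.full(n, np.inf)
    dfs_raw = np.minimum(relapse, os_raw)

    c = config.censor_time
    patients["sim_stratum"] = strata
    patients["os_time"] = np.minimum(os_raw, c)
    patients["os_event"] = os_raw < c
    patients["dfs_time"] = np.minimum(dfs_raw, c)
    patients["dfs_event"] = dfs_raw < c
    return patients


_TABLE1_COLUMNS = [
    "sample_id",
    "gene",
    "function_class",
    "damaging_tally",
    "chrom",
    "start",
    "ref",
    "obs",
]


def load_table1_fixture() -> pd.DataFrame:
    """Load the packaged 13-row mutation table of the sequencing cohort.

    One row per reportable mutation: sample, gene, exonic function,
    coordinates, ref/obs alleles, and the "k/4"-style tally of damage
    predictors (absent for stopgain / frameshift / splice-site calls,
    for which the predictors make no call).
    """
    try:
        path = resources.files("mb17q.data").joinpath("table1_mutations.tsv")
        with path.open() as fh:
            df = pd.read_csv(
                fh,
                sep="\t",
                dtype={"sample_id": str, "damaging_tally": str},
            )
    except (FileNotFoundError, OSError) as exc:
        raise RuntimeError(f"mutation-table fixture missing or unreadable: {exc}")
    missing = [c for c in _TABLE1_COLUMNS if c not in df.columns]
    if missing or df[["sample_id", "gene", "function_class", "chrom", "start"]].isna().any().any():
        raise RuntimeError(f"mutation-table fixture corrupt (missing {missing})")
    df["damaging_tally"] = df["damaging_tally"].fillna("")
    return df
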