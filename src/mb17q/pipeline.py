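"""End-to-end orchestration: filter -> summarize -> dosage -> compare -> survival.

Given a :class:`~mb17q.config.RunConfig` with input paths, the pipeline
runs each analysis stage in order and writes fixed-name outputs plus a
provenance record (config hash, seed, stage counts) to the output
directory. Any input left unset is synthesized from the packaged
generators with the run seed, which gives a self-contained demo mode.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import dosage, expression, io, simulate, survival, variants
from .config import RunConfig, SimConfig


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


@_stage("inputs")
def _load_inputs(config: RunConfig, outdir: Path):
    sim = SimConfig(seed=config.seed, breakpoint=config.breakpoint,
                    focal_gene=config.focal_gene)
    if config.pooled_variants:
        pooled = io.read_variant_file(config.pooled_variants)
        reps = io.read_variant_files(config.replicate_variants)
        truth = (
            pd.read_csv(config.truth_table, sep="\t") if config.truth_table else None
        )
    else:
        reps, pooled, truth = simulate.gen_variant_replicates(sim)
        io.write_variant_tsv(pooled, outdir / "sim_pooled_calls.tsv")
        io.write_variant_tsv(reps, outdir / "sim_replicate_calls.tsv")
        truth.to_csv(outdir / "sim_truth.tsv", sep="\t", index=False)
    if config.expression:
        cohort = io.read_expression_bundle(
            config.expression, config.feature_meta, config.sample_meta
        )
    else:
        cohort = simulate.gen_expression_cohort(sim)
        io.write_expression_bundle(
            cohort,
            outdir / "sim_expression.tsv",
            outdir / "sim_feature_meta.tsv",
            outdir / "sim_sample_meta.tsv",
        )
    if config.clinical:
        clinical = io.read_clinical_table(config.clinical)
    else:
        # demo survival data: hazard follows the combined molecular-risk label
        surv_sim = SimConfig(
            seed=config.seed, hazard_by_group={"low": 0.0025, "high": 0.0153}
        )
        clinical = simulate.gen_survival_cohort(surv_sim, risk_assignment="combined")
        io.write_clinical_table(clinical, outdir / "sim_clinical.tsv")
    panel = (
        pd.read_csv(config.gene_panel, sep="\t") if config.gene_panel else None
    )
    return pooled, reps, truth, cohort, clinical, panel


@_stage("variant_filtering")
def _run_variants(config: RunConfig, pooled, reps, truth, outdir: Path):
    retained, report = variants.run_filter_pipeline(
        pooled,
        reps,
        min_qual=config.min_qual,
        min_mapq=config.min_mapq,
        min_af=config.min_af,
        max_pop_af=config.max_pop_af,
        min_replicate_af=config.min_replicate_af,
    )
    if truth is not None:
        report = variants.evaluate_filter_performance(
            retained, truth, report.stage_counts
        )
    records = variants.records_from_calls(retained)
    summary = variants.summarize_mutation_table(records, config.cohort_size)
    records.to_csv(outdir / "filtered_mutations.tsv", sep="\t", index=False)
    io.write_json(report.to_dict(), outdir / "filter_report.json")
    io.write_json(summary, outdir / "mutation_summary.json")
    return records, report, summary


@_stage("dosage_analysis")
def _run_dosage(config: RunConfig, cohort, panel, outdir: Path):
    result = dosage.focal_excess_test(
        cohort,
        focal_gene=config.focal_gene,
        breakpoint=config.breakpoint,
        alpha=config.alpha,
    )
    io.write_json(result.to_dict(), outdir / "dosage_result.json")
    fold_frame = pd.DataFrame(
        {
            "fold_expression": result.fold_expression,
            "compartment": result.compartments,
        }
    )
    fold_frame.to_csv(outdir / "fold_expression.tsv", sep="\t", index_label="feature_id")
    if panel is not None:
        profile = dosage.pathway_panel_profile(cohort, panel)
        profile.to_csv(outdir / "panel_profile.tsv", sep="\t")
    return result


@_stage("expression_compare")
def _run_compare(config: RunConfig, cohort, genes, outdir: Path):
    cohort_n = expression.probe_normalize(cohort)
    rows = []
    for gene in genes:
        try:
            a = expression.subgroup_anova(cohort_n, gene)
            t = expression.two_group_test(cohort_n, gene, "i17q_status")
        except (KeyError, ValueError):
            continue
        rows.append(
            {
                "gene": gene,
                "F_statistic": a.F_statistic,
                "p_anova": a.p_anova,
                "t_statistic": t.t_statistic,
                "p_ttest": t.p_ttest,
                "direction_i17q": t.direction,
            }
        )
    out = pd.DataFrame(rows)
    out.to_csv(outdir / "compare_results.tsv", sep="\t", index=False)
    return out


@_stage("survival_stratification")
def _run_survival(config: RunConfig, clinical, outdir: Path):
    labeled = survival.assign_combined_risk(clinical)
    grid = survival.full_survival_grid(labeled)
    grid.to_csv(outdir / "survival_grid.tsv", sep="\t", index=False)
    for endpoint in ("OS", "DFS"):
        res = survival.run_survival_analysis(labeled, "combined", endpoint, "all")
        for level, curve in res["curves"].items():
            curve.to_frame().to_csv(
                outdir / f"km_{endpoint}_{level}.tsv", sep="\t", index=False
            )
    return grid


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for attr in ("pooled_variants", "expression", "clinical"):
        p = getattr(config, attr)
        if p and not Path(p).exists():
            raise PipelineError(f"stage 'inputs' failed: input path missing: {p}")

    pooled, reps, truth, cohort, clinical, panel = _load_inputs(config, outdir)
    records, report, summary = _run_variants(config, pooled, reps, truth, outdir)
    dosage_result = _run_dosage(config, cohort, panel, outdir)
    genes = ["MLL3", "KDM6A", "GPS2", "ZMYM3", config.focal_gene, "PPM1D"]
    compare = _run_compare(config, cohort, genes, outdir)
    grid = _run_survival(config, clinical, outdir)

    run_report = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stage_counts": report.stage_counts,
        "mutation_summary": summary,
        "dosage": dosage_result.to_dict(),
        "n_compare_genes": int(len(compare)),
        "survival_cells": int(len(grid)),
    }
    io.write_json(run_report, outdir / "run_report.json")
    return run_report
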