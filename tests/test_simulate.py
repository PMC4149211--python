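"""Tests of the synthetic cohort generators and the packaged mutation table."""

import numpy as np
import pandas as pd
import pytest

from mb17q.config import ConfigError, SimConfig
from mb17q.simulate import (
    gen_expression_cohort,
    gen_survival_cohort,
    gen_variant_replicates,
    load_table1_fixture,
)


class TestSimConfig:
    def test_invalid_field_error_names_the_field(self):
        with pytest.raises(ConfigError, match="i17q_fraction"):
            SimConfig(i17q_fraction=1.5)
        with pytest.raises(ConfigError, match="true_variant_rate"):
            SimConfig(true_variant_rate=-1)
        with pytest.raises(ConfigError, match="hemizygous_fold"):
            SimConfig(hemizygous_fold=1.2)
        with pytest.raises(ConfigError, match="breakpoint"):
            SimConfig(breakpoint=999_000_000)

    def test_roundtrips_through_dict(self):
        cfg = SimConfig(seed=9, artifact_rate=3.5)
        assert SimConfig.from_dict(cfg.to_dict()) == cfg


class TestVariantReplicates:
    def test_fixed_seed_gives_byte_identical_call_sets(self):
        cfg = SimConfig(seed=7, n_samples=20, true_variant_rate=0.5)
        a = gen_variant_replicates(cfg)
        b = gen_variant_replicates(cfg)
        for x, y in zip(a, b):
            assert x.to_csv() == y.to_csv()

    def test_no_artifacts_means_all_true_and_replicate_consistent(self):
        cfg = SimConfig(seed=3, n_samples=30, artifact_rate=0.0, true_variant_rate=1.0)
        reps, pooled, truth = gen_variant_replicates(cfg)
        assert (truth["label"] == "true").all()
        counts = reps.groupby(["sample_id", "chrom", "pos", "ref", "alt"]).size()
        assert (counts == cfg.n_replicates_per_sample).all()

    def test_true_variants_in_all_replicates_at_af_ge_020(self, small_variant_sim):
        cfg, reps, pooled, truth = small_variant_sim
        true_keys = truth[truth["label"] == "true"]
        merged = true_keys.merge(reps, on=["sample_id", "chrom", "pos", "ref", "alt"])
        per_var = merged.groupby(["sample_id", "chrom", "pos", "ref", "alt"])
        assert (per_var.size() == cfg.n_replicates_per_sample).all()
        assert (merged["af"] >= 0.2).all()

    def test_pooled_af_is_read_weighted_mean_bounded_by_replicates(
        self, small_variant_sim
    ):
        cfg, reps, pooled, truth = small_variant_sim
        # variants called in every replicate: pooled AF must lie within the
        # replicate AF range (weighted mean, no zero-AF padding)
        counts = reps.groupby(["sample_id", "chrom", "pos", "ref", "alt"])["af"]
        full = counts.agg(["size", "min", "max"])
        full = full[full["size"] == cfg.n_replicates_per_sample]
        keyed = pooled.set_index(["sample_id", "chrom", "pos", "ref", "alt"])
        sub = keyed.loc[full.index]
        assert (sub["af"] >= full["min"] - 1e-12).all()
        assert (sub["af"] <= full["max"] + 1e-12).all()

    def test_artifact_substitutions_biased_toward_deamination(self):
        cfg = SimConfig(
            seed=13, n_samples=200, true_variant_rate=0.0, artifact_rate=5.0
        )
        reps, _, truth = gen_variant_replicates(cfg)
        assert (truth["label"] == "artifact").all()
        sub = reps["ref"] + ">" + reps["alt"]
        deam = sub.isin(["C>T", "G>A"]).mean()
        assert deam > 0.4  # ~50% of refs are C/G, 80% of those deaminate

    def test_artifact_cooccurrence_matches_binomial_closed_form(self):
        """Empirical two-replicate same-site artifact rate vs the exact
        per-position Poisson-thinning probability (1 - exp(-rate/positions))^2."""
        n_pos, rate, n_samples = 200, 4.0, 1000
        cfg = SimConfig(
            seed=29,
            n_samples=n_samples,
            true_variant_rate=0.0,
            artifact_rate=rate,
            n_target_positions=n_pos,
        )
        reps, _, _ = gen_variant_replicates(cfg)
        hits = 0
        for _, g in reps.groupby("sample_id"):
            r1 = set(g.loc[g["replicate_id"] == "r1", "pos"])
            r2 = set(g.loc[g["replicate_id"] == "r2", "pos"])
            hits += len(r1 & r2)
        p_site = 1.0 - np.exp(-rate / n_pos)
        expected = n_samples * n_pos * p_site**2
        sd = np.sqrt(expected)  # Poisson-like tolerance
        assert abs(hits - expected) < 5 * sd + 5

    def test_annotation_is_consistent_per_variant_across_observations(
        self, small_variant_sim
    ):
        _, reps, pooled, _ = small_variant_sim
        both = pd.concat([reps, pooled], ignore_index=True)
        per_var = both.groupby(["chrom", "pos", "ref", "alt"])["function_class"]
        assert (per_var.nunique() == 1).all()


class TestExpressionCohort:
    def test_noiseless_folds_equal_configured_folds_exactly(self, noiseless_cohort):
        from mb17q.dosage import compute_fold_changes, partition_by_breakpoint

        cfg, cohort = noiseless_cohort
        fold = compute_fold_changes(cohort)
        comp = partition_by_breakpoint(cohort.feature_meta, cfg.breakpoint)
        assert np.allclose(fold[comp == "hemizygous"], cfg.hemizygous_fold)
        assert np.allclose(fold[comp == "duplicated"], cfg.duplicated_fold)
        assert np.allclose(fold[comp == "other"], 1.0)

    def test_focal_excess_halves_the_focal_fold(self):
        from mb17q.dosage import compute_fold_changes

        cfg = SimConfig(
            seed=5, n_samples=40, i17q_fraction=0.5, noise_sd=0.0,
            focal_excess_log2=1.0, n_features=100, n_chr17_features=60,
        )
        cohort = gen_expression_cohort(cfg)
        fold = compute_fold_changes(cohort)
        focal = cohort.feature_for_gene("TP53")
        assert fold[focal] == pytest.approx(cfg.hemizygous_fold / 2, abs=1e-12)

    def test_moment_recovery_of_fold_distribution(self):
        """Per-feature log2 fold-changes recover the generative mean and SD."""
        sd, n_per = 0.2, 50
        cfg = SimConfig(
            seed=17, n_samples=2 * n_per, i17q_fraction=0.5, noise_sd=sd,
            n_features=910, n_chr17_features=910,
        )
        cohort = gen_expression_cohort(cfg, hemizygous_feature_fraction=0.55)
        from mb17q.dosage import compute_fold_changes, partition_by_breakpoint

        log2fold = np.log2(compute_fold_changes(cohort))
        comp = partition_by_breakpoint(cohort.feature_meta, cfg.breakpoint)
        hemi = log2fold[(comp == "hemizygous")
                        & (cohort.feature_meta["gene"] != cfg.focal_gene)]
        k = len(hemi)
        assert k >= 400
        gen_sd = sd * np.sqrt(1 / n_per + 1 / n_per)
        assert abs(hemi.mean() - np.log2(cfg.hemizygous_fold)) < 3 * gen_sd / np.sqrt(k)
        se_sd = gen_sd / np.sqrt(2 * (k - 1))
        assert abs(hemi.std(ddof=1) - gen_sd) < 3 * se_sd

    def test_hemizygous_feature_count_is_deterministic(self):
        cfg = SimConfig(seed=2, n_samples=20, n_features=625, n_chr17_features=625)
        cohort = gen_expression_cohort(cfg, hemizygous_feature_fraction=0.8)
        below = (
            (cohort.feature_meta["chrom"] == "chr17")
            & (cohort.feature_meta["pos"] < cfg.breakpoint)
        ).sum()
        assert below == 500

    def test_i17q_samples_concentrate_in_group4(self):
        cfg = SimConfig(seed=23, n_samples=400, i17q_fraction=0.5)
        cohort = gen_expression_cohort(cfg)
        meta = cohort.sample_meta
        pos = meta[meta["i17q_status"] == 1]
        assert set(pos["subgroup"]) <= {"group3", "group4"}
        assert (pos["subgroup"] == "group4").mean() > 0.75

    def test_breakpoint_below_focal_gene_rejected(self):
        cfg = SimConfig(seed=1, n_samples=10, breakpoint=1_000_000)
        with pytest.raises(ConfigError, match="focal gene"):
            gen_expression_cohort(cfg)

    def test_fixed_seed_gives_identical_cohort(self):
        cfg = SimConfig(seed=31, n_samples=25, n_features=50, n_chr17_features=20)
        a = gen_expression_cohort(cfg)
        b = gen_expression_cohort(cfg)
        assert a.matrix.to_csv() == b.matrix.to_csv()
        assert a.sample_meta.to_csv() == b.sample_meta.to_csv()


class TestSurvivalCohort:
    def test_censor_time_zero_means_no_events(self):
        cfg = SimConfig(seed=3, n_samples=30, censor_time=0.0)
        rec = gen_survival_cohort(cfg)
        assert not rec["os_event"].any()
        assert not rec["dfs_event"].any()
        assert (rec["os_time"] == 0).all()

    def test_dfs_time_never_exceeds_os_time(self):
        cfg = SimConfig(seed=19, n_samples=500)
        rec = gen_survival_cohort(cfg)
        assert (rec["dfs_time"] <= rec["os_time"] + 1e-12).all()
        assert (rec["os_time"] >= 0).all()

    def test_fixed_seed_gives_identical_cohort(self):
        cfg = SimConfig(seed=8, n_samples=40)
        a = gen_survival_cohort(cfg)
        b = gen_survival_cohort(cfg)
        assert a.to_csv() == b.to_csv()

    def test_unknown_stratum_label_rejected(self):
        cfg = SimConfig(seed=8, n_samples=10)
        with pytest.raises(ConfigError, match="hazard_by_group"):
            gen_survival_cohort(cfg, risk_assignment=["nosuch"] * 10)

    def test_exponential_event_fraction_matches_hazard(self):
        lam, c = 0.01, 60.0
        cfg = SimConfig(
            seed=37, n_samples=4000, censor_time=c,
            hazard_by_group={"SR": lam, "HR": lam},
        )
        rec = gen_survival_cohort(cfg)
        expected = 1 - np.exp(-lam * c)
        se = np.sqrt(expected * (1 - expected) / len(rec))
        assert abs(rec["os_event"].mean() - expected) < 4 * se


class TestTable1Fixture:
    def test_thirteen_rows_ten_patients(self):
        t1 = load_table1_fixture()
        assert len(t1) == 13
        assert t1["sample_id"].nunique() == 10

    def test_sample_32_is_the_gps2_splice_site_variant(self):
        t1 = load_table1_fixture()
        row = t1[t1["sample_id"] == "32"].iloc[0]
        assert row["gene"] == "GPS2"
        assert row["function_class"] == "splice_site"
        assert (row["chrom"], row["start"]) == ("chr17", 7217225)
        assert (row["ref"], row["obs"]) == ("C", "T")

    def test_gene_and_class_composition(self):
        t1 = load_table1_fixture()
        assert (t1["gene"] == "MLL3").sum() == 11
        assert (t1["function_class"] == "nonsynonymous").sum() == 9
        # damage tallies absent exactly for stopgain/frameshift/splice rows
        no_tally = t1["damaging_tally"] == ""
        assert set(t1.loc[no_tally, "function_class"]) == {
            "splice_site", "frameshift", "stopgain",
        }
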