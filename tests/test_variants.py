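"""Tests of the stringent variant-retention pipeline and mutation summaries."""

import numpy as np
import pandas as pd
import pytest

from mb17q.simulate import load_table1_fixture
from mb17q.variants import (
    apply_annotation_filters,
    apply_call_thresholds,
    apply_concordance_filter,
    evaluate_filter_performance,
    records_from_calls,
    run_filter_pipeline,
    summarize_mutation_table,
)


def _call(**kw):
    base = dict(
        sample_id="S1", replicate_id="pooled", chrom="chr7", pos=100,
        ref="G", alt="A", qual=50.0, mapq=60.0, af=0.4, depth=500,
        function_class="nonsynonymous", pop_af=np.nan, gene="MLL3",
    )
    base.update(kw)
    return base


def calls_frame(rows):
    return pd.DataFrame(rows)


class TestCallThresholds:
    @pytest.mark.parametrize(
        "qual,mapq,af,kept",
        [
            (30.0, 30.0, 0.20, True),   # boundary: minima are inclusive
            (29.9, 60.0, 0.50, False),
            (60.0, 29.9, 0.50, False),
            (60.0, 60.0, 0.19, False),
            (60.0, 60.0, 0.21, True),
        ],
    )
    def test_boundary_semantics(self, qual, mapq, af, kept):
        df = calls_frame([_call(qual=qual, mapq=mapq, af=af)])
        out = apply_call_thresholds(df)
        assert len(out) == (1 if kept else 0)

    def test_matches_brute_force_predicate_on_random_calls(self):
        rng = np.random.default_rng(0)
        rows = [
            _call(pos=i, qual=rng.uniform(0, 60), mapq=rng.uniform(0, 60),
                  af=rng.uniform(0, 1))
            for i in range(100)
        ]
        df = calls_frame(rows)
        out = apply_call_thresholds(df)
        expected = [
            r["qual"] >= 30 and r["mapq"] >= 30 and r["af"] >= 0.20 for r in rows
        ]
        assert list(out.index) == [i for i, e in enumerate(expected) if e]

    def test_empty_input_returns_empty(self):
        df = calls_frame([_call()]).iloc[0:0]
        assert apply_call_thresholds(df).empty


class TestAnnotationFilters:
    def test_splice_site_without_pop_af_retained(self):
        df = calls_frame([_call(function_class="splice_site", pop_af=np.nan)])
        assert len(apply_annotation_filters(df)) == 1

    @pytest.mark.parametrize("cls", ["synonymous", "intronic"])
    def test_silent_classes_removed(self, cls):
        df = calls_frame([_call(function_class=cls)])
        assert apply_annotation_filters(df).empty

    def test_population_frequency_rule_is_strictly_exclusive(self):
        df = calls_frame(
            [_call(pos=1, pop_af=0.01), _call(pos=2, pop_af=0.0101)]
        )
        out = apply_annotation_filters(df)
        assert list(out["pos"]) == [1]  # exactly 1% retained, above removed

    def test_unknown_function_class_rejected(self):
        df = calls_frame([_call(function_class="weird")])
        with pytest.raises(ValueError, match="weird"):
            apply_annotation_filters(df)


class TestConcordanceFilter:
    def _reps(self, afs, sample="S1"):
        return calls_frame(
            [
                _call(sample_id=sample, replicate_id=f"r{i + 1}", af=af)
                for i, af in enumerate(afs)
            ]
        )

    def test_passes_with_one_replicate_above_5pct(self):
        pooled = calls_frame([_call(af=0.25)])
        out = apply_concordance_filter(pooled, self._reps([0.06, 0.0]))
        assert len(out) == 1

    def test_exactly_5pct_is_rejected(self):
        pooled = calls_frame([_call(af=0.25)])
        out = apply_concordance_filter(pooled, self._reps([0.05, 0.04]))
        assert out.empty

    def test_pooled_run_does_not_count_as_its_own_replicate(self):
        pooled = calls_frame([_call(af=0.25)])
        reps = calls_frame([_call(replicate_id="pooled", af=0.25),
                            _call(replicate_id="r1", af=0.0, pos=999)])
        out = apply_concordance_filter(pooled, reps)
        assert out.empty

    def test_sample_without_replicates_errors_naming_sample(self):
        pooled = calls_frame([_call(sample_id="S9")])
        with pytest.raises(ValueError, match="S9"):
            apply_concordance_filter(pooled, self._reps([0.3, 0.3], sample="S1"))

    def test_matches_brute_force_rule_on_simulation(self, small_variant_sim):
        _, reps, pooled, _ = small_variant_sim
        out = apply_concordance_filter(pooled, reps)
        rep_lookup = {}
        for r in reps.itertuples():
            key = (r.sample_id, r.chrom, r.pos, r.ref, r.alt)
            rep_lookup.setdefault(key, []).append(r.af)
        expected_idx = [
            i
            for i, r in zip(pooled.index, pooled.itertuples())
            if any(
                af > 0.05
                for af in rep_lookup.get(
                    (r.sample_id, r.chrom, r.pos, r.ref, r.alt), []
                )
            )
        ]
        assert list(out.index) == expected_idx


class TestPipelineProperties:
    def test_threshold_and_annotation_filters_commute(self, small_variant_sim):
        _, _, pooled, _ = small_variant_sim
        ab = apply_annotation_filters(apply_call_thresholds(pooled))
        ba = apply_call_thresholds(apply_annotation_filters(pooled))
        assert ab.sort_index().equals(ba.sort_index())

    def test_stage_counts_monotone_and_match_brute_force(self, small_variant_sim):
        _, reps, pooled, _ = small_variant_sim
        retained, report = run_filter_pipeline(pooled, reps)
        counts = list(report.stage_counts.values())
        assert counts == sorted(counts, reverse=True)

        rep_lookup = {}
        for r in reps.itertuples():
            key = (r.sample_id, r.chrom, r.pos, r.ref, r.alt)
            rep_lookup.setdefault(key, []).append(r.af)

        def keep(r):
            return (
                r.qual >= 30
                and r.mapq >= 30
                and r.af >= 0.20
                and r.function_class not in ("synonymous", "intronic")
                and not (not pd.isna(r.pop_af) and r.pop_af > 0.01)
                and any(
                    af > 0.05
                    for af in rep_lookup.get(
                        (r.sample_id, r.chrom, r.pos, r.ref, r.alt), []
                    )
                )
            )

        expected_idx = [
            i for i, r in zip(pooled.index, pooled.itertuples()) if keep(r)
        ]
        assert list(retained.index) == expected_idx

    def test_sensitivity_is_one_on_construction(self, small_variant_sim):
        _, reps, pooled, truth = small_variant_sim
        retained, report = run_filter_pipeline(pooled, reps)
        perf = evaluate_filter_performance(retained, truth, report.stage_counts)
        assert perf.sensitivity == 1.0


class TestPerformanceReport:
    def test_perfect_filter_scores_one_one(self):
        truth = pd.DataFrame(
            {
                "sample_id": ["S1", "S1"],
                "chrom": ["chr7", "chr7"],
                "pos": [1, 2],
                "ref": ["G", "C"],
                "alt": ["A", "T"],
                "label": ["true", "artifact"],
            }
        )
        retained = calls_frame([_call(pos=1)])
        perf = evaluate_filter_performance(retained, truth)
        assert (perf.sensitivity, perf.specificity) == (1.0, 1.0)

    def test_no_true_variants_leaves_sensitivity_undefined(self):
        truth = pd.DataFrame(
            {
                "sample_id": ["S1"], "chrom": ["chr7"], "pos": [2],
                "ref": ["C"], "alt": ["T"], "label": ["artifact"],
            }
        )
        perf = evaluate_filter_performance(calls_frame([]).iloc[0:0], truth)
        assert perf.sensitivity is None
        assert not perf.sensitivity_defined
        assert perf.specificity == 1.0

    def test_retained_variant_absent_from_truth_errors(self):
        truth = pd.DataFrame(
            {
                "sample_id": ["S1"], "chrom": ["chr7"], "pos": [2],
                "ref": ["C"], "alt": ["T"], "label": ["artifact"],
            }
        )
        with pytest.raises(ValueError, match="absent from the truth table"):
            evaluate_filter_performance(calls_frame([_call(pos=1)]), truth)


class TestMutationSummary:
    def test_packaged_table_reproduces_printed_percentages(self):
        t1 = load_table1_fixture()
        s = summarize_mutation_table(t1, cohort_size=57)
        assert s["n_mutations"] == 13
        assert s["n_patients"] == 10
        assert s["patient_fraction_pct"] == 18
        assert s["gene_fraction_pct"]["MLL3"] == 85
        assert s["function_class_fraction_pct"]["nonsynonymous"] == 69

    def test_empty_records_give_zero_counts(self):
        empty = load_table1_fixture().iloc[0:0]
        s = summarize_mutation_table(empty, cohort_size=57)
        assert s["n_mutations"] == 0
        assert s["n_patients"] == 0
        assert s["gene_counts"] == {}

    def test_duplicating_a_sample_under_new_id_adds_one_patient(self):
        t1 = load_table1_fixture()
        extra = t1.iloc[[0]].assign(sample_id="99")
        s = summarize_mutation_table(pd.concat([t1, extra]), cohort_size=57)
        assert s["n_patients"] == 11
        assert s["n_mutations"] == 14

    def test_cohort_smaller_than_patient_count_errors(self):
        with pytest.raises(ValueError, match="cohort size"):
            summarize_mutation_table(load_table1_fixture(), cohort_size=5)


class TestRecordsFromCalls:
    def test_deduplicates_on_sample_and_variant(self):
        df = calls_frame([_call(), _call()])
        rec = records_from_calls(df)
        assert len(rec) == 1
        assert list(rec.columns[:4]) == ["sample_id", "gene", "function_class", "chrom"]

    def test_rejects_unfiltered_silent_calls(self):
        df = calls_frame([_call(function_class="synonymous")])
        with pytest.raises(ValueError, match="synonymous"):
            records_from_calls(df)
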