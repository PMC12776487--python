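"""Filter cascade: stage predicates, funnel assembly, monotonicity."""

from __future__ import annotations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from trioprio.cascade import (
    CascadeConfig,
    StageResult,
    consensus_vote,
    consequence_filter,
    lof_gate,
    rarity_filter,
    run_cascade,
    splice_gate,
)
from trioprio.errors import ConfigError, UsageError
from trioprio.types import PREDICTOR_TOOLS, AnnotationPanel, Consequence, Verdict

from conftest import make_panel, make_variant

CFG = CascadeConfig()


class TestConsequenceFilter:
    @pytest.mark.parametrize(
        "consequence,expected",
        [
            (Consequence.missense, True),
            (Consequence.frameshift, True),
            (Consequence.stop_gained, True),
            (Consequence.stop_lost, True),
            (Consequence.start_gained, True),
            (Consequence.start_lost, True),
            (Consequence.splice_region, True),
            (Consequence.synonymous, False),
            (Consequence.inframe_indel, False),
            (Consequence.other, False),
        ],
    )
    def test_protein_altering_classes_pass(self, consequence, expected):
        assert consequence_filter(make_variant(consequence=consequence)) is expected


class TestRarityFilter:
    @pytest.mark.parametrize(
        "mafs,expected",
        [
            ({"KG1000": 0.004, "ESP": 0.0, "GNOMAD": None}, True),
            ({"KG1000": 0.009, "ESP": 0.02, "GNOMAD": 0.001}, False),
            ({}, True),  # novel: absent from every database
            ({"GNOMAD": 0.01}, False),  # boundary: strict inequality
            ({"GNOMAD": 0.009999}, True),
        ],
    )
    def test_max_over_present_sources_strictly_below_threshold(self, mafs, expected):
        assert rarity_filter(make_panel(mafs=mafs), CFG) is expected

    def test_observed_zero_is_distinct_from_missing_and_passes(self):
        assert rarity_filter(make_panel(mafs={"KG1000": 0.0}), CFG)


class TestConsensusVote:
    @pytest.mark.parametrize(
        "votes,expected",
        [(11, True), (7, True), (6, True), (5, False), (0, False)],
    )
    def test_majority_threshold(self, votes, expected):
        passed, support = consensus_vote(make_panel(votes=votes), CFG)
        assert passed is expected
        assert support == votes

    def test_missing_verdicts_count_toward_denominator_only(self):
        # 6 pathogenic, 5 missing: still passes; 5 pathogenic, 6 missing: fails
        def panel(n):
            verdicts = {
                t: Verdict.pathogenic if i < n else Verdict.missing
                for i, t in enumerate(PREDICTOR_TOOLS)
            }
            return AnnotationPanel(predictor_verdicts=verdicts)

        assert consensus_vote(panel(6), CFG) == (True, 6)
        assert consensus_vote(panel(5), CFG) == (False, 5)

    def test_non_missense_usage_rejected(self):
        with pytest.raises(UsageError):
            consensus_vote(make_panel(votes=7), CFG, Consequence.stop_gained)

    @given(st.lists(st.sampled_from(list(Verdict)), min_size=11, max_size=11))
    def test_vote_count_matches_brute_force(self, verdict_list):
        panel = AnnotationPanel(
            predictor_verdicts=dict(zip(PREDICTOR_TOOLS, verdict_list))
        )
        _, support = consensus_vote(panel, CFG)
        assert support == sum(1 for v in verdict_list if v is Verdict.pathogenic)


class TestClassGates:
    @pytest.mark.parametrize(
        "cadd,expected", [(35.0, True), (20.0, True), (12.0, False), (None, False)]
    )
    def test_cadd_gate(self, cadd, expected):
        assert lof_gate(make_panel(cadd=cadd), CFG) is expected

    @pytest.mark.parametrize(
        "delta,expected", [(0.8, True), (0.5, True), (0.1, False), (None, False)]
    )
    def test_splice_gate(self, delta, expected):
        assert splice_gate(make_panel(splice=delta), CFG) is expected

    def test_wrong_class_usage_rejected(self):
        with pytest.raises(UsageError):
            lof_gate(make_panel(cadd=30.0), CFG, Consequence.missense)
        with pytest.raises(UsageError):
            splice_gate(make_panel(splice=0.9), CFG, Consequence.missense)


def _six_variant_fixture():
    return [
        make_variant(consequence="synonymous", votes=None, gene="G1"),
        make_variant(votes=9, mafs={"GNOMAD": 0.08}, gene="G2"),  # common missense
        make_variant(votes=7, mafs={"GNOMAD": 0.001}, gene="G3"),  # rare, 7/11
        make_variant(votes=4, mafs={"GNOMAD": 0.001}, gene="G4"),  # rare, 4/11
        make_variant(consequence="frameshift", votes=None, gene="G5", dbsnp_id="NOVEL"),
        make_variant(consequence="stop_gained", votes=None, cadd=35.0,
                     mafs={"GNOMAD": 0.0004}, gene="G6"),
    ]


class TestRunCascade:
    def test_hand_built_fixture_keeps_three_survivors(self):
        report = run_cascade(_six_variant_fixture(), CFG)
        assert report.input_count == 6
        assert report.survivors["panel_tier"] == 3
        assert {d.gene for d in report.final_survivors} == {"G3", "G5", "G6"}

    def test_table1_fixture_fully_survives(self, table1):
        variants, _ = table1
        report = run_cascade(variants, CFG)
        assert report.survivors["panel_tier"] == 14

    def test_threshold_exceeding_panel_size_fails_all_missense(self):
        cfg = CascadeConfig(consensus_min=12)
        report = run_cascade(_six_variant_fixture(), cfg)
        assert all(
            not d.final
            for d, v in zip(report.decisions, _six_variant_fixture())
            if v.consequence is Consequence.missense
        )

    def test_empty_input_yields_empty_report(self):
        report = run_cascade([], CFG)
        assert report.input_count == 0 and report.decisions == []

    def test_trace_complete_and_counts_recomputable(self):
        report = run_cascade(_six_variant_fixture(), CFG)
        assert len(report.decisions) == report.input_count
        recomputed = sum(1 for d in report.decisions if d.final)
        assert recomputed == report.survivors["panel_tier"]
        for fid, counts in report.by_family.items():
            fam_final = [d for d in report.decisions if d.family_id == fid and d.final]
            assert counts["panel_tier"] == len(fam_final)

    def test_panel_tier_annotates_but_never_discards(self):
        cfg = CascadeConfig(panel_genes=frozenset({"G3"}))
        report = run_cascade(_six_variant_fixture(), cfg)
        tiers = {d.gene: d.tier for d in report.final_survivors}
        assert tiers["G3"] == "known_phenotype_gene"
        assert tiers["G5"] == "other"
        assert report.survivors["panel_tier"] == 3  # same survivors as untier'd run

    def test_decision_final_iff_no_stage_failed(self):
        for d in run_cascade(_six_variant_fixture(), CFG).decisions:
            assert d.final == all(r is not StageResult.failed for r in d.stages.values())


class TestMonotonicity:
    @given(
        maf_lo=st.floats(0.001, 0.05),
        maf_hi=st.floats(0.05, 0.5),
        consensus_lo=st.integers(1, 6),
        consensus_hi=st.integers(6, 11),
    )
    def test_relaxing_thresholds_never_loses_survivors(
        self, maf_lo, maf_hi, consensus_lo, consensus_hi
    ):
        variants = _six_variant_fixture()
        strict = run_cascade(variants, CascadeConfig(maf_threshold=maf_lo,
                                                     consensus_min=consensus_hi))
        loose = run_cascade(variants, CascadeConfig(maf_threshold=maf_hi,
                                                    consensus_min=consensus_lo))
        assert strict.survivors["panel_tier"] <= loose.survivors["panel_tier"]

    def test_funnel_counts_non_increasing(self):
        report = run_cascade(_six_variant_fixture(), CFG)
        counts = [report.input_count] + list(report.survivors.values())
        assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_invalid_config_rejected():
    with pytest.raises(ConfigError):
        CascadeConfig(maf_threshold=0.0)
    with pytest.raises(ConfigError):
        CascadeConfig(consensus_min=-1)
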