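"""Consensus voting, the quality cascade and the functional filter."""

import pytest
from hypothesis import given, settings, strategies as st

from enoc_strat.calling_filters import (
    apply_functional_filter,
    apply_quality_filters,
    classify_mmr_status,
    consensus_filter,
    removal_report,
)
from enoc_strat.io_model import ClinVar, Consequence, MmrStatus, PolyPhen, Sift


class TestConsensusFilter:
    def test_majority_vote_retains_two_of_three(self):
        calls = {("1", 100, "C", "T"): {"A", "B"}}
        assert consensus_filter(calls, min_callers=2) == {("1", 100, "C", "T")}

    def test_single_caller_dropped(self):
        calls = {("1", 100, "C", "T"): {"A"}, ("1", 200, "G", "A"): {"A", "B"}}
        assert consensus_filter(calls, 2) == {("1", 200, "G", "A")}

    def test_full_support_is_identity(self):
        calls = {(str(i), i, "C", "T"): {"A", "B", "C"} for i in range(1, 6)}
        assert consensus_filter(calls, 2) == set(calls)

    def test_min_callers_above_caller_count_errors(self):
        with pytest.raises(ValueError):
            consensus_filter({("1", 1, "C", "T"): {"A"}}, min_callers=2)

    @given(
        support=st.dictionaries(
            st.tuples(st.just("1"), st.integers(1, 50), st.just("C"), st.just("T")),
            st.sets(st.sampled_from(["A", "B", "C"]), min_size=1),
            max_size=20,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_set_algebra_equivalence(self, support):
        """min=1 is the union of call sets; min=n_callers the intersection."""
        assert consensus_filter(support, 1) == set(support)
        n = len({c for cs in support.values() for c in cs}) if support else 1
        expect = {k for k, cs in support.items() if len(cs) == n or cs >= set("ABC")}
        intersection = {k for k, cs in support.items() if len(cs) >= n}
        assert consensus_filter(support, max(n, 1)) == intersection


class TestQualityFilters:
    def test_low_depth_removed_with_reason(self, call_factory):
        v = call_factory(depth=19, alt_depth=9)
        kept, removed = apply_quality_filters([v])
        assert kept == [] and removed[0][1] == "depth"

    def test_low_vaf_removed_with_reason(self, call_factory):
        v = call_factory(depth=100, alt_depth=9)  # vaf 0.09
        kept, removed = apply_quality_filters([v])
        assert removed[0][1] == "vaf"

    def test_vaf_boundary_inclusive(self, call_factory):
        v = call_factory(depth=100, alt_depth=10)  # vaf exactly 0.10
        kept, _ = apply_quality_filters([v])
        assert kept == [v]

    def test_all_passing_is_identity(self, call_factory, rng):
        variants = [
            call_factory(pos=int(p), depth=100, alt_depth=int(a))
            for p, a in zip(rng.integers(1, 10**6, 10), rng.integers(20, 80, 10))
        ]
        kept, removed = apply_quality_filters(variants)
        assert kept == variants and removed == []

    def test_first_failing_reason_accounting_additive(self, call_factory):
        variants = (
            [call_factory(pos=i, depth=10, alt_depth=1) for i in (1, 2)]  # depth
            + [call_factory(pos=3, depth=100, alt_depth=5)]  # vaf
            + [call_factory(pos=4, depth=100, alt_depth=40, population_af=0.2)]
            + [call_factory(pos=i, depth=100, alt_depth=40) for i in (5, 6, 7, 8)]
        )
        kept, removed = apply_quality_filters(variants)
        assert len(kept) == 4
        assert len(kept) + len(removed) == len(variants)
        assert removal_report(removed) == {
            "depth": 2, "vaf": 1, "common": 1, "artifact": 0,
        }

    def test_artifact_flag_removed_last_in_cascade(self, call_factory):
        v = call_factory(depth=10, alt_depth=1, orientation_bias_flag=True)
        _, removed = apply_quality_filters([v])
        assert removed[0][1] == "depth"  # first failing reason wins

    def test_idempotent(self, call_factory):
        variants = [
            call_factory(pos=1, depth=19, alt_depth=5),
            call_factory(pos=2, depth=100, alt_depth=40),
            call_factory(pos=3, depth=100, alt_depth=40, orientation_bias_flag=True),
        ]
        once, _ = apply_quality_filters(variants)
        twice, removed = apply_quality_filters(once)
        assert twice == once and removed == []


class TestFunctionalFilter:
    @pytest.mark.parametrize(
        "consequence,clinvar,polyphen,sift,kept",
        [
            (Consequence.MISSENSE, ClinVar.UNKNOWN, PolyPhen.BENIGN, Sift.TOLERATED, False),
            (Consequence.MISSENSE, ClinVar.PATHOGENIC, PolyPhen.BENIGN, Sift.TOLERATED, True),
            (Consequence.MISSENSE, ClinVar.UNKNOWN, PolyPhen.BENIGN, Sift.MISSING, True),
            (Consequence.MISSENSE, ClinVar.UNKNOWN, PolyPhen.DAMAGING, Sift.TOLERATED, True),
            (Consequence.NONSENSE, ClinVar.UNKNOWN, PolyPhen.MISSING, Sift.MISSING, True),
            (Consequence.NONSENSE, ClinVar.BENIGN, PolyPhen.MISSING, Sift.MISSING, False),
            (Consequence.FRAMESHIFT_INDEL, ClinVar.UNKNOWN, PolyPhen.MISSING, Sift.MISSING, True),
            (Consequence.SPLICE_SITE, ClinVar.UNKNOWN, PolyPhen.MISSING, Sift.MISSING, True),
            (Consequence.SYNONYMOUS, ClinVar.UNKNOWN, PolyPhen.MISSING, Sift.MISSING, False),
            (Consequence.SYNONYMOUS, ClinVar.PATHOGENIC, PolyPhen.MISSING, Sift.MISSING, True),
            (Consequence.OTHER, ClinVar.UNKNOWN, PolyPhen.MISSING, Sift.MISSING, True),
        ],
    )
    def test_rule_table(self, annotated_call, consequence, clinvar, polyphen, sift, kept):
        v = annotated_call(consequence, clinvar, polyphen, sift)
        result = apply_functional_filter([v])
        assert (result == [v]) is kept


class TestMmrStatus:
    def test_high_impact_dominates(self, call_factory):
        variants = [
            call_factory(gene="MSH6", ref="AT", alt="A",
                         consequence=Consequence.FRAMESHIFT_INDEL),
            call_factory(gene="MLH3", consequence=Consequence.MISSENSE),
        ]
        assert classify_mmr_status(variants) is MmrStatus.HIGH_IMPACT

    def test_missense_only(self, call_factory):
        v = call_factory(gene="MSH3", consequence=Consequence.MISSENSE)
        assert classify_mmr_status([v]) is MmrStatus.MISSENSE_ONLY

    def test_wt_when_no_mmr_genes_hit(self, call_factory):
        v = call_factory(gene="TP53", consequence=Consequence.NONSENSE)
        assert classify_mmr_status([v]) is MmrStatus.WT

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            classify_mmr_status([], mmr_genes=frozenset())
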