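"""Filter cascade: per-call/per-variant predicates, trace, consensus, properties."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from exofam.cohort_io import read_vcf_cohort
from exofam.filtering import (
    FilterConfig,
    alt_fraction,
    classify_pathogenicity,
    consensus_across_sources,
    damaging_gate,
    genotype_qc_pass,
    in_fraction_window,
    internal_control_pass,
    rare_in_panels,
    run_cascade,
    run_cascade_consensus,
)
from exofam.model import GT_HET, GT_HOM_ALT, GenotypeCall, VariantRecord

from conftest import (
    FIXTURE_EXPECTED_STAGES,
    FIXTURE_SURVIVOR_POSITIONS,
    random_small_cohort,
)

CFG = FilterConfig()


def call(gt=GT_HET, depth=40, gq=90, ad=None, sample="S1"):
    if ad is None and depth is not None:
        ad = (depth // 2, depth - depth // 2)
    return GenotypeCall(sample, gt, depth, gq, ad)


def record(consequence="missense", panel_freqs=None, predictions=None,
           hgmd=False, internal_af=None):
    return VariantRecord(
        "1", 100, "A", "G", gene="G1", consequence=consequence,
        panel_freqs=panel_freqs or {}, predictions=predictions or {},
        hgmd=hgmd, internal_af=internal_af,
    )


class TestGenotypeQc:
    @pytest.mark.parametrize(
        "depth,gq,expected",
        [
            (14, 50, False),   # depth just below the cut
            (15, 20, True),    # boundary pass: strict '<' removal
            (100, 19, False),  # quality just below the cut
            (None, 90, False),  # missing depth treated as low quality
            (40, None, False),
        ],
    )
    def test_depth_and_quality_boundaries(self, depth, gq, expected):
        assert genotype_qc_pass(call(depth=depth, gq=gq), CFG) is expected


class TestAltFraction:
    @pytest.mark.parametrize(
        "ad,expected_frac,in_window",
        [
            ((30, 10), 0.25, False),
            ((10, 10), 0.50, True),
            ((3, 17), 0.85, True),   # inclusive upper bound
            ((14, 6), 0.30, True),   # inclusive lower bound
            ((2, 18), 0.90, False),
        ],
    )
    def test_window_inclusive_bounds(self, ad, expected_frac, in_window):
        c = call(ad=ad, depth=sum(ad))
        assert alt_fraction(c) == pytest.approx(expected_frac)
        assert in_fraction_window(c, CFG) is in_window

    def test_no_informative_reads_fails_window(self):
        c = call(ad=(0, 0), depth=0)
        assert alt_fraction(c) is None
        assert not in_fraction_window(c, CFG)

    def test_hom_alt_bypasses_window(self):
        c = call(gt=GT_HOM_ALT, ad=(0, 40), depth=40)
        assert in_fraction_window(c, CFG)


class TestRarity:
    def test_rare_in_all_panels(self):
        assert rare_in_panels(record(panel_freqs={"KG": 0.005, "EXAC": 0.002}), CFG)

    def test_common_in_one_required_panel_fails(self):
        assert not rare_in_panels(record(panel_freqs={"KG": 0.02}), CFG)

    def test_absent_everywhere_counts_as_rare(self):
        assert rare_in_panels(record(), CFG)

    def test_any_panel_policy_needs_one_qualifying_panel(self):
        cfg = CFG.with_overrides(panel_policy="any_panel")
        v = record(panel_freqs={"KG": 0.02, "EXAC": 0.005, "ESP": 0.03})
        assert rare_in_panels(v, cfg)
        assert not rare_in_panels(v, CFG)


class TestPathogenicity:
    @pytest.mark.parametrize(
        "consequence,hgmd,category",
        [
            ("stop_gained", False, 2),
            ("frameshift", False, 2),
            ("start_lost", False, 2),
            ("missense", False, 3),
            ("inframe_indel", False, 3),
            ("synonymous", False, None),
            ("missense", True, 1),  # HGMD listing dominates
            ("utr", False, None),
        ],
    )
    def test_category_assignment(self, consequence, hgmd, category):
        assert classify_pathogenicity(record(consequence, hgmd=hgmd)) == category

    def test_unknown_consequence_is_none_not_error(self):
        assert classify_pathogenicity(record("weird_term_xyz")) is None


class TestDamagingGate:
    def test_sift_damaging_alone_suffices(self):
        v = record(predictions={"sift": "damaging", "polyphen": "benign"})
        assert damaging_gate(v, CFG)

    def test_all_benign_missense_fails(self):
        v = record(predictions={"sift": "tolerated", "polyphen": "benign"})
        assert not damaging_gate(v, CFG)

    def test_lof_consequence_passes_without_predictions(self):
        assert damaging_gate(record("frameshift"), CFG)

    def test_possibly_damaging_polyphen_passes(self):
        assert damaging_gate(record(predictions={"polyphen": "possibly_damaging"}), CFG)


class TestInternalControl:
    @pytest.mark.parametrize(
        "iaf,expected", [(0.05, False), (None, True), (0.0, True), (0.02, True)]
    )
    def test_threshold(self, iaf, expected):
        assert internal_control_pass(record(internal_af=iaf), CFG) is expected


class TestCascadeOnFixture:
    def test_stage_survivor_counts_match_hand_enumeration(self, fixture_vcf):
        table = read_vcf_cohort(fixture_vcf)
        filtered, trace = run_cascade(table, CFG)
        assert trace.survivors_by_stage() == FIXTURE_EXPECTED_STAGES
        assert sorted(filtered.table.variants["pos"]) == FIXTURE_SURVIVOR_POSITIONS

    def test_identity_configuration_keeps_everything(self, fixture_vcf):
        table = read_vcf_cohort(fixture_vcf)
        cfg = FilterConfig(
            min_depth=0, min_gq=0, alt_fraction_range=(0.0, 1.0), maf_threshold=1.0,
            internal_af_max=1.0,
        )
        # identity also needs the qualitative gates wide open
        cfg = cfg.with_overrides(
            sift_damaging=frozenset({"damaging", "tolerated"}),
            polyphen_damaging=frozenset({"probably_damaging", "possibly_damaging", "benign"}),
        )
        filtered, trace = run_cascade(table, cfg)
        # only the pathogenicity stage still filters (synonymous is never
        # category 1-3); everything else passes untouched
        assert trace.survivors_by_stage()["rarity"] == trace.n_input
        assert trace.survivors_by_stage()["internal_control"] >= trace.n_input - 1

    def test_empty_table_gives_trace_of_zeros(self, tmp_path):
        p = tmp_path / "empty.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        )
        table = read_vcf_cohort(p)
        filtered, trace = run_cascade(table, CFG)
        assert trace.n_input == 0 and trace.n_survivors == 0
        assert len(filtered.table.variants) == 0

    def test_trace_chains_and_accounts_for_every_variant(self, fixture_vcf):
        table = read_vcf_cohort(fixture_vcf)
        _, trace = run_cascade(table, CFG)
        for prev, nxt in zip(trace.stages, trace.stages[1:]):
            assert prev.n_out == nxt.n_in
        removed = sum(len(s.removed_keys) for s in trace.stages)
        assert removed + trace.n_survivors == trace.n_input


class TestCascadeProperties:
    @given(seed=st.integers(0, 10**6))
    def test_cascade_agrees_with_scalar_predicates(self, seed):
        """The vectorized cascade equals the per-record predicate definitions."""
        table = random_small_cohort(seed)
        filtered, _ = run_cascade(table, CFG)
        survivors = set(filtered.keys)
        expected = set()
        for key in table.keys:
            calls = table.calls(key)
            ok_calls = [
                c for c in calls
                if c.is_carrier and genotype_qc_pass(c, CFG) and in_fraction_window(c, CFG)
            ]
            v = table.record(key)
            if (
                ok_calls
                and rare_in_panels(v, CFG)
                and classify_pathogenicity(v) in (1, 2, 3)
                and damaging_gate(v, CFG)
                and internal_control_pass(v, CFG)
            ):
                expected.add(key)
        assert survivors == expected

    @given(
        seed=st.integers(0, 10**6),
        d_depth=st.integers(0, 20),
        d_gq=st.integers(0, 30),
        shrink=st.floats(0.0, 0.2),
        d_maf=st.floats(0.0, 0.009),
    )
    def test_tightening_thresholds_never_adds_survivors(
        self, seed, d_depth, d_gq, shrink, d_maf
    ):
        table = random_small_cohort(seed)
        loose, _ = run_cascade(table, CFG)
        low, high = CFG.alt_fraction_range
        tight_cfg = CFG.with_overrides(
            min_depth=CFG.min_depth + d_depth,
            min_gq=CFG.min_gq + d_gq,
            alt_fraction_range=(low + shrink, high - shrink),
            maf_threshold=CFG.maf_threshold - d_maf,
        )
        tight, _ = run_cascade(table, tight_cfg)
        assert set(tight.keys) <= set(loose.keys)

    @given(seed=st.integers(0, 10**6))
    def test_survivors_are_order_free_conjunction_of_stage_flags(self, seed):
        """Per-variant stages commute: survivors = per-call pass AND all flags,
        regardless of the order the trace records."""
        table = random_small_cohort(seed)
        filtered, _ = run_cascade(table, CFG)
        from exofam.filtering import _per_call_masks, _variant_pass_flags

        carrier, qc, win = _per_call_masks(table, CFG)
        call_pass = (carrier & qc & win).any(axis=1)
        flags = _variant_pass_flags(table.variants, CFG)
        conj = call_pass.copy()
        for name in ("internal_control", "damaging", "pathogenicity", "rarity"):
            conj &= flags[name]  # reversed relative to the canonical order
        assert set(filtered.keys) == set(np.asarray(table.keys)[conj])


class TestConsensus:
    def test_two_of_three_rule(self):
        sets = {"A": {"v1", "v2"}, "B": {"v1"}, "C": {"v3"}}
        assert consensus_across_sources(sets, 2) == {"v1"}

    def test_single_source_pass_is_dropped(self):
        sets = {"A": {"v1"}, "B": set(), "C": set()}
        assert consensus_across_sources(sets, 2) == set()

    @given(
        sets=st.lists(
            st.sets(st.sampled_from([f"v{i}" for i in range(8)])), min_size=1, max_size=5
        )
    )
    def test_min_one_is_union_and_max_is_intersection(self, sets):
        union = set().union(*sets)
        inter = set.intersection(*sets)
        assert consensus_across_sources(sets, 1) == union
        assert consensus_across_sources(sets, len(sets)) == inter

    @given(
        sets=st.lists(
            st.sets(st.sampled_from([f"v{i}" for i in range(8)])), min_size=2, max_size=5
        )
    )
    def test_consensus_is_antitone_in_min_sources(self, sets):
        prev = None
        for k in range(1, len(sets) + 1):
            cur = consensus_across_sources(sets, k)
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_min_sources_beyond_available_errors(self):
        with pytest.raises(ValueError):
            consensus_across_sources([{"v1"}], 2)


def test_consensus_cascade_uses_attached_sources(fixture_vcf):
    table = read_vcf_cohort(fixture_vcf)
    # three identical sources: consensus result equals single-source cascade
    ann = table.variants[
        ["consequence", "sift", "polyphen", "hgmd", "cadd", "internal_af",
         "af_KG", "af_EXAC", "af_ESP"]
    ]
    for name in ("source_1", "source_2", "source_3"):
        table.annotations[name] = ann.copy()
    single, _ = run_cascade(table, CFG)
    consensus, traces = run_cascade_consensus(table, CFG)
    assert set(consensus.keys) == set(single.keys)
    assert set(traces) == {"source_1", "source_2", "source_3"}
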