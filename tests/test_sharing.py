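"""Dominant-model carrier logic, family/case sharing, cross-cohort overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from exofam.filtering import FilteredCohort
from exofam.model import (
    GT_HEMI_ALT,
    GT_HET,
    GT_HOM_ALT,
    GT_REF,
    CohortTable,
    GenotypeCall,
)
from exofam.sharing import (
    ShareResult,
    cohort_overlap,
    dominant_carriers,
    family_shared_variants,
    gene_case_sharing,
)

from conftest import small_pedigree


def make_filtered(gt_rows, genes, samples):
    """FilteredCohort from explicit genotype rows (all calls pass per-call QC)."""
    n = len(gt_rows)
    keys = [f"1:{100 + i}:A:G" for i in range(n)]
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(100, 100 + n),
            "ref": "A",
            "alt": "G",
            "gene": genes,
        },
        index=pd.Index(keys, name="key"),
    )
    gt = np.array(gt_rows, dtype=np.int32)
    table = CohortTable(variants, samples, gt)
    return FilteredCohort(table=table, carrier_mask=table.carrier_matrix()), keys


class TestDominantCarriers:
    def test_any_alt_bearing_genotype_is_carrier(self):
        calls = [
            GenotypeCall("a", GT_HET),
            GenotypeCall("b", GT_REF),
            GenotypeCall("c", GT_HOM_ALT),
            GenotypeCall("d", GT_HEMI_ALT),  # male X single alt allele
            GenotypeCall("e", -1),
        ]
        assert dominant_carriers(calls) == {"a", "c", "d"}


class TestFamilySharedVariants:
    def test_variant_shared_by_both_sisters_is_kept(self):
        ped = small_pedigree()
        samples = [m.id for fam in ped.families.values() for m in fam]
        rows = []
        # v0: het in both F1 sisters; v1: het in only one; v2: het in all F2 affected
        for pattern in [
            {"F1_D1": GT_HET, "F1_D2": GT_HET},
            {"F1_D1": GT_HET},
            {"F2_MO": GT_HET, "F2_D1": GT_HET, "F2_D2": GT_HET},
        ]:
            rows.append([pattern.get(s, GT_REF) for s in samples])
        filtered, keys = make_filtered(rows, ["GA", "GB", "GC"], samples)

        res1 = family_shared_variants("F1", filtered, ped)
        assert res1.shared_variants == {keys[0]}
        assert res1.shared_genes == {"GA"}
        assert res1.scope == "pair"

        res2 = family_shared_variants("F2", filtered, ped)  # a triad
        assert res2.shared_variants == {keys[2]}
        assert res2.scope == "family"

    def test_family_with_one_genotyped_affected_is_skipped(self):
        ped = small_pedigree()
        samples = ["F1_D1"]  # F1_D2 affected but ungenotyped
        filtered, _ = make_filtered([[GT_HET]], ["GA"], samples)
        assert family_shared_variants("F1", filtered, ped) is None

    def test_ungenotyped_affected_excluded_from_intersection(self):
        ped = small_pedigree()
        samples = ["F2_MO", "F2_D1"]  # F2_D2 affected but not sequenced
        filtered, keys = make_filtered([[GT_HET, GT_HET]], ["GA"], samples)
        res = family_shared_variants("F2", filtered, ped)
        assert res.shared_variants == set(keys)


class TestGeneCaseSharing:
    def _cohort(self):
        ped = small_pedigree()
        samples = [m.id for fam in ped.families.values() for m in fam]
        # gene GA: carriers F1_D1, F1_D2, F2_D1 (two families)
        # gene GB: carriers F1_D1, F1_D2 + F1_MO (one family only)
        # gene GC: one carrier
        rows = [
            {"F1_D1": GT_HET, "F2_D1": GT_HET},          # GA variant 1
            {"F1_D2": GT_HET},                            # GA variant 2
            {"F1_D1": GT_HET, "F1_D2": GT_HET},           # GB variant
            {"F3_D1": GT_HOM_ALT},                        # GC variant
        ]
        gt = [[r.get(s, GT_REF) for s in samples] for r in rows]
        filtered, keys = make_filtered(gt, ["GA", "GA", "GB", "GC"], samples)
        cases = ["F1_D1", "F1_D2", "F2_D1", "F2_D2", "F3_D1"]
        return ped, filtered, cases, keys

    def test_gene_with_three_cases_two_families_is_retained(self):
        ped, filtered, cases, keys = self._cohort()
        res = gene_case_sharing(filtered, cases, ped, min_cases=3, min_families=2)
        assert res.shared_genes == {"GA"}
        carriers, fams = res.per_gene_carriers["GA"]
        assert carriers == {"F1_D1", "F1_D2", "F2_D1"}
        assert fams == {"F1", "F2"}
        assert res.shared_variants == {keys[0], keys[1]}

    def test_single_family_gene_dropped_by_family_requirement(self):
        ped, filtered, cases, _ = self._cohort()
        res = gene_case_sharing(filtered, cases, ped, min_cases=2, min_families=2)
        assert "GB" not in res.shared_genes  # 2 carriers but one family

    def test_no_constraints_keeps_every_carried_gene(self):
        ped, filtered, cases, _ = self._cohort()
        res = gene_case_sharing(filtered, cases, ped, min_cases=1, min_families=1)
        assert res.shared_genes == {"GA", "GB", "GC"}

    @given(
        seed=st.integers(0, 10**5),
        mc=st.integers(1, 5),
        mf=st.integers(1, 3),
    )
    def test_antitone_in_min_cases_and_min_families(self, seed, mc, mf):
        ped = small_pedigree()
        samples = [m.id for fam in ped.families.values() for m in fam]
        rng = np.random.default_rng(seed)
        gt = rng.choice([GT_REF, GT_HET], (15, len(samples)), p=[0.6, 0.4])
        genes = [f"G{int(g)}" for g in rng.integers(0, 5, 15)]
        filtered, _ = make_filtered(gt.tolist(), genes, samples)
        cases = [s for s in samples if ped.individuals[s].affected]
        base = gene_case_sharing(filtered, cases, ped, mc, mf)
        tighter_cases = gene_case_sharing(filtered, cases, ped, mc + 1, mf)
        tighter_fams = gene_case_sharing(filtered, cases, ped, mc, mf + 1)
        assert tighter_cases.shared_genes <= base.shared_genes
        assert tighter_fams.shared_genes <= base.shared_genes

    def test_adding_unrelated_unaffected_sample_changes_nothing(self):
        ped, filtered, cases, _ = self._cohort()
        before = gene_case_sharing(filtered, cases, ped, 3, 2)
        # append an unrelated sample carrying everything
        table = filtered.table
        gt = np.hstack([table.gt, np.full((len(table.variants), 1), GT_HET, np.int32)])
        bigger = CohortTable(table.variants, table.samples + ["LONER"], gt)
        filtered2 = FilteredCohort(table=bigger, carrier_mask=bigger.carrier_matrix())
        after = gene_case_sharing(filtered2, cases, ped, 3, 2)
        assert after.shared_genes == before.shared_genes
        assert after.per_gene_carriers == before.per_gene_carriers

    def test_unknown_case_id_is_an_error(self):
        ped, filtered, _, _ = self._cohort()
        with pytest.raises(ValueError, match="not genotyped"):
            gene_case_sharing(filtered, ["GHOST"], ped, 1, 1)


class TestCohortOverlap:
    def _result(self, genes, variants):
        return ShareResult("cohort", frozenset(variants), frozenset(genes))

    def test_intersection_semantics(self):
        a = self._result({"g1", "g2"}, {"v1"})
        b = self._result({"g2", "g3"}, {"v2"})
        genes, variants = cohort_overlap(a, b)
        assert genes == {"g2"} and variants == set()

    def test_identical_inputs_overlap_fully(self):
        a = self._result({"g1"}, {"v1"})
        genes, variants = cohort_overlap(a, a)
        assert genes == {"g1"} and variants == {"v1"}

    def test_same_gene_different_variants_overlaps_at_gene_level_only(self):
        a = self._result({"g1"}, {"1:100:A:G"})
        b = self._result({"g1"}, {"1:200:C:T"})
        genes, variants = cohort_overlap(a, b)
        assert genes == {"g1"}
        assert variants == set()

    def test_per_family_mappings_are_pooled(self):
        a = {
            "F1": self._result({"g1"}, {"v1"}),
            "F2": self._result({"g2"}, {"v2"}),
        }
        b = self._result({"g2"}, {"v2", "v3"})
        genes, variants = cohort_overlap(a, b)
        assert genes == {"g2"} and variants == {"v2"}


def test_family_share_is_subset_of_each_member_carrier_set():
    ped = small_pedigree()
    samples = [m.id for fam in ped.families.values() for m in fam]
    rng = np.random.default_rng(7)
    gt = rng.choice([GT_REF, GT_HET, GT_HOM_ALT], (30, len(samples)), p=[0.5, 0.35, 0.15])
    filtered, _ = make_filtered(gt.tolist(), ["G1"] * 30, samples)
    for fam in ped.families:
        res = family_shared_variants(fam, filtered, ped)
        if res is None:
            continue
        for member in ped.affected(fam):
            if member not in samples:
                continue
            j = filtered.table.sample_index(member)
            carried = set(filtered.table.keys[filtered.carrier_mask[:, j]])
            assert res.shared_variants <= carried
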