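"""Synthetic cohort generator: determinism, Mendelian consistency, truth recovery."""

import numpy as np
import pytest

from exofam.cohort_io import read_pedigree, read_vcf_cohort, write_pedigree
from exofam.filtering import FilterConfig, run_cascade, run_cascade_consensus
from exofam.model import GT_HEMI_ALT, GT_HET, GT_HOM_ALT, GT_MISSING, GT_REF
from exofam.sharing import family_shared_variants
from exofam.synthetic import (
    NoiseConfig,
    PlantSpec,
    build_gene_map,
    default_pathways,
    generate_pedigrees,
    simulate_cohort,
)

GENE_MAP = build_gene_map()
PATHWAYS = default_pathways(GENE_MAP)


@pytest.fixture(scope="module")
def quiet_sim():
    ped = generate_pedigrees(n_families=5, seed=11)
    return simulate_cohort(
        ped, n_background_variants=4000, noise=NoiseConfig.none(), seed=11,
        gene_map=GENE_MAP, pathways=PATHWAYS,
    )


@pytest.fixture(scope="module")
def noisy_sim():
    ped = generate_pedigrees(n_families=5, seed=13)
    return simulate_cohort(
        ped, n_background_variants=4000, seed=13, gene_map=GENE_MAP, pathways=PATHWAYS
    )


class TestPedigrees:
    def test_multiplex_families_have_requested_affected_females(self):
        ped = generate_pedigrees(n_families=7, affected_per_family_range=(2, 4), seed=3)
        assert len(ped.families) == 7
        for fam in ped.families:
            affected = ped.affected(fam)
            assert 2 <= len(affected) <= 4
            assert all(ped.individuals[a].is_female for a in affected)

    def test_sisters_mode_emits_pairs_with_shared_parents(self):
        ped = generate_pedigrees(
            n_families=93, affected_per_family_range=(2, 2), sisters_mode=True, seed=4
        )
        assert len(ped.families) == 93
        for fam in ped.families:
            sisters = ped.affected(fam)
            assert len(sisters) == 2
            parents = {
                (ped.individuals[s].father, ped.individuals[s].mother) for s in sisters
            }
            assert len(parents) == 1  # a true sister pair

    def test_same_seed_gives_byte_identical_ped(self, tmp_path):
        for i, name in enumerate(("a.ped", "b.ped")):
            write_pedigree(generate_pedigrees(n_families=4, seed=9), tmp_path / name)
        assert (tmp_path / "a.ped").read_bytes() == (tmp_path / "b.ped").read_bytes()

    def test_pedigree_round_trips_through_ped_file(self, tmp_path):
        ped = generate_pedigrees(n_families=3, seed=2)
        write_pedigree(ped, tmp_path / "fam.ped")
        back = read_pedigree(tmp_path / "fam.ped")
        assert set(back.individuals) == set(ped.individuals)
        for fam in ped.families:
            assert back.affected(fam) == ped.affected(fam)


class TestSimulationStructure:
    def test_deterministic_given_seed(self):
        ped = generate_pedigrees(n_families=3, seed=5)
        a = simulate_cohort(ped, 2000, seed=5, gene_map=GENE_MAP, pathways=PATHWAYS)
        b = simulate_cohort(ped, 2000, seed=5, gene_map=GENE_MAP, pathways=PATHWAYS)
        assert list(a.table.keys) == list(b.table.keys)
        assert np.array_equal(a.table.gt, b.table.gt)
        assert a.truth.planted == b.truth.planted

    def test_mendelian_consistency_in_every_trio(self, noisy_sim):
        table = noisy_sim.table
        ped = noisy_sim.pedigree
        is_x = (table.variants["chrom"] == "X").to_numpy()
        for child in ped.individuals.values():
            if child.father is None:
                continue
            c = table.gt[:, table.sample_index(child.id)]
            m = table.gt[:, table.sample_index(child.mother)]
            f = table.gt[:, table.sample_index(child.father)]

            def alleles(g, male_x):
                # (min, max) transmissible alternate-allele dose per parent
                lo = np.where((g == GT_HOM_ALT) | (g == GT_HEMI_ALT), 1, 0)
                hi = np.where(g >= GT_HET, 1, 0)
                return lo, hi

            m_lo, m_hi = alleles(m, False)
            f_lo, f_hi = alleles(f, True)
            if child.sex == 1:
                # sons: X comes from the mother only
                dose = np.where(c == GT_HEMI_ALT, 1, np.where(c == GT_HET, 1, np.where(c == GT_HOM_ALT, 2, 0)))
                lo = np.where(is_x, m_lo, m_lo + f_lo)
                hi = np.where(is_x, m_hi, m_hi + f_hi)
            else:
                dose = np.where(c == GT_HET, 1, np.where(c == GT_HOM_ALT, 2, 0))
                lo = m_lo + f_lo
                hi = m_hi + f_hi
            called = c != GT_MISSING
            assert np.all(dose[called] >= lo[called])
            assert np.all(dose[called] <= hi[called])

    def test_males_are_hemizygous_on_x(self, noisy_sim):
        table = noisy_sim.table
        is_x = (table.variants["chrom"] == "X").to_numpy()
        assert is_x.any()
        for ind in noisy_sim.pedigree.individuals.values():
            g = table.gt[:, table.sample_index(ind.id)]
            if ind.sex == 1:
                assert not np.isin(g[is_x], [GT_HET, GT_HOM_ALT]).any()
            else:
                assert not (g[is_x] == GT_HEMI_ALT).any()

    def test_planted_request_exceeding_pathway_errors(self):
        ped = generate_pedigrees(n_families=3, seed=1)
        with pytest.raises(ValueError, match="holds"):
            simulate_cohort(
                ped, 500, plant=PlantSpec(n_planted_genes=21), seed=1,
                gene_map=GENE_MAP, pathways=PATHWAYS,
            )

    def test_frequency_spectrum_has_rare_and_common_mass(self, noisy_sim):
        af = noisy_sim.table.variants["af_KG"].dropna()
        assert (af < 0.01).mean() > 0.15
        assert (af > 0.05).mean() > 0.30


class TestRoundTrip:
    def test_vcf_round_trip_reproduces_cohort(self, tmp_path, quiet_sim):
        paths = quiet_sim.write_all(tmp_path)
        back = read_vcf_cohort(paths["vcf"])
        table = quiet_sim.table
        assert list(back.keys) == list(table.keys)
        assert back.samples == table.samples
        assert np.array_equal(back.gt, table.gt)
        assert np.array_equal(back.dp, table.dp)
        assert np.array_equal(back.gq, table.gq)
        assert np.array_equal(back.ad_ref, table.ad_ref)
        assert np.array_equal(back.ad_alt, table.ad_alt)
        for col in ("gene", "consequence"):
            assert list(back.variants[col]) == list(table.variants[col])
        for col in ("af_KG", "af_EXAC", "af_ESP", "cadd", "internal_af"):
            np.testing.assert_allclose(
                back.variants[col].astype(float),
                table.variants[col].astype(float),
                rtol=1e-5, equal_nan=True,
            )

    def test_sidecar_round_trip_matches_source_frames(self, tmp_path, quiet_sim):
        from exofam.cohort_io import attach_annotation_source

        paths = quiet_sim.write_all(tmp_path)
        back = read_vcf_cohort(paths["vcf"])
        attach_annotation_source(back, "source_2", paths["sidecar_source_2"])
        orig = quiet_sim.table.annotations["source_2"]
        got = back.annotations["source_2"]
        assert list(got["consequence"]) == list(orig["consequence"])
        np.testing.assert_allclose(
            got["af_KG"].astype(float), orig["af_KG"].astype(float),
            rtol=1e-5, equal_nan=True,
        )


class TestTruthRecovery:
    def test_no_noise_cascade_keeps_every_planted_variant(self, quiet_sim):
        filtered, _ = run_cascade(quiet_sim.table, FilterConfig())
        survivors = set(filtered.keys)
        assert set(quiet_sim.truth.planted) <= survivors

    def test_no_noise_family_sharing_recovers_planted_sets_exactly(self, quiet_sim):
        filtered, _ = run_cascade(quiet_sim.table, FilterConfig())
        by_family = quiet_sim.truth.planted_by_family()
        for fam, planted_keys in by_family.items():
            res = family_shared_variants(fam, filtered, quiet_sim.pedigree)
            planted_shared = res.shared_variants & set(quiet_sim.truth.planted)
            assert planted_shared == planted_keys

    def test_planted_variants_pass_rarity_threshold(self, quiet_sim):
        v = quiet_sim.table.variants
        planted = v.loc[list(quiet_sim.truth.planted)]
        assert (planted[["af_KG", "af_EXAC", "af_ESP"]] < 0.01).all().all()

    def test_zero_discordance_makes_consensus_equal_single_source(self, quiet_sim):
        cfg = FilterConfig()
        single, _ = run_cascade(quiet_sim.table, cfg, annotation_source="source_1")
        consensus, _ = run_cascade_consensus(quiet_sim.table, cfg)
        assert set(consensus.keys) == set(single.keys)

    def test_artifact_calls_fail_their_intended_stage(self, noisy_sim):
        from exofam.filtering import genotype_qc_pass, in_fraction_window

        cfg = FilterConfig()
        table = noisy_sim.table
        checked = 0
        for art in noisy_sim.truth.artifact_calls[:200]:
            call = table.call(art["key"], art["sample"])
            if art["stage"] == "genotype_qc":
                assert not genotype_qc_pass(call, cfg)
            elif art["stage"] == "alt_fraction" and call.gt == GT_HET:
                assert not in_fraction_window(call, cfg)
            checked += 1
        assert checked > 0

    def test_internal_artifacts_marked_and_filtered(self, noisy_sim):
        v = noisy_sim.table.variants
        for key in list(noisy_sim.truth.artifact_variants)[:50]:
            assert v.loc[key, "internal_af"] > FilterConfig().internal_af_max
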