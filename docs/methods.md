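# Methods

This note documents the models, defaults and design choices behind
`exofam`, and what its synthetic benchmarks do and do not demonstrate.

## Variant representation

All records are keyed by a normalized `chrom:pos:ref:alt` after
splitting multi-allelic sites (one record per alternate allele;
genotypes recoded against that allele, other alternates counting as
reference) and trimming shared allele sequence (right-trim the common
suffix, then left-trim the common prefix while advancing `pos`).
Trimming is idempotent and sufficient to reconcile the same variant
across annotation exports; it is not full left-alignment of indels in
repeat tracts, which would require the reference genome and is out of
scope. Gene symbols are matched case-insensitively with no alias
resolution, keeping matching deterministic.

Genotypes are coded ref / het / hom-alt / hemizygous-alt / missing.
Haploid calls (male X) read as hemizygous; a hemizygous alternate
allele counts as carrier status under the dominant model.

## Filter cascade

Stages run in a canonical order — genotype QC, alt-allele fraction,
rarity, pathogenicity, damaging evidence, internal control — though the
per-variant stages commute (a property the tests assert). Defaults,
with rationale:

| parameter | default | meaning |
|---|---|---|
| `min_depth` | 15 reads | calls below are removed (strict `<` removal, so 15 passes) |
| `min_gq` | 20 (phred) | genotype-quality floor, same boundary convention |
| `alt_fraction_range` | [0.30, 0.85] | het-call sanity window on alt/(alt+ref), inclusive at both bounds; hom-alt and hemizygous calls bypass it |
| `maf_threshold` | 0.01 | "rare" means frequency < 1% or absent |
| `panel_policy` | `all_panels` | the variant must qualify in *every* required panel; the any-panel reading is configurable |
| `required_panels` | KG, EXAC, ESP | per-cohort panel lists (e.g. a national reference panel for one population, a continental one for another) are supported via config |
| `internal_af_max` | 0.02 | "relatively high frequency in the internal control" cut; the exact value is a judgment call, so it is exposed in config and logged in every trace |
| `min_consensus_sources` | 2 | a variant is valid when ≥ 2 annotation sources reproduce its pass |

Decisions worth stating explicitly:

* **Missing DP or GQ fails QC.** Missingness is indistinguishable from
  low quality; the conservative choice is removal.
* **The fraction window applies to heterozygous calls only.** It is a
  het-call plausibility check; applying it to hom-alt calls would
  discard valid genotypes whose fraction is near 1.
* **Inclusive window bounds.** "Range 0.3–0.85" is read as a closed
  interval; boundary fixtures (0.30 and 0.85 exactly) pin the choice.
* **Pathogenicity categories.** 1 = listed in a disease-mutation
  database; 2 = loss-of-function-type consequences (start/stop loss,
  premature stop, frameshift, splice donor/acceptor, whole-gene
  deletion); 3 = missense, in-frame indel, splice-region context. Only
  categories 1–3 pass. Unknown consequence terms map to no category
  with a logged warning rather than an error.
* **Per-call vs per-variant failures.** A failed call removes the
  variant from that sample's carrier set; the variant leaves the table
  globally only when no passing alt-bearing call remains (which also
  covers sites monomorphic in the cohort, reported at the QC stage).
* **"Call quality" is read as FORMAT/GQ.** Annotation tools name this
  field inconsistently; both common readings apply the same threshold,
  and site-level QUAL is not used.

The trace records (stage, n in, n out, removed keys, reason histogram)
and is emitted as TSV and JSON; the invariant `removals + survivors =
input` is enforced.

## Sharing analyses

"Cases" for the case-group analysis are an explicit, reproducible
sample list; `select_cases` picks genotyped affected individuals
round-robin across families so every family is represented before any
contributes twice. Compound heterozygosity is not specially modelled —
each heterozygous variant counts independently under the dominant
bundle. Ungenotyped affected members are excluded from the family
intersection (logged) rather than failing the family; families with
fewer than two genotyped affected members are skipped. Family
membership for the multi-family requirement is the family id of record.

## Enrichment

The test is one-sided (over-representation only). The upper-tail
hypergeometric probability is computed with exact integer suffix sums
(`math.comb`), cached per (N, m, n); no normal approximation anywhere.
Ties in p are broken by pathway name; non-significant pathways are
retained in output but flagged.

The **universe** is the main knob when comparing against results from
closed-source pathway tools, whose universes are not published. Default:
all genes with ≥ 1 variant call surviving the genotype-level stages in
the cohort; union-of-sets or an explicit file are alternatives, and the
choice is logged. No multiple-testing correction is applied by default
(the reporting rule thresholds raw p at 0.01); Benjamini–Hochberg
q-values are available as an explicit extra.

Cross-family aggregation counts families with p < α and reports the
mean and median p **over the significant families** (matching how pooled
family tables are usually presented); pooling all families is a config
switch (`aggregation_mode: all_families`) since published tables rarely
state which convention they use. Rank is dense on (family count
descending, median p ascending).

## Summary-statistic inference

When only printed group summaries (mean ± SEM, n) are available, the
two-group comparison is Welch's t from summaries: `t = Δmean /
sqrt(SEM_a² + SEM_b²)` with Welch–Satterthwaite degrees of freedom on
the squared SEMs. This is deliberately *not* a reconstruction of a
three-group ANOVA with post-hoc testing — raw replicates are not
assumed available — so agreement with published pairwise p-values is
claimed only as a consistency bound (the Welch p should not exceed the
printed pairwise p), not an exact match. Relative qPCR expression uses
the standard ΔΔCt fold change `2^(−ΔΔCt)` against a housekeeping gene
and calibrator sample.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
chosen once as the study conditions:

* **Pedigrees:** 7 multiplex families by default, each a founder couple
  with 2–4 affected females (the mother plus daughters) and one
  unaffected son so male-X hemizygous calls occur; a sisters mode emits
  affected sister pairs/triads with unaffected parents.
* **Background:** 100,000 variants assigned uniformly over a fixed,
  deterministically built 2,000-gene map (22 autosomes plus X, ~4% of
  genes on X). Frequency mixture: 50% common (0.05–0.50), 25%
  low-frequency (0.01–0.05), 25% rare (log-uniform 5e-4–0.01). SNVs are
  drawn with a 2:1 transition bias (cohort Ti/Tv ≈ 2, the usual exome
  value); 10% are 1-bp indels. Founder genotypes are Hardy–Weinberg
  draws; children receive Mendelian transmissions, with X handled
  haploid in males.
* **Planting:** 8 genes of one 20-gene target pathway, one variant per
  (gene, carrier family) for 4 carrier families; heterozygous in the
  designated affected members (the transmitting mother is always a
  carrier, keeping trios consistent), missense with damaging
  predictions, panel frequency 0.001, absent from the internal control.
* **Noise:** 3% of calls get low depth, 3% low GQ, 2% of het calls a
  skewed allele fraction; 1% of rare background variants get an
  inflated internal-control frequency; each of 3 annotation sources
  independently perturbs 5% of variants (prediction flips, occasional
  consequence downgrades). Everything injected is recorded in the truth
  set with the cascade stage expected to remove it.
* **Determinism:** one integer seed drives a single generator in fixed
  draw order; same seed, byte-identical outputs.

What passing synthetic benchmarks shows: the pipeline's logic —
filtering, consensus, sharing, enrichment — recovers a planted signal
of realistic strength under realistic nuisance rates, and every stage
does exactly what its contract says on known truth. What it does not
show: performance on real exomes, whose error modes (batch effects,
capture-platform differences, population structure, LD between nearby
variants, segmental duplications) the generator deliberately does not
model. Real-cohort quantities such as per-family shared-variant counts
or pathway p-values therefore cannot be validated here; the report
formats mirror the standard pathway/family table structures so that
equivalent real inputs would populate them.

## Problem sizes used in the shipped benchmarks

The recovery benchmark runs 100 seeded replicates at the design scale
of the discovery analysis (7 families, 10 cases, 100,000 background
variants, 2,000-gene universe, 50 disjoint 20-gene pathways, 8 planted
genes in 4 families) and requires the planted pathway at rank 1 with
p < 0.01 in ≥ 95 of 100 replicates. The exact-test sweep covers every
(k, m, n, N) with N ≤ 60 against an independently computed
hypergeometric tail at 1e-12, plus literal enumeration of all candidate
draws for N ≤ 10. These sizes were chosen so the whole suite documents
the method at the scale it is meant for while remaining quick to run on
a laptop.

## Known limitations

* No liftover, no reference-based indel left-alignment, no gene-symbol
  alias resolution.
* Compound-heterozygote pairing, X-inactivation and imprinting are not
  modelled; the dominant bundle treats every alt-bearing call equally.
* The internal-control cut (2%) and the enrichment universe are
  judgment calls exposed as configuration; conclusions sensitive to
  them should be checked under alternatives.
* The Welch-from-summary comparison cannot recover the exact post-hoc
  p-values of an ANOVA on raw replicates; only consistency bounds are
  claimed.
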