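"""Dominant-model carrier logic and variant/gene sharing analyses.

Three analyses operate on cascade survivors:

* within-family sharing -- variants carried by every genotyped affected
  member of a family (the family-specific analysis);
* cross-case gene sharing -- genes in which at least ``min_cases``
  distinct cases carry some qualifying variant (the variants may differ
  per case), with the carriers spanning at least ``min_families``
  distinct families;
* cross-cohort overlap -- gene-level and variant-key-level intersection
  of two sharing results (e.g. discovery vs replication cohorts).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .filtering import FilteredCohort
from .model import CARRIER_CODES, CohortTable, GenotypeCall, PedigreeSet

log = logging.getLogger(__name__)


@dataclass
class ShareResult:
    scope: str  # "family", "cohort" or "pair"
    shared_variants: frozenset[str]
    shared_genes: frozenset[str]
    per_gene_carriers: dict[str, tuple[frozenset[str], frozenset[str]]] = field(
        default_factory=dict
    )
    family_id: Optional[str] = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene in sorted(self.per_gene_carriers):
            cases, fams = self.per_gene_carriers[gene]
            rows.append(
                {
                    "gene": gene,
                    "n_cases": len(cases),
                    "case_ids": ",".join(sorted(cases)),
                    "family_ids": ",".join(sorted(fams)),
                }
            )
        return pd.DataFrame(rows, columns=["gene", "n_cases", "case_ids", "family_ids"])

    def to_json(self) -> str:
        return json.dumps(
            {
                "scope": self.scope,
                "family_id": self.family_id,
                "shared_variants": sorted(self.shared_variants),
                "shared_genes": sorted(self.shared_genes),
                "per_gene_carriers": {
                    g: {"cases": sorted(c), "families": sorted(f)}
                    for g, (c, f) in sorted(self.per_gene_carriers.items())
                },
            },
            indent=2,
        )


def dominant_carriers(calls: Iterable[GenotypeCall]) -> set[str]:
    """Samples bearing >= 1 alternate allele (het, hom-alt or hemizygous-alt).

    Hemizygous male X calls arrive already coded as hemizygous-alt, so a
    single alternate allele there makes the sample a carrier.
    """
    return {c.sample_id for c in calls if c.is_carrier}


def _genes_of(table: CohortTable, keys: Iterable[str]) -> frozenset[str]:
    if "gene" not in table.variants.columns:
        return frozenset()
    genes = table.variants.loc[list(keys), "gene"].dropna().astype(str)
    return frozenset(g.upper() for g in genes)


def family_shared_variants(
    family_id: str,
    filtered: FilteredCohort,
    pedigree: PedigreeSet,
) -> Optional[ShareResult]:
    """Variants for which every genotyped affected family member is a carrier.

    Affected members without a genotype column are excluded from the
    intersection (logged).  Families with fewer than two genotyped
    affected members are skipped (returns None, logged).
    """
    table = filtered.table
    affected = pedigree.affected(family_id)
    genotyped = [s for s in affected if s in table.samples]
    dropped = set(affected) - set(genotyped)
    if dropped:
        log.info("family %s: %d affected members ungenotyped: %s",
                 family_id, len(dropped), sorted(dropped))
    if len(genotyped) < 2:
        log.warning(
            "family %s skipped: fewer than 2 genotyped affected members", family_id
        )
        return None
    cols = [table.sample_index(s) for s in genotyped]
    shared = filtered.carrier_mask[:, cols].all(axis=1)
    keys = frozenset(table.variants.index[shared])
    genes = _genes_of(table, keys)
    per_gene: dict[str, tuple[frozenset[str], frozenset[str]]] = {
        g: (frozenset(genotyped), frozenset({family_id})) for g in genes
    }
    return ShareResult(
        scope="pair" if len(genotyped) == 2 else "family",
        shared_variants=keys,
        shared_genes=genes,
        per_gene_carriers=per_gene,
        family_id=family_id,
    )


def all_family_shared(
    filtered: FilteredCohort, pedigree: PedigreeSet
) -> dict[str, ShareResult]:
    """family_shared_variants for every family with >= 2 genotyped affected."""
    out = {}
    for fam in pedigree.families:
        res = family_shared_variants(fam, filtered, pedigree)
        if res is not None:
            out[fam] = res
    return out


def gene_case_sharing(
    filtered: FilteredCohort,
    case_ids: Iterable[str],
    pedigree: PedigreeSet,
    min_cases: int,
    min_families: int,
) -> ShareResult:
    """Genes with qualifying rare variants in >= min_cases cases from >= min_families families.

    A gene is retained iff at least ``min_cases`` distinct cases carry
    some qualifying variant in it (the variants may differ per case) and
    those carriers span at least ``min_families`` distinct families.
    """
    if min_cases < 1 or min_families < 1:
        raise ValueError("min_cases and min_families must be >= 1")
    table = filtered.table
    case_ids = list(case_ids)
    unknown = [c for c in case_ids if c not in table.samples]
    if unknown:
        raise ValueError(f"case ids not genotyped in cohort: {unknown[:5]}")
    if "gene" not in table.variants.columns:
        raise ValueError("cohort has no gene annotations")

    cols = np.array([table.sample_index(c) for c in case_ids])
    mask = filtered.carrier_mask[:, cols] if len(cols) else np.zeros((len(table.variants), 0), bool)
    genes = table.variants["gene"].astype(object)

    per_gene: dict[str, set[str]] = {}
    gene_variants: dict[str, set[str]] = {}
    arr = mask
    for i, (key, gene) in enumerate(zip(table.variants.index, genes)):
        if gene is None or (isinstance(gene, float) and np.isnan(gene)):
            continue
        gene = str(gene).upper()
        carriers = {case_ids[j] for j in np.nonzero(arr[i])[0]}
        if not carriers:
            continue
        per_gene.setdefault(gene, set()).update(carriers)
        gene_variants.setdefault(gene, set()).add(key)

    retained: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
    shared_variants: set[str] = set()
    for gene, carriers in per_gene.items():
        fams = {pedigree.family_of[c] for c in carriers if c in pedigree.family_of}
        if len(carriers) >= min_cases and len(fams) >= min_families:
            retained[gene] = (frozenset(carriers), frozenset(fams))
            shared_variants |= gene_variants[gene]

    return ShareResult(
        scope="cohort",
        shared_variants=frozenset(shared_variants),
        shared_genes=frozenset(retained),
        per_gene_carriers=retained,
    )


def cohort_overlap(
    result_a: ShareResult | Mapping[str, ShareResult],
    result_b: ShareResult | Mapping[str, ShareResult],
) -> tuple[frozenset[str], frozenset[str]]:
    """Common genes and common variant keys between two sharing results.

    Accepts single ShareResults or per-family mappings (whose gene and
    variant sets are unioned first, mirroring the pooled comparison of
    two cohorts' family analyses).  Returns (common_genes,
    common_variant_keys), reported separately: the same gene can overlap
    through different variants.
    """

    def _pool(r):
        if isinstance(r, ShareResult):
            return set(r.shared_genes), set(r.shared_variants)
        genes, variants = set(), set()
        for res in r.values():
            genes |= res.shared_genes
            variants |= res.shared_variants
        return genes, variants

    genes_a, vars_a = _pool(result_a)
    genes_b, vars_b = _pool(result_b)
    return frozenset(genes_a & genes_b), frozenset(vars_a & vars_b)
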