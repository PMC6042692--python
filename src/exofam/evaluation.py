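"""Self-evaluation on synthetic cohorts with known planted truth.

Runs the full discovery chain -- simulate, consensus filter cascade,
case-group gene sharing, pathway enrichment -- on seeded replicates and
reports how often the planted pathway is recovered at rank 1 with
p below the significance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .enrichment import enrich
from .filtering import FilterConfig, run_cascade_consensus
from .model import PathwayCollection
from .pipeline import select_cases
from .sharing import gene_case_sharing
from .synthetic import (
    NoiseConfig,
    PlantSpec,
    build_gene_map,
    default_pathways,
    generate_pedigrees,
    simulate_cohort,
)


@dataclass(frozen=True)
class TrialResult:
    seed: int
    target_pathway: str
    rank: Optional[int]  # 1-based rank of the planted pathway; None if absent
    p_value: Optional[float]
    n_shared_genes: int
    recovered: bool  # rank 1 and p < alpha


def run_discovery_trial(
    seed: int,
    gene_map: Optional[pd.DataFrame] = None,
    pathways: Optional[PathwayCollection] = None,
    n_families: int = 7,
    n_background_variants: int = 100_000,
    n_cases: int = 10,
    min_cases: int = 3,
    min_families: int = 2,
    alpha: float = 0.01,
    filter_config: Optional[FilterConfig] = None,
    plant: Optional[PlantSpec] = None,
    noise: Optional[NoiseConfig] = None,
) -> TrialResult:
    """One seeded end-to-end discovery run against the planted truth."""
    gene_map = gene_map if gene_map is not None else build_gene_map()
    pathways = pathways or default_pathways(gene_map)
    fconf = filter_config or FilterConfig()
    plant = plant or PlantSpec()
    ped = generate_pedigrees(n_families=n_families, seed=seed)
    sim = simulate_cohort(
        ped,
        n_background_variants=n_background_variants,
        plant=plant,
        noise=noise or NoiseConfig(),
        seed=seed,
        gene_map=gene_map,
        pathways=pathways,
    )
    filtered, _ = run_cascade_consensus(sim.table, fconf)
    cases = select_cases(sim.pedigree, sim.table.samples, n_cases)
    share = gene_case_sharing(filtered, cases, sim.pedigree, min_cases, min_families)
    target = sim.plant.target_pathway
    if not share.shared_genes:
        return TrialResult(seed, target, None, None, 0, False)
    collection = pathways.restrict_universe(filtered.post_qc_genes)
    results = enrich(share.shared_genes, collection, alpha=alpha)
    rank = p = None
    for i, r in enumerate(results, start=1):
        if r.pathway == target:
            rank, p = i, r.p_value
            break
    recovered = rank == 1 and p is not None and p < alpha
    return TrialResult(seed, target, rank, p, len(share.shared_genes), recovered)


def planted_recovery(
    n_seeds: int = 100, base_seed: int = 0, **trial_kwargs
) -> tuple[int, list[TrialResult]]:
    """Run ``n_seeds`` replicates; returns (number recovered, all trials).

    Replicate seeds are ``base_seed * 1000 + i`` so that different base
    seeds give disjoint replicate sets.
    """
    gene_map = trial_kwargs.pop("gene_map", None)
    gene_map = gene_map if gene_map is not None else build_gene_map()
    pathways = trial_kwargs.pop("pathways", None) or default_pathways(gene_map)
    trials = [
        run_discovery_trial(
            base_seed * 1000 + i, gene_map=gene_map, pathways=pathways, **trial_kwargs
        )
        for i in range(n_seeds)
    ]
    return sum(t.recovered for t in trials), trials
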