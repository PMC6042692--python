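"""End-to-end orchestration: read -> cascade (-> consensus) -> sharing ->
enrichment -> aggregation, driven by a single validated configuration.

The pipeline runs in one of three cohort modes:

* ``case_group`` -- pool the selected cases and require gene-level
  sharing (>= min_cases cases from >= min_families families), then run
  one pathway enrichment on the shared genes;
* ``per_family`` -- intersect variants within each family's affected
  members, run enrichment per family, and aggregate across families
  (how many families reach p < alpha, with mean/median p);
* ``both`` -- both of the above.

Inputs are either files (VCF + PED + GMT + annotation sidecars) or a
simulated cohort generated in-process from the ``generate`` section.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import pandas as pd
import yaml

from . import cohort_io
from .enrichment import (
    EnrichmentResult,
    FamilyAggregate,
    aggregate_families,
    aggregates_frame,
    enrich,
    pathways_in_min_families,
    per_family_enrich,
    results_frame,
)
from .filtering import FilterConfig, FilteredCohort, FilterTrace, run_cascade, run_cascade_consensus
from .model import CohortTable, PathwayCollection, PedigreeSet
from .sharing import ShareResult, all_family_shared, gene_case_sharing
from .synthetic import (
    NoiseConfig,
    PlantSpec,
    SimulatedCohort,
    generate_pedigrees,
    simulate_cohort,
)

log = logging.getLogger(__name__)

_TOP_KEYS = {
    "seed", "mode", "inputs", "generate", "filter", "consensus", "cases",
    "n_cases", "min_cases", "min_families", "alpha", "min_families_listing",
    "universe", "out_dir", "aggregation_mode",
}
_INPUT_KEYS = {"vcf", "ped", "gmt", "sidecars", "universe_file"}
_GENERATE_KEYS = {
    "n_families", "affected_per_family_range", "sisters_mode",
    "n_background_variants", "plant", "noise",
}
_FILTER_KEYS = {
    "min_depth", "min_gq", "alt_fraction_range", "maf_threshold", "panel_policy",
    "required_panels", "internal_af_max", "min_consensus_sources",
}


class ConfigError(ValueError):
    pass


def _check_keys(section: Mapping, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown config key(s) in {where}: {sorted(unknown)}")


def load_config(config: Any) -> dict:
    """Load and validate a pipeline configuration (YAML path or dict)."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ConfigError("configuration must be a mapping")
    _check_keys(config, _TOP_KEYS, "top level")
    mode = config.get("mode", "both")
    if mode not in ("case_group", "per_family", "both"):
        raise ConfigError(f"unknown mode {mode!r}")
    if "inputs" in config and "generate" in config:
        raise ConfigError("give either 'inputs' or 'generate', not both")
    if "inputs" not in config and "generate" not in config:
        raise ConfigError("configuration needs an 'inputs' or 'generate' section")
    if "inputs" in config:
        _check_keys(config["inputs"], _INPUT_KEYS, "inputs")
        for req in ("vcf", "ped", "gmt"):
            if req not in config["inputs"]:
                raise ConfigError(f"inputs section lacks {req!r}")
    if "generate" in config:
        _check_keys(config["generate"] or {}, _GENERATE_KEYS, "generate")
    _check_keys(config.get("filter", {}) or {}, _FILTER_KEYS, "filter")
    return config


def filter_config_from(section: Mapping) -> FilterConfig:
    kw = dict(section)
    if "alt_fraction_range" in kw:
        kw["alt_fraction_range"] = tuple(kw["alt_fraction_range"])
    if "required_panels" in kw:
        kw["required_panels"] = tuple(kw["required_panels"])
    return FilterConfig(**kw)


def select_cases(
    pedigree: PedigreeSet, samples, n: Optional[int] = None
) -> list[str]:
    """Pick up to ``n`` genotyped affected individuals spanning all families.

    Round-robin over families in pedigree order (each family's affected
    members in pedigree order) so that every family is represented before
    any family contributes a second case.  ``n=None`` selects them all.
    """
    samples = set(samples)
    per_family = [
        [s for s in pedigree.affected(fam) if s in samples] for fam in pedigree.families
    ]
    picked: list[str] = []
    depth = 0
    while any(len(f) > depth for f in per_family):
        for fam_list in per_family:
            if depth < len(fam_list):
                picked.append(fam_list[depth])
                if n is not None and len(picked) == n:
                    return picked
        depth += 1
    return picked


@dataclass
class PipelineReport:
    """Everything a run produced, with writers for the report bundle."""

    mode: str
    config: dict
    filtered: FilteredCohort
    traces: dict[str, FilterTrace]
    universe: frozenset[str]
    case_share: Optional[ShareResult] = None
    case_enrichment: list[EnrichmentResult] = field(default_factory=list)
    family_share: dict[str, ShareResult] = field(default_factory=dict)
    family_enrichment: dict[str, list[EnrichmentResult]] = field(default_factory=dict)
    family_aggregates: list[FamilyAggregate] = field(default_factory=list)
    cross_family_listing: list[tuple[str, int]] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def write(self, outdir) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, trace in self.traces.items():
            p = outdir / f"filter_trace_{name}.tsv"
            trace.to_frame().to_csv(p, sep="\t", index=False)
            paths[f"trace_{name}"] = str(p)
        if self.case_share is not None:
            p = outdir / "shared_genes.tsv"
            self.case_share.to_frame().to_csv(p, sep="\t", index=False)
            paths["shared_genes"] = str(p)
        if self.case_enrichment:
            p = outdir / "pathways_case_group.tsv"
            results_frame(self.case_enrichment).to_csv(p, sep="\t", index=False)
            paths["pathways_case_group"] = str(p)
        if self.family_aggregates:
            p = outdir / "pathways_families.tsv"
            aggregates_frame(self.family_aggregates).to_csv(p, sep="\t", index=False)
            paths["pathways_families"] = str(p)
        p = outdir / "summary.json"
        with open(p, "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)
        paths["summary"] = str(p)
        return paths


def _load_inputs(config) -> tuple[CohortTable, PedigreeSet, PathwayCollection]:
    inputs = config["inputs"]
    table = cohort_io.read_vcf_cohort(inputs["vcf"])
    for name, path in sorted((inputs.get("sidecars") or {}).items()):
        cohort_io.attach_annotation_source(table, name, path)
    pedigree = cohort_io.read_pedigree(inputs["ped"])
    universe_mode = config.get("universe", "cohort_genes")
    if universe_mode == "cohort_genes":
        genes = table.variants["gene"].dropna().astype(str)
        collection = cohort_io.read_gene_sets(
            inputs["gmt"], "cohort_genes", cohort_genes=genes
        )
    elif universe_mode == "file":
        collection = cohort_io.read_gene_sets(
            inputs["gmt"], "file", universe_file=inputs.get("universe_file")
        )
    else:
        collection = cohort_io.read_gene_sets(inputs["gmt"], "union_of_sets")
    return table, pedigree, collection


def _generate_inputs(config) -> SimulatedCohort:
    g = dict(config.get("generate") or {})
    seed = int(config.get("seed", 0))
    ped = generate_pedigrees(
        n_families=int(g.get("n_families", 7)),
        affected_per_family_range=tuple(g.get("affected_per_family_range", (2, 4))),
        sisters_mode=bool(g.get("sisters_mode", False)),
        seed=seed,
    )
    plant = PlantSpec(**(g.get("plant") or {})) if g.get("plant") is not None else PlantSpec()
    noise = NoiseConfig(**(g.get("noise") or {})) if g.get("noise") is not None else NoiseConfig()
    return simulate_cohort(
        ped,
        n_background_variants=int(g.get("n_background_variants", 100_000)),
        plant=plant,
        noise=noise,
        seed=seed,
    )


def run_pipeline(config: Any, **overrides) -> PipelineReport:
    """Execute the configured analysis end to end.

    ``overrides`` shadow top-level config keys (e.g. ``alpha=0.05``,
    ``min_cases=4``).  Returns the in-memory report; writes the report
    bundle when ``out_dir`` is configured.
    """
    config = dict(load_config(config))
    config.update({k: v for k, v in overrides.items() if v is not None})
    _check_keys(config, _TOP_KEYS, "top level (after overrides)")

    fconf = filter_config_from(config.get("filter", {}) or {})
    mode = config.get("mode", "both")
    alpha = float(config.get("alpha", 0.01))

    simulated: Optional[SimulatedCohort] = None
    if "generate" in config:
        simulated = _generate_inputs(config)
        table, pedigree, collection = simulated.table, simulated.pedigree, simulated.pathways
    else:
        table, pedigree, collection = _load_inputs(config)

    use_consensus = bool(config.get("consensus", bool(table.annotations)))
    if use_consensus and table.annotations:
        filtered, traces = run_cascade_consensus(table, fconf)
    else:
        filtered, trace = run_cascade(table, fconf)
        traces = {"primary": trace}

    # resolve the enrichment universe
    universe_mode = config.get("universe", "cohort_genes")
    if universe_mode == "cohort_genes":
        universe = filtered.post_qc_genes
    else:
        universe = frozenset(collection.universe)
    collection_u = collection.restrict_universe(universe) if universe else collection
    log.info("enrichment universe: %d genes (%s)", len(universe), universe_mode)

    report = PipelineReport(
        mode=mode, config=config, filtered=filtered, traces=traces,
        universe=frozenset(universe),
    )

    gene_of = filtered.table.variants["gene"].astype(object)

    if mode in ("case_group", "both"):
        cases = config.get("cases") or select_cases(
            pedigree, table.samples, config.get("n_cases")
        )
        share = gene_case_sharing(
            filtered, cases, pedigree,
            min_cases=int(config.get("min_cases", 3)),
            min_families=int(config.get("min_families", 2)),
        )
        report.case_share = share
        counts: dict[str, int] = {}
        for key in share.shared_variants:
            g = gene_of.loc[key]
            if isinstance(g, str):
                counts[g.upper()] = counts.get(g.upper(), 0) + 1
        if share.shared_genes:
            report.case_enrichment = enrich(
                share.shared_genes, collection_u, alpha=alpha, variant_counts=counts
            )

    if mode in ("per_family", "both"):
        report.family_share = all_family_shared(filtered, pedigree)
        report.family_enrichment = per_family_enrich(
            report.family_share, collection_u, alpha=alpha
        )
        report.family_aggregates = aggregate_families(
            report.family_enrichment, alpha=alpha,
            mode=config.get("aggregation_mode", "significant_only"),
        )
        report.cross_family_listing = pathways_in_min_families(
            report.family_enrichment, alpha=alpha,
            min_families=int(config.get("min_families_listing", 2)),
        )

    report.summary = _summarize(report, table, fconf, alpha, simulated)
    if config.get("out_dir"):
        report.write(config["out_dir"])
    return report


def _summarize(report, table, fconf, alpha, simulated) -> dict:
    first_trace = next(iter(report.traces.values()))
    summary = {
        "mode": report.mode,
        "n_samples": table.n_samples,
        "n_variants_input": first_trace.n_input,
        "n_variants_pass": len(report.filtered.table.variants),
        "universe_size": len(report.universe),
        "alpha": alpha,
        "thresholds": {
            "min_depth": fconf.min_depth,
            "min_gq": fconf.min_gq,
            "alt_fraction_range": list(fconf.alt_fraction_range),
            "maf_threshold": fconf.maf_threshold,
            "panel_policy": fconf.panel_policy,
            "required_panels": list(fconf.required_panels),
            "internal_af_max": fconf.internal_af_max,
            "min_consensus_sources": fconf.min_consensus_sources,
        },
        "stage_survivors": {
            name: trace.survivors_by_stage() for name, trace in report.traces.items()
        },
    }
    if report.case_share is not None:
        summary["case_group"] = {
            "n_shared_genes": len(report.case_share.shared_genes),
            "n_shared_variants": len(report.case_share.shared_variants),
            "top_pathways": [
                {"pathway": r.pathway, "p_value": r.p_value, "n_genes": len(r.genes_hit)}
                for r in report.case_enrichment[:5]
            ],
        }
    if report.family_aggregates:
        summary["per_family"] = {
            "n_families_analyzed": len(report.family_enrichment),
            "top_aggregates": [
                {
                    "rank": a.rank, "pathway": a.pathway,
                    "n_families": a.n_families_significant,
                    "mean_p": a.mean_p, "median_p": a.median_p,
                }
                for a in report.family_aggregates[:5]
            ],
        }
    if simulated is not None:
        summary["truth"] = {
            "target_pathway": simulated.plant.target_pathway,
            "n_planted_variants": len(simulated.truth.planted),
            "planted_genes": sorted(simulated.truth.planted_genes),
        }
    return summary
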