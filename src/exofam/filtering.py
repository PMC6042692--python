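"""Rare-variant prioritization filter cascade with a per-stage audit trace.

The cascade applies, in order:

1. genotype QC       -- per call: read depth >= 15 and genotype quality >= 20
2. alt-allele fraction -- per heterozygous call: alt/(alt+ref) within [0.30, 0.85]
3. rarity            -- per variant: MAF < 1% or absent in the required panels
4. pathogenicity     -- per variant: ACMG-derived category 1-3 by HGMD/consequence
5. damaging gate     -- per variant: SIFT/PolyPhen damaging, HGMD, or LoF consequence
6. internal control  -- per variant: frequency in the internal control cohort <= cap

A per-call failure removes the variant from that sample's carrier set
only; the variant leaves the table when no passing alt-bearing call
remains.  A per-variant failure removes the variant globally.  Every
removal is recorded in the :class:`FilterTrace`.

A multi-annotator consensus step retains only variants whose cascade
pass is reproduced by at least ``min_consensus_sources`` independent
annotation sources.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    GT_HEMI_ALT,
    GT_HET,
    GT_HOM_ALT,
    CohortTable,
    GenotypeCall,
    VariantRecord,
)

log = logging.getLogger(__name__)

#: consequences "expected to be pathogenic": loss of initiation, premature
#: stop, disruption of stop, whole-gene deletion, frameshift, splice disruption
CATEGORY2_CONSEQUENCES = frozenset(
    {
        "start_lost",
        "stop_gained",
        "stop_lost",
        "whole_gene_deletion",
        "frameshift",
        "splice_acceptor",
        "splice_donor",
    }
)

#: consequences of "unknown significance but potentially disease-causing":
#: nonsynonymous substitution, in-frame indel, splice-context overlap
CATEGORY3_CONSEQUENCES = frozenset({"missense", "inframe_indel", "splice_region"})

KNOWN_CONSEQUENCES = (
    CATEGORY2_CONSEQUENCES
    | CATEGORY3_CONSEQUENCES
    | frozenset({"synonymous", "intron", "utr", "intergenic", "upstream", "downstream"})
)

STAGES = (
    "genotype_qc",
    "alt_fraction",
    "rarity",
    "pathogenicity",
    "damaging",
    "internal_control",
)


@dataclass(frozen=True)
class FilterConfig:
    """All cascade thresholds.

    Defaults follow the standard prioritization recipe for family exome
    studies of this kind: calls with read depth < 15 or genotype quality
    < 20 are removed, heterozygous calls must show an alternate-allele
    fraction within [0.30, 0.85] (inclusive), variants must be rare
    (MAF < 1%) or absent in every required reference panel, carry an
    ACMG-derived pathogenicity category 1-3, pass a damaging-prediction
    gate, and not be common in the internal control cohort.
    """

    min_depth: int = 15
    min_gq: float = 20.0
    alt_fraction_range: tuple[float, float] = (0.30, 0.85)
    maf_threshold: float = 0.01
    panel_policy: str = "all_panels"  # or "any_panel"
    required_panels: tuple[str, ...] = ("KG", "EXAC", "ESP")
    internal_af_max: float = 0.02
    sift_damaging: frozenset[str] = frozenset({"damaging"})
    polyphen_damaging: frozenset[str] = frozenset({"probably_damaging", "possibly_damaging"})
    min_consensus_sources: int = 2

    def __post_init__(self):
        low, high = self.alt_fraction_range
        if not (0.0 <= low < high <= 1.0):
            raise ValueError(f"invalid alt_fraction_range {self.alt_fraction_range}")
        if self.min_depth < 0 or self.min_gq < 0:
            raise ValueError("thresholds must be non-negative")
        if not (0.0 <= self.maf_threshold <= 1.0):
            raise ValueError("maf_threshold must be in [0, 1]")
        if self.panel_policy not in ("all_panels", "any_panel"):
            raise ValueError(f"unknown panel_policy {self.panel_policy!r}")
        if self.min_consensus_sources < 1:
            raise ValueError("min_consensus_sources must be >= 1")

    def with_overrides(self, **kw) -> "FilterConfig":
        return replace(self, **kw)


@dataclass
class StageRecord:
    name: str
    n_in: int
    n_out: int
    removed_keys: list[str]
    reasons: Counter = field(default_factory=Counter)


@dataclass
class FilterTrace:
    """Ordered per-stage survivor counts with removal reasons."""

    stages: list[StageRecord] = field(default_factory=list)

    def add(self, name, n_in, n_out, removed_keys, reasons=None):
        if n_out > n_in:
            raise ValueError("stage cannot add variants")
        if self.stages and self.stages[-1].n_out != n_in:
            raise ValueError("stage inputs must chain exactly")
        self.stages.append(
            StageRecord(name, int(n_in), int(n_out), list(removed_keys), Counter(reasons or {}))
        )

    @property
    def n_input(self) -> int:
        return self.stages[0].n_in if self.stages else 0

    @property
    def n_survivors(self) -> int:
        return self.stages[-1].n_out if self.stages else 0

    def survivors_by_stage(self) -> dict[str, int]:
        return {s.name: s.n_out for s in self.stages}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.name,
                    "n_in": s.n_in,
                    "n_out": s.n_out,
                    "n_removed": s.n_in - s.n_out,
                    "reasons": ";".join(f"{k}={v}" for k, v in sorted(s.reasons.items())),
                }
                for s in self.stages
            ]
        )

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "stage": s.name,
                    "n_in": s.n_in,
                    "n_out": s.n_out,
                    "removed_keys": sorted(s.removed_keys),
                    "reasons": dict(sorted(s.reasons.items())),
                }
                for s in self.stages
            ],
            indent=2,
        )


# ---------------------------------------------------------------------------
# Per-call predicates
# ---------------------------------------------------------------------------

def genotype_qc_pass(call: GenotypeCall, config: FilterConfig) -> bool:
    """True iff depth >= min_depth and GQ >= min_gq.

    A call with missing depth or GQ fails: missingness is
    indistinguishable from low quality, so the conservative choice is
    removal.
    """
    if call.depth is None or call.gq is None:
        return False
    return call.depth >= config.min_depth and call.gq >= config.min_gq


def alt_fraction(call: GenotypeCall) -> Optional[float]:
    """alt_reads / (alt_reads + ref_reads); None when no informative reads."""
    if call.allele_depths is None:
        return None
    r, a = call.allele_depths
    if r + a == 0:
        return None
    return a / (r + a)


def in_fraction_window(call: GenotypeCall, config: FilterConfig) -> bool:
    """Heterozygous-call sanity window on the alt-allele fraction.

    Inclusive at both bounds.  Only heterozygous calls are subject to the
    window; homozygous-alt and hemizygous calls bypass it.  A het call
    with no informative reads fails ("no-informative-reads").
    """
    if call.gt != GT_HET:
        return True
    frac = alt_fraction(call)
    if frac is None:
        return False
    low, high = config.alt_fraction_range
    return low <= frac <= high


# ---------------------------------------------------------------------------
# Per-variant predicates
# ---------------------------------------------------------------------------

def rare_in_panels(variant: VariantRecord, config: FilterConfig) -> bool:
    """Rarity test against the required reference panels.

    Under ``all_panels`` the variant must have frequency < maf_threshold
    or be absent in *every* required panel; under ``any_panel`` one
    qualifying panel suffices.  Absent everywhere counts as rare (novel).
    """
    checks = []
    for panel in config.required_panels:
        f = variant.panel_freqs.get(panel)
        checks.append(f is None or f < config.maf_threshold)
    if not checks:
        return True
    return all(checks) if config.panel_policy == "all_panels" else any(checks)


_warned_consequences: set[str] = set()


def classify_pathogenicity(variant: VariantRecord) -> Optional[int]:
    """ACMG-derived category: 1 reported disease-causing (HGMD-listed),
    2 expected pathogenic (LoF-type consequence), 3 potentially
    disease-causing (missense/in-frame/splice-context); None otherwise.
    """
    if variant.hgmd:
        return 1
    csq = variant.consequence
    if csq is None:
        return None
    if csq in CATEGORY2_CONSEQUENCES:
        return 2
    if csq in CATEGORY3_CONSEQUENCES:
        return 3
    if csq not in KNOWN_CONSEQUENCES and csq not in _warned_consequences:
        _warned_consequences.add(csq)
        log.warning("unknown consequence term %r; treated as non-qualifying", csq)
    return None


def damaging_gate(variant: VariantRecord, config: FilterConfig) -> bool:
    """Predicted-functional-effect gate.

    Passes when any qualifying condition holds: SIFT damaging, PolyPhen
    probably/possibly damaging, HGMD-listed, or a gain/loss-of-function
    consequence (the category-2 list).
    """
    if variant.hgmd:
        return True
    if variant.consequence in CATEGORY2_CONSEQUENCES:
        return True
    sift = variant.predictions.get("sift")
    if sift is not None and sift in config.sift_damaging:
        return True
    poly = variant.predictions.get("polyphen")
    if poly is not None and poly in config.polyphen_damaging:
        return True
    return False


def internal_control_pass(variant: VariantRecord, config: FilterConfig) -> bool:
    """True iff the internal-control frequency is absent or <= internal_af_max."""
    return variant.internal_af is None or variant.internal_af <= config.internal_af_max


# ---------------------------------------------------------------------------
# Vectorized cascade
# ---------------------------------------------------------------------------

@dataclass
class FilteredCohort:
    """Cascade survivors plus the per-sample carrier eligibility mask.

    ``carrier_mask[i, j]`` is True when sample j bears an alternate
    allele at surviving variant i through a call that passed the
    per-call filters.
    """

    table: CohortTable
    carrier_mask: np.ndarray
    post_qc_genes: frozenset[str] = frozenset()

    @property
    def keys(self) -> pd.Index:
        return self.table.keys


def _per_call_masks(table: CohortTable, config: FilterConfig):
    carrier = table.carrier_matrix()
    qc_ok = (
        (table.dp >= config.min_depth)
        & (table.gq >= config.min_gq)
        & (table.dp >= 0)
        & (table.gq >= 0)
    )
    low, high = config.alt_fraction_range
    het = table.gt == GT_HET
    total = table.ad_ref + table.ad_alt
    informative = (table.ad_ref >= 0) & (table.ad_alt >= 0) & (total > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(informative, table.ad_alt / np.maximum(total, 1), np.nan)
    window_ok = ~het | (informative & (frac >= low) & (frac <= high))
    return carrier, qc_ok, window_ok


def _variant_pass_flags(frame: pd.DataFrame, config: FilterConfig):
    """Vectorized rarity / pathogenicity / damaging / internal-control flags."""
    n = len(frame)
    # rarity
    panel_checks = []
    for panel in config.required_panels:
        col = f"af_{panel}"
        if col not in frame.columns:
            raise ValueError(f"required panel {panel!r} not present in annotations")
        f = pd.to_numeric(frame[col], errors="coerce")
        panel_checks.append((f.isna() | (f < config.maf_threshold)).to_numpy())
    if panel_checks:
        stacked = np.vstack(panel_checks)
        rare = stacked.all(axis=0) if config.panel_policy == "all_panels" else stacked.any(axis=0)
    else:
        rare = np.ones(n, dtype=bool)

    csq = frame["consequence"] if "consequence" in frame.columns else pd.Series([None] * n, index=frame.index)
    csq = csq.astype(object)
    hgmd = (
        frame["hgmd"].fillna(False).astype(bool).to_numpy()
        if "hgmd" in frame.columns
        else np.zeros(n, dtype=bool)
    )
    cat2 = csq.isin(CATEGORY2_CONSEQUENCES).to_numpy()
    cat3 = csq.isin(CATEGORY3_CONSEQUENCES).to_numpy()
    pathogenic = hgmd | cat2 | cat3

    def _labels(col, wanted):
        if col not in frame.columns:
            return np.zeros(n, dtype=bool)
        return frame[col].astype(object).isin(wanted).to_numpy()

    damaging = (
        hgmd
        | cat2
        | _labels("sift", config.sift_damaging)
        | _labels("polyphen", config.polyphen_damaging)
    )

    if "internal_af" in frame.columns:
        iaf = pd.to_numeric(frame["internal_af"], errors="coerce")
        internal_ok = (iaf.isna() | (iaf <= config.internal_af_max)).to_numpy()
    else:
        internal_ok = np.ones(n, dtype=bool)
    return {
        "rarity": rare,
        "pathogenicity": pathogenic,
        "damaging": damaging,
        "internal_control": internal_ok,
    }


def run_cascade(
    table: CohortTable,
    config: FilterConfig,
    annotation_source: Optional[str] = None,
    *,
    _masks=None,
) -> tuple[FilteredCohort, FilterTrace]:
    """Apply the full cascade; returns survivors plus the audit trace.

    ``annotation_source`` selects an attached alternative annotation
    frame for the per-variant stages (the genotype-level stages are
    annotation-independent).
    """
    trace = FilterTrace()
    keys = table.variants.index.to_numpy()
    alive = np.ones(len(keys), dtype=bool)

    carrier, qc_ok, window_ok = _masks if _masks is not None else _per_call_masks(table, config)

    # stage 1: genotype QC (per call)
    mask = carrier & qc_ok
    survive = mask.any(axis=1)
    _record(trace, "genotype_qc", alive, alive & survive, keys, "low_dp_or_gq")
    alive &= survive

    # stage 2: alt-allele fraction window (per het call)
    mask &= window_ok
    survive = mask.any(axis=1)
    _record(trace, "alt_fraction", alive, alive & survive, keys, "alt_fraction_out_of_window")
    alive &= survive

    post_qc_genes = frozenset(
        g.upper()
        for g in table.variants.loc[alive, "gene"].dropna().astype(str)
    ) if "gene" in table.variants.columns else frozenset()

    # stages 3-6: per-variant filters on the chosen annotation frame
    frame = table.annotation_frame(annotation_source)
    flags = _variant_pass_flags(frame, config)
    reasons = {
        "rarity": "common_in_panel",
        "pathogenicity": "no_category_1_3",
        "damaging": "no_damaging_evidence",
        "internal_control": "high_internal_af",
    }
    for stage in ("rarity", "pathogenicity", "damaging", "internal_control"):
        survive = flags[stage]
        _record(trace, stage, alive, alive & survive, keys, reasons[stage])
        alive &= survive

    surviving_keys = keys[alive]
    filtered = table.subset_variants(surviving_keys)
    return (
        FilteredCohort(
            table=filtered, carrier_mask=mask[alive], post_qc_genes=post_qc_genes
        ),
        trace,
    )


def _record(trace, name, alive_before, alive_after, keys, reason):
    removed = keys[alive_before & ~alive_after]
    trace.add(
        name,
        int(alive_before.sum()),
        int(alive_after.sum()),
        removed.tolist(),
        {reason: len(removed)} if len(removed) else {},
    )


# ---------------------------------------------------------------------------
# Consensus across annotation sources
# ---------------------------------------------------------------------------

def consensus_across_sources(
    per_source_pass_sets: Mapping[str, Iterable[str]] | Sequence[Iterable[str]],
    min_sources: int,
) -> set[str]:
    """Variant keys whose cascade pass is reproduced by >= min_sources sources."""
    if isinstance(per_source_pass_sets, Mapping):
        sets = [set(v) for v in per_source_pass_sets.values()]
    else:
        sets = [set(v) for v in per_source_pass_sets]
    if not sets:
        raise ValueError("need at least one source set")
    if min_sources > len(sets):
        raise ValueError(f"min_sources={min_sources} exceeds number of sources {len(sets)}")
    counts: Counter = Counter()
    for s in sets:
        counts.update(s)
    return {k for k, c in counts.items() if c >= min_sources}


def run_cascade_consensus(
    table: CohortTable,
    config: FilterConfig,
    sources: Optional[Sequence[str]] = None,
) -> tuple[FilteredCohort, dict[str, FilterTrace]]:
    """Run the cascade once per annotation source and apply the consensus rule.

    ``sources`` defaults to the table's attached annotation sources; when
    the table has none, the primary annotations are used as a single
    source (consensus then requires min_consensus_sources == 1).
    Genotype-level masks are shared across sources, so the returned
    carrier mask comes from the first source's run restricted to the
    consensus keys.
    """
    if sources is None:
        sources = sorted(table.annotations) or [None]  # type: ignore[list-item]
    traces: dict[str, FilterTrace] = {}
    pass_sets: dict[str, set[str]] = {}
    first: Optional[FilteredCohort] = None
    masks = _per_call_masks(table, config)
    for src in sources:
        filtered, trace = run_cascade(table, config, annotation_source=src, _masks=masks)
        label = src if src is not None else "primary"
        traces[label] = trace
        pass_sets[label] = set(filtered.keys)
        if first is None:
            first = filtered
    consensus = consensus_across_sources(pass_sets, config.min_consensus_sources)
    carrier, qc_ok, window_ok = masks
    mask = carrier & qc_ok & window_ok
    order = [k for k in table.variants.index if k in consensus]
    idx = table.variants.index.get_indexer(order)
    assert first is not None
    result = FilteredCohort(
        table=table.subset_variants(order),
        carrier_mask=mask[idx],
        post_qc_genes=first.post_qc_genes,
    )
    return result, traces
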