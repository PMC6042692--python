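"""Gene-set over-representation via the one-sided Fisher exact test.

For a candidate gene set of size ``n`` drawn from a universe of ``N``
genes, and a pathway occupying ``m`` genes of that universe, the
overlap ``k`` under the null is hypergeometric:

    P(X >= k) = sum_{i=k}^{min(m,n)} C(m, i) C(N-m, n-i) / C(N, n)

The upper-tail probability is computed with exact integer arithmetic
(no normal approximation); results are cached per (N, m, n) so ranking
many pathways against one candidate set costs one table each.

Per-family analysis and the cross-family aggregation (how many families
reach significance for a pathway, with mean/median of their p-values)
mirror the presentation used for multiplex-family cohort studies.
"""

from __future__ import annotations

import logging
import statistics
import warnings
from dataclasses import dataclass
from functools import lru_cache
from math import comb
from typing import Iterable, Mapping, Optional

import pandas as pd

from .model import PathwayCollection
from .sharing import ShareResult

log = logging.getLogger(__name__)


@lru_cache(maxsize=300_000)
def _tail_numerators(N: int, m: int, n: int) -> tuple[tuple[int, ...], int]:
    """Suffix sums of hypergeometric numerators for k = 0..min(m, n)."""
    kmax = min(m, n)
    terms = [comb(m, i) * comb(N - m, n - i) for i in range(kmax + 1)]
    suffix = [0] * (kmax + 2)
    for i in range(kmax, -1, -1):
        suffix[i] = suffix[i + 1] + terms[i]
    return tuple(suffix[: kmax + 1]), comb(N, n)


def fisher_enrichment_p(k: int, m: int, n: int, N: int) -> float:
    """One-sided upper-tail P(X >= k), X ~ Hypergeometric(N, m, n).

    Parameters are the 2x2 margins: ``k`` observed overlap, ``m``
    pathway size in the universe, ``n`` candidate-set size, ``N``
    universe size.  Exact integer computation.
    """
    if not (0 <= m <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= m, n <= N; got m={m}, n={n}, N={N}")
    if not (0 <= k <= min(m, n)):
        raise ValueError(f"need 0 <= k <= min(m, n) = {min(m, n)}; got k={k}")
    if k == 0:
        return 1.0
    suffix, denom = _tail_numerators(N, m, n)
    return suffix[k] / denom


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    p_value: float
    genes_hit: frozenset[str]
    n_variants: int
    table: tuple[int, int, int, int]  # (k, m, n, N)
    significant: bool

    @property
    def k(self) -> int:
        return self.table[0]


def enrich(
    candidate_genes: Iterable[str],
    collection: PathwayCollection,
    alpha: float = 0.01,
    variant_counts: Optional[Mapping[str, int]] = None,
) -> list[EnrichmentResult]:
    """Rank every pathway by one-sided Fisher exact over-representation.

    Candidate genes outside the universe are dropped with a warning.
    Results are sorted ascending by p, ties broken by pathway name;
    pathways with p >= alpha are flagged non-significant but retained.
    ``variant_counts`` (gene -> qualifying-variant count) feeds the
    per-pathway variant tally.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    candidates = {g.upper() for g in candidate_genes}
    if not candidates:
        raise ValueError("empty candidate gene set")
    outside = candidates - collection.universe
    if outside:
        warnings.warn(
            f"{len(outside)} candidate genes outside the universe dropped "
            f"(e.g. {sorted(outside)[:3]})"
        )
        candidates -= outside
    if not candidates:
        raise ValueError("no candidate genes remain inside the universe")

    N = len(collection.universe)
    n = len(candidates)
    counts = {g.upper(): int(c) for g, c in (variant_counts or {}).items()}

    results = []
    for name, genes in collection.sets.items():
        hit = frozenset(genes & candidates)
        k, m = len(hit), len(genes)
        p = fisher_enrichment_p(k, m, n, N)
        results.append(
            EnrichmentResult(
                pathway=name,
                p_value=p,
                genes_hit=hit,
                n_variants=sum(counts.get(g, 0) for g in hit),
                table=(k, m, n, N),
                significant=p < alpha,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.pathway))
    return results


def results_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view with the classic pathway-report column structure."""
    return pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "p_value": r.p_value,
                "n_genes": len(r.genes_hit),
                "n_variants": r.n_variants,
                "genes": ",".join(sorted(r.genes_hit)),
                "k": r.table[0],
                "m": r.table[1],
                "n": r.table[2],
                "N": r.table[3],
                "significant": r.significant,
            }
            for r in results
        ],
        columns=[
            "pathway", "p_value", "n_genes", "n_variants", "genes",
            "k", "m", "n", "N", "significant",
        ],
    )


def per_family_enrich(
    family_share_results: Mapping[str, ShareResult | Iterable[str]],
    collection: PathwayCollection,
    alpha: float = 0.01,
) -> dict[str, list[EnrichmentResult]]:
    """Enrichment per family, each family contributing its shared-gene set.

    Families with an empty shared-gene set are reported with no results.
    """
    out: dict[str, list[EnrichmentResult]] = {}
    for fam, res in family_share_results.items():
        genes = set(res.shared_genes) if isinstance(res, ShareResult) else set(res)
        genes = {g.upper() for g in genes} & collection.universe
        if not genes:
            log.info("family %s has no shared genes inside the universe", fam)
            out[fam] = []
            continue
        out[fam] = enrich(genes, collection, alpha=alpha)
    return out


def pathways_in_min_families(
    per_family_results: Mapping[str, Iterable[EnrichmentResult]],
    alpha: float = 0.01,
    min_families: int = 2,
) -> list[tuple[str, int]]:
    """Pathways significant (p < alpha) in at least ``min_families`` families.

    Returns (pathway, n_families) sorted by descending family count then
    pathway name.
    """
    counts: dict[str, int] = {}
    for results in per_family_results.values():
        for r in results:
            if r.p_value < alpha:
                counts[r.pathway] = counts.get(r.pathway, 0) + 1
    listing = [(p, c) for p, c in counts.items() if c >= min_families]
    listing.sort(key=lambda t: (-t[1], t[0]))
    return listing


@dataclass(frozen=True)
class FamilyAggregate:
    pathway: str
    n_families_significant: int
    mean_p: float
    median_p: float
    rank: int


def aggregate_families(
    per_family_results: Mapping[str, Iterable[EnrichmentResult]],
    alpha: float = 0.01,
    mode: str = "significant_only",
) -> list[FamilyAggregate]:
    """Cross-family aggregation: family counts and average/median p per pathway.

    ``mode='significant_only'`` (default) computes mean/median over the
    families where the pathway reached p < alpha, matching how pooled
    family tables are usually presented; ``mode='all_families'`` pools
    every family that produced a result for the pathway.  Pathways
    significant in no family are omitted.  Rank is 1-based and dense on
    the sort key (family count descending, then median p ascending).
    """
    if mode not in ("significant_only", "all_families"):
        raise ValueError(f"unknown mode {mode!r}")
    sig_p: dict[str, list[float]] = {}
    all_p: dict[str, list[float]] = {}
    for results in per_family_results.values():
        for r in results:
            all_p.setdefault(r.pathway, []).append(r.p_value)
            if r.p_value < alpha:
                sig_p.setdefault(r.pathway, []).append(r.p_value)

    rows = []
    for pathway, ps in sig_p.items():
        pool = ps if mode == "significant_only" else all_p[pathway]
        rows.append(
            (
                pathway,
                len(ps),
                float(statistics.mean(pool)),
                float(statistics.median(pool)),
            )
        )
    rows.sort(key=lambda t: (-t[1], t[3], t[0]))

    aggregates: list[FamilyAggregate] = []
    rank = 0
    prev_key = None
    for pathway, count, mean_p, median_p in rows:
        key = (count, median_p)
        if key != prev_key:
            rank += 1
            prev_key = key
        aggregates.append(FamilyAggregate(pathway, count, mean_p, median_p, rank))
    return aggregates


def aggregates_frame(aggregates: Iterable[FamilyAggregate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": a.rank,
                "pathway": a.pathway,
                "n_families": a.n_families_significant,
                "mean_p": a.mean_p,
                "median_p": a.median_p,
            }
            for a in aggregates
        ],
        columns=["rank", "pathway", "n_families", "mean_p", "median_p"],
    )


def benjamini_hochberg(results: list[EnrichmentResult]) -> list[tuple[EnrichmentResult, float]]:
    """Optional BH-adjusted q-values alongside the raw ranking."""
    ordered = sorted(results, key=lambda r: r.p_value)
    m = len(ordered)
    qs = [0.0] * m
    prev = 1.0
    for i in range(m - 1, -1, -1):
        q = min(prev, ordered[i].p_value * m / (i + 1))
        qs[i] = q
        prev = q
    return list(zip(ordered, qs))
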