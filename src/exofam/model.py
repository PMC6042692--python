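"""Core in-memory containers for multiplex-family exome cohorts.

The central container is :class:`CohortTable`: a normalized variant table
(one row per ``chrom:pos:ref:alt`` key, single alternate allele) together
with dense per-sample call matrices (genotype code, depth, genotype
quality, allele depths).  Variant annotations -- consequence, reference
panel allele frequencies, pathogenicity predictions, internal-control
frequency -- live in the variant table; alternative annotation sources
(e.g. exports of the same cohort from different annotation software) can
be attached as sidecar frames sharing the same index.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

# Genotype codes used in CohortTable.gt
GT_MISSING = -1
GT_REF = 0
GT_HET = 1
GT_HOM_ALT = 2
GT_HEMI_ALT = 3

#: codes that make a sample a carrier under the dominant model
CARRIER_CODES = (GT_HET, GT_HOM_ALT, GT_HEMI_ALT)

GT_LABELS = {
    GT_MISSING: "missing",
    GT_REF: "ref-ref",
    GT_HET: "het",
    GT_HOM_ALT: "hom-alt",
    GT_HEMI_ALT: "hemizygous-alt",
}

#: default reference-panel names (1000 Genomes, ExAC, NHLBI ESP style)
DEFAULT_PANELS = ("KG", "EXAC", "ESP")

_ANNOTATION_COLUMNS = ("consequence", "sift", "polyphen", "hgmd", "cadd", "internal_af")


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    """Normalize a biallelic variant by trimming shared allele sequence.

    Right-trims the common suffix, then left-trims the common prefix
    (advancing ``pos``), leaving at least one base in each allele.  This
    puts SNVs and simple indels into a canonical representation so that
    the same variant exported by different annotation tools gets the same
    key.  The operation is idempotent.
    """
    if ref == alt:
        raise ValueError(f"ref and alt are identical at {chrom}:{pos} ({ref})")
    ref = ref.upper()
    alt = alt.upper()
    # right-trim common suffix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref = ref[:-1]
        alt = alt[:-1]
    # left-trim common prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref = ref[1:]
        alt = alt[1:]
        pos += 1
    return chrom, pos, ref, alt


def variant_key(chrom: str, pos: int, ref: str, alt: str, *, normalize: bool = True) -> str:
    if normalize:
        chrom, pos, ref, alt = normalize_variant(chrom, pos, ref, alt)
    return f"{chrom}:{pos}:{ref}:{alt}"


_KEY_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<pos>\d+):(?P<ref>[ACGTN]+):(?P<alt>[ACGTN]+)$")


def parse_key(key: str) -> tuple[str, int, str, str]:
    m = _KEY_RE.match(key)
    if m is None:
        raise ValueError(f"not a variant key: {key!r}")
    return m["chrom"], int(m["pos"]), m["ref"], m["alt"]


@dataclass(frozen=True)
class VariantRecord:
    """A single normalized variant with its annotations."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Optional[str] = None
    consequence: Optional[str] = None
    panel_freqs: Mapping[str, float] = field(default_factory=dict)
    predictions: Mapping[str, str] = field(default_factory=dict)
    hgmd: bool = False
    cadd: Optional[float] = None
    internal_af: Optional[float] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        for name, f in self.panel_freqs.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"panel frequency {name}={f} outside [0, 1]")
        if self.internal_af is not None and not (0.0 <= self.internal_af <= 1.0):
            raise ValueError(f"internal_af={self.internal_af} outside [0, 1]")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one variant."""

    sample_id: str
    gt: int  # GT_* code
    depth: Optional[int] = None
    gq: Optional[float] = None
    allele_depths: Optional[tuple[int, int]] = None  # (ref_reads, alt_reads)

    def __post_init__(self):
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.gq is not None and self.gq < 0:
            raise ValueError("gq must be >= 0")
        if self.allele_depths is not None and self.depth is not None:
            r, a = self.allele_depths
            if r >= 0 and a >= 0 and r + a > self.depth:
                raise ValueError("ref_reads + alt_reads exceeds depth")

    @property
    def is_carrier(self) -> bool:
        return self.gt in CARRIER_CODES


@dataclass(frozen=True)
class Individual:
    id: str
    father: Optional[str]
    mother: Optional[str]
    sex: int  # 1 = male, 2 = female
    affected: Optional[bool]  # None = unknown phenotype

    @property
    def is_female(self) -> bool:
        return self.sex == 2


class PedigreeSet:
    """Families, individuals, parentage, sex and affection status."""

    def __init__(self, families: Mapping[str, Iterable[Individual]]):
        self.families: dict[str, list[Individual]] = {
            fam: list(members) for fam, members in families.items()
        }
        self.individuals: dict[str, Individual] = {}
        self.family_of: dict[str, str] = {}
        for fam, members in self.families.items():
            ids = {m.id for m in members}
            for m in members:
                if m.id in self.individuals:
                    raise ValueError(f"duplicated individual id {m.id!r}")
                for parent in (m.father, m.mother):
                    if parent is not None and parent not in ids:
                        raise ValueError(
                            f"parent {parent!r} of {m.id!r} not found in family {fam!r}"
                        )
                self.individuals[m.id] = m
                self.family_of[m.id] = fam

    def affected(self, family: str) -> list[str]:
        return [m.id for m in self.families[family] if m.affected]

    def affected_all(self) -> list[str]:
        return [i.id for i in self.individuals.values() if i.affected]

    def __len__(self) -> int:
        return len(self.individuals)

    def __repr__(self) -> str:
        return f"PedigreeSet({len(self.families)} families, {len(self)} individuals)"


class PathwayCollection:
    """Named gene sets plus the background gene universe.

    Gene symbols are uppercased; every set must be non-empty and, after
    universe resolution, a subset of the universe.
    """

    def __init__(self, sets: Mapping[str, Iterable[str]], universe: Iterable[str]):
        self.sets: dict[str, frozenset[str]] = {}
        for name, genes in sets.items():
            genes = frozenset(g.upper() for g in genes)
            if not genes:
                raise ValueError(f"pathway {name!r} is empty")
            self.sets[name] = genes
        self.universe: frozenset[str] = frozenset(g.upper() for g in universe)
        for name, genes in self.sets.items():
            missing = genes - self.universe
            if missing:
                raise ValueError(
                    f"pathway {name!r} has genes outside the universe: {sorted(missing)[:5]}"
                )

    def restrict_universe(self, universe: Iterable[str]) -> "PathwayCollection":
        """Re-resolve against a new universe, intersecting each set with it."""
        universe = frozenset(g.upper() for g in universe)
        sets = {}
        for name, genes in self.sets.items():
            kept = genes & universe
            if kept:
                sets[name] = kept
        return PathwayCollection(sets, universe)

    def __repr__(self) -> str:
        return f"PathwayCollection({len(self.sets)} sets, universe={len(self.universe)})"


@dataclass
class CohortSummary:
    """Cohort-level QC metrics.

    ``het_hom_ratio`` is the per-sample heterozygous / homozygous-alt call
    ratio averaged over samples for which it is defined (``None`` when no
    sample has a homozygous-alt call).  ``titv`` is the transition /
    transversion ratio over SNVs only and is ``None`` (flagged undefined)
    when there are no transversions.
    """

    n_variants: int
    n_samples: int
    het_hom_ratio: Optional[float]
    het_hom_median: Optional[float]
    titv: Optional[float]
    n_transitions: int = 0
    n_transversions: int = 0

    @property
    def titv_undefined(self) -> bool:
        return self.titv is None


class CohortTable:
    """Normalized variant x sample matrix with per-call QC fields.

    Parameters
    ----------
    variants : pd.DataFrame
        Indexed by variant key; must contain columns ``chrom, pos, ref,
        alt`` and may contain ``gene, consequence, sift, polyphen, hgmd,
        cadd, internal_af`` plus one ``af_<PANEL>`` column per reference
        panel.
    samples : list of str
    gt, dp, gq, ad_ref, ad_alt : int arrays of shape (n_variants, n_samples)
        ``gt`` uses the GT_* codes; ``dp``/``gq``/``ad_*`` use -1 for
        absent values.
    annotations : optional mapping source-name -> DataFrame
        Alternative annotation frames with the same index as ``variants``.
    """

    def __init__(
        self,
        variants: pd.DataFrame,
        samples: list[str],
        gt: np.ndarray,
        dp: Optional[np.ndarray] = None,
        gq: Optional[np.ndarray] = None,
        ad_ref: Optional[np.ndarray] = None,
        ad_alt: Optional[np.ndarray] = None,
        annotations: Optional[dict[str, pd.DataFrame]] = None,
    ):
        n, s = len(variants), len(samples)
        if not variants.index.is_unique:
            dup = variants.index[variants.index.duplicated()][:3].tolist()
            raise ValueError(f"duplicate variant keys: {dup}")

        def _full(a, fill):
            if a is None:
                return np.full((n, s), fill, dtype=np.int32)
            a = np.asarray(a, dtype=np.int32)
            if a.shape != (n, s):
                raise ValueError(f"matrix shape {a.shape} != ({n}, {s})")
            return a

        self.variants = variants
        self.samples = list(samples)
        self.gt = _full(gt, GT_MISSING)
        self.dp = _full(dp, -1)
        self.gq = _full(gq, -1)
        self.ad_ref = _full(ad_ref, -1)
        self.ad_alt = _full(ad_alt, -1)
        self.annotations: dict[str, pd.DataFrame] = dict(annotations or {})
        self._sample_index = {sid: j for j, sid in enumerate(self.samples)}

    # -- basic accessors ------------------------------------------------
    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def keys(self) -> pd.Index:
        return self.variants.index

    def panel_names(self) -> list[str]:
        return [c[3:] for c in self.variants.columns if c.startswith("af_")]

    def sample_index(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def annotation_frame(self, source: Optional[str] = None) -> pd.DataFrame:
        """Annotation columns from ``source`` (default: the primary table)."""
        if source is None:
            return self.variants
        return self.annotations[source]

    # -- record-level views --------------------------------------------
    def record(self, key: str, source: Optional[str] = None) -> VariantRecord:
        base = self.variants.loc[key]
        row = base if source is None else self.annotation_frame(source).loc[key]
        panel_freqs = {}
        frame = row if source is None else row
        for col in frame.index:
            if col.startswith("af_") and pd.notna(frame[col]):
                panel_freqs[col[3:]] = float(frame[col])
        predictions = {}
        for src in ("sift", "polyphen"):
            v = row.get(src)
            if isinstance(v, str) and v:
                predictions[src] = v
        cadd = row.get("cadd")
        iaf = row.get("internal_af")
        return VariantRecord(
            chrom=str(base["chrom"]),
            pos=int(base["pos"]),
            ref=str(base["ref"]),
            alt=str(base["alt"]),
            gene=(str(base["gene"]) if pd.notna(base.get("gene")) else None),
            consequence=(str(row["consequence"]) if pd.notna(row.get("consequence")) else None),
            panel_freqs=panel_freqs,
            predictions=predictions,
            hgmd=bool(row.get("hgmd", False)),
            cadd=(float(cadd) if pd.notna(cadd) else None),
            internal_af=(float(iaf) if pd.notna(iaf) else None),
        )

    def call(self, key: str, sample_id: str) -> GenotypeCall:
        i = self.variants.index.get_loc(key)
        j = self._sample_index[sample_id]
        dp = int(self.dp[i, j])
        gq = int(self.gq[i, j])
        r, a = int(self.ad_ref[i, j]), int(self.ad_alt[i, j])
        return GenotypeCall(
            sample_id=sample_id,
            gt=int(self.gt[i, j]),
            depth=(dp if dp >= 0 else None),
            gq=(gq if gq >= 0 else None),
            allele_depths=((r, a) if r >= 0 and a >= 0 else None),
        )

    def calls(self, key: str) -> list[GenotypeCall]:
        return [self.call(key, s) for s in self.samples]

    # -- manipulation ---------------------------------------------------
    def subset_variants(self, keys) -> "CohortTable":
        """Row-subset (and reorder) to ``keys``, keeping annotation frames aligned."""
        idx = self.variants.index.get_indexer(pd.Index(keys))
        if (idx < 0).any():
            missing = pd.Index(keys)[idx < 0][:3].tolist()
            raise KeyError(f"unknown variant keys: {missing}")
        return CohortTable(
            variants=self.variants.iloc[idx],
            samples=self.samples,
            gt=self.gt[idx],
            dp=self.dp[idx],
            gq=self.gq[idx],
            ad_ref=self.ad_ref[idx],
            ad_alt=self.ad_alt[idx],
            annotations={k: v.iloc[idx] for k, v in self.annotations.items()},
        )

    def carrier_matrix(self) -> np.ndarray:
        """Boolean (n_variants, n_samples): sample bears >= 1 alternate allele."""
        return np.isin(self.gt, CARRIER_CODES)

    def __repr__(self) -> str:
        return f"CohortTable({self.n_variants} variants x {self.n_samples} samples)"


def empty_variants_frame(panels: Iterable[str] = DEFAULT_PANELS) -> pd.DataFrame:
    cols = ["chrom", "pos", "ref", "alt", "gene"] + list(_ANNOTATION_COLUMNS)
    cols += [f"af_{p}" for p in panels]
    return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
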