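"""Synthetic multiplex-family exome cohorts with planted pathway signal.

Generates pedigrees of affected mothers/sisters, a background of exome
variants with a mixed common/low-frequency/rare allele-frequency
spectrum, Mendelian-consistent genotypes within each family, and a set
of *planted* rare, damaging, heterozygous variants shared by the
affected members of designated carrier families and clustered in one
target pathway.  Optional noise injects the QC artifacts the filter
cascade is designed to remove (low depth, low genotype quality, skewed
allele fraction) and per-annotation-source discordance, all recorded in
a truth set so every pipeline stage is testable without external data.

All randomness flows from a single integer seed through one generator
in a fixed draw order, so outputs are byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    GT_HEMI_ALT,
    GT_HET,
    GT_HOM_ALT,
    GT_REF,
    CohortTable,
    Individual,
    PathwayCollection,
    PedigreeSet,
)

CHROMS = tuple(str(c) for c in range(1, 23)) + ("X",)
_CHROM_ORDER = {c: i for i, c in enumerate(CHROMS)}
_GENE_SPAN = 20_000
_GENE_SPACING = 200_000
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

ANNOTATION_SOURCES = ("source_1", "source_2", "source_3")


def build_gene_map(n_genes: int = 2000) -> pd.DataFrame:
    """Fixed synthetic gene map: symbols, chromosome and coordinates.

    Deterministic (internal fixed seed, independent of cohort seeds) so
    the same map ships with every simulated cohort; ~4% of genes sit on
    chromosome X to exercise hemizygous calls.
    """
    rng = np.random.default_rng(104729)
    weights = np.array([23.0 - c for c in range(1, 23)] + [1.0])
    weights /= weights.sum()
    counts = np.floor(weights * n_genes).astype(int)
    counts[0] += n_genes - counts.sum()
    rows = []
    i = 0
    for chrom, count in zip(CHROMS, counts):
        for j in range(count):
            start = 1_000_000 + j * _GENE_SPACING
            rows.append(
                {
                    "gene": f"GENE{i + 1:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + _GENE_SPAN,
                }
            )
            i += 1
    df = pd.DataFrame(rows)
    # shuffle symbol order so gene ids carry no positional information
    perm = rng.permutation(len(df))
    df["gene"] = df["gene"].to_numpy()[perm]
    return df


def default_pathways(
    gene_map: pd.DataFrame, n_pathways: int = 50, genes_per_set: int = 20
) -> PathwayCollection:
    """Disjoint synthetic pathway collection over the gene map's universe."""
    rng = np.random.default_rng(7919)
    genes = gene_map["gene"].to_numpy().copy()
    rng.shuffle(genes)
    need = n_pathways * genes_per_set
    if need > len(genes):
        raise ValueError("pathway collection larger than the gene map")
    sets = {
        f"SYNTH_PATHWAY_{i + 1:02d}": genes[i * genes_per_set : (i + 1) * genes_per_set]
        for i in range(n_pathways)
    }
    return PathwayCollection(sets, gene_map["gene"])


@dataclass(frozen=True)
class PlantSpec:
    """Where and how strongly the causal signal is planted."""

    target_pathway: str = "SYNTH_PATHWAY_01"
    n_planted_genes: int = 8
    carrier_families: Optional[tuple[str, ...]] = None  # default: 4 drawn families
    carrier_pattern: str = "all_affected"  # or "subset"
    planted_maf: float = 0.001
    planted_consequence: str = "missense"

    def __post_init__(self):
        if self.carrier_pattern not in ("all_affected", "subset"):
            raise ValueError(f"unknown carrier_pattern {self.carrier_pattern!r}")
        if not (0.0 < self.planted_maf < 0.01):
            raise ValueError("planted_maf should be a rare frequency in (0, 0.01)")


@dataclass(frozen=True)
class NoiseConfig:
    """Rates of injected QC artifacts and annotation discordance."""

    low_dp_rate: float = 0.03
    low_gq_rate: float = 0.03
    af_skew_rate: float = 0.02
    annotation_discordance: float = 0.05
    internal_artifact_rate: float = 0.01
    n_sources: int = 3

    @classmethod
    def none(cls, n_sources: int = 3) -> "NoiseConfig":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, n_sources)


@dataclass
class TruthSet:
    """Ground truth for a simulated cohort.

    ``planted``: variant key -> gene / pathway / carrier family /
    intended carriers.  ``artifact_calls``: (key, sample, kind) for each
    noise-injected call, with the cascade stage expected to remove it.
    ``artifact_variants``: key -> stage for variant-level artifacts
    (internal-control frequency spikes).  ``discordant``: (key, source)
    pairs whose annotations were perturbed in that source.
    """

    planted: dict[str, dict] = field(default_factory=dict)
    artifact_calls: list[dict] = field(default_factory=list)
    artifact_variants: dict[str, str] = field(default_factory=dict)
    discordant: list[dict] = field(default_factory=list)

    @property
    def planted_genes(self) -> frozenset[str]:
        return frozenset(v["gene"] for v in self.planted.values())

    def planted_by_family(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for key, info in self.planted.items():
            out.setdefault(info["family"], set()).add(key)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted": self.planted,
                "artifact_calls": self.artifact_calls,
                "artifact_variants": self.artifact_variants,
                "discordant": self.discordant,
            },
            indent=2,
            sort_keys=True,
        )


def generate_pedigrees(
    n_families: int = 7,
    affected_per_family_range: tuple[int, int] = (2, 4),
    sisters_mode: bool = False,
    seed: int = 0,
) -> PedigreeSet:
    """Multiplex pedigrees: a founder couple plus affected females.

    In the default (multiplex) mode the mother and her daughters are the
    affected individuals (2-4 affected females per family, emulating
    recurrent-preterm-delivery families), and one unaffected son is
    included so chromosome-X hemizygous calls occur.  In ``sisters_mode``
    only the daughters are affected (sister pairs/triads with shared,
    unaffected parents).  Deterministic given the seed.
    """
    lo, hi = affected_per_family_range
    if not (1 <= lo <= hi <= 6):
        raise ValueError("affected_per_family_range must lie within [1, 6]")
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(seed)
    families: dict[str, list[Individual]] = {}
    for f in range(n_families):
        fam = f"F{f + 1:02d}"
        n_aff = int(rng.integers(lo, hi + 1))
        father = f"{fam}_FA"
        mother = f"{fam}_MO"
        members = [
            Individual(father, None, None, sex=1, affected=False),
            Individual(mother, None, None, sex=2, affected=not sisters_mode),
        ]
        n_daughters = n_aff if sisters_mode else max(n_aff - 1, 1)
        for d in range(n_daughters):
            affected = True if sisters_mode else d < n_aff - 1
            members.append(
                Individual(f"{fam}_D{d + 1}", father, mother, sex=2, affected=affected)
            )
        if not sisters_mode:
            members.append(Individual(f"{fam}_S1", father, mother, sex=1, affected=False))
        families[fam] = members
    return PedigreeSet(families)


@dataclass
class SimulatedCohort:
    table: CohortTable
    pedigree: PedigreeSet
    truth: TruthSet
    pathways: PathwayCollection
    gene_map: pd.DataFrame
    plant: PlantSpec
    noise: NoiseConfig
    seed: int

    def write_all(self, outdir) -> dict[str, str]:
        """Write VCF + PED + per-source sidecars + truth JSON; returns paths."""
        from pathlib import Path

        from .cohort_io import write_gene_sets, write_pedigree

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": str(outdir / "cohort.vcf"),
            "ped": str(outdir / "cohort.ped"),
            "gmt": str(outdir / "pathways.gmt"),
            "truth": str(outdir / "truth.json"),
        }
        write_vcf(self.table, paths["vcf"])
        write_pedigree(self.pedigree, paths["ped"])
        write_gene_sets(self.pathways, paths["gmt"])
        for src in sorted(self.table.annotations):
            p = str(outdir / f"annotations_{src}.tsv")
            write_annotation_sidecar(self.table, src, p)
            paths[f"sidecar_{src}"] = p
        with open(paths["truth"], "w") as fh:
            fh.write(self.truth.to_json())
        return paths


def simulate_cohort(
    pedigrees: PedigreeSet,
    n_background_variants: int = 100_000,
    plant: Optional[PlantSpec] = None,
    noise: Optional[NoiseConfig] = None,
    seed: int = 0,
    gene_map: Optional[pd.DataFrame] = None,
    pathways: Optional[PathwayCollection] = None,
) -> SimulatedCohort:
    """Simulate an exome cohort over the given pedigrees.

    Background variants get a mixed frequency spectrum (50% common, 25%
    low-frequency, 25% rare by default draw), Mendelian transmission
    within families, realistic depth/quality fields, and annotation
    frames for ``noise.n_sources`` sources.  Planted variants are
    heterozygous in the designated carriers.  Deterministic given seed.
    """
    plant = plant or PlantSpec()
    noise = noise or NoiseConfig()
    gene_map = gene_map if gene_map is not None else build_gene_map()
    pathways = pathways or default_pathways(gene_map)
    rng = np.random.default_rng(seed)

    if plant.target_pathway not in pathways.sets:
        raise ValueError(f"unknown target pathway {plant.target_pathway!r}")
    pathway_genes = sorted(pathways.sets[plant.target_pathway])
    if plant.n_planted_genes > len(pathway_genes):
        raise ValueError(
            f"plant requests {plant.n_planted_genes} genes but pathway "
            f"{plant.target_pathway!r} holds {len(pathway_genes)}"
        )

    fams = list(pedigrees.families)
    if plant.carrier_families is None:
        k = min(4, len(fams))
        carrier_families = sorted(rng.choice(fams, size=k, replace=False).tolist())
    else:
        carrier_families = list(plant.carrier_families)
        unknown = set(carrier_families) - set(fams)
        if unknown:
            raise ValueError(f"carrier families not in pedigree: {sorted(unknown)}")

    # ----- background variant sites -----------------------------------
    nb = n_background_variants
    gm_gene = gene_map["gene"].to_numpy()
    gm_chrom = gene_map["chrom"].to_numpy()
    gm_start = gene_map["start"].to_numpy()
    gidx = rng.integers(0, len(gene_map), nb)
    pos = gm_start[gidx] + rng.integers(0, _GENE_SPAN, nb)
    chrom = gm_chrom[gidx]
    gene = gm_gene[gidx]

    cat = rng.choice(3, size=nb, p=[0.50, 0.25, 0.25])
    f = np.empty(nb)
    f[cat == 0] = rng.uniform(0.05, 0.50, (cat == 0).sum())
    f[cat == 1] = rng.uniform(0.01, 0.05, (cat == 1).sum())
    nrare = (cat == 2).sum()
    f[cat == 2] = 10 ** rng.uniform(np.log10(5e-4), np.log10(0.01), nrare)

    is_indel = rng.random(nb) < 0.10
    bases = np.array(list("ACGT"))
    base_idx = rng.integers(0, 4, nb)
    transition = rng.random(nb) < (2.0 / 3.0)  # transition bias gives Ti/Tv ~ 2
    tv_pick = rng.integers(0, 2, nb)
    _TRANS_CODE = np.array([2, 3, 0, 1])  # A<->G, C<->T with ACGT = 0..3
    _TV_CODE = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])
    alt_idx = np.where(transition, _TRANS_CODE[base_idx], _TV_CODE[base_idx, tv_pick])
    ref = bases[base_idx].astype(object)
    alt = bases[alt_idx].astype(object)
    ind = np.flatnonzero(is_indel)
    extra = bases[rng.integers(0, 4, len(ind))]
    insertion = rng.random(len(ind)) < 0.5
    for i, e, ins in zip(ind, extra, insertion):
        if ins:
            alt[i] = ref[i] + e
        else:
            ref[i], alt[i] = ref[i] + e, ref[i]

    # resolve (chrom, pos) collisions so keys are unique
    for _ in range(20):
        dup_idx = np.flatnonzero(
            pd.DataFrame({"c": chrom, "p": pos}).duplicated(keep="first").to_numpy()
        )
        if len(dup_idx) == 0:
            break
        pos[dup_idx] += rng.integers(1, 977, len(dup_idx))
    else:
        raise RuntimeError("could not de-duplicate variant positions")

    # ----- planted variant sites --------------------------------------
    planted_genes = sorted(
        rng.choice(pathway_genes, size=plant.n_planted_genes, replace=False).tolist()
    )
    gm_by_gene = gene_map.set_index("gene")
    p_rows = []
    for g in planted_genes:
        for fam in carrier_families:
            p_rows.append((g, fam))
    np_ = len(p_rows)
    p_gene = np.array([r[0] for r in p_rows], dtype=object)
    p_fam = [r[1] for r in p_rows]
    p_chrom = gm_by_gene.loc[p_gene, "chrom"].to_numpy()
    p_start = gm_by_gene.loc[p_gene, "start"].to_numpy()
    # planted offsets sit past the background window, so keys never clash
    p_pos = p_start + _GENE_SPAN + 1 + rng.integers(0, _GENE_SPAN, np_)
    for _ in range(20):
        dup_idx = np.flatnonzero(
            pd.DataFrame({"c": p_chrom, "p": p_pos}).duplicated(keep="first").to_numpy()
        )
        if len(dup_idx) == 0:
            break
        p_pos[dup_idx] += rng.integers(1, 977, len(dup_idx))
    p_ref = np.array(["C"] * np_, dtype=object)
    p_alt = np.array(["T"] * np_, dtype=object)
    p_f = np.full(np_, plant.planted_maf)

    # ----- combine and order ------------------------------------------
    chrom = np.concatenate([chrom, p_chrom])
    pos = np.concatenate([pos, p_pos]).astype(np.int64)
    ref = np.concatenate([ref, p_ref])
    alt = np.concatenate([alt, p_alt])
    gene = np.concatenate([gene, p_gene])
    f = np.concatenate([f, p_f])
    planted_mask = np.zeros(len(pos), dtype=bool)
    planted_mask[nb:] = True

    chrom_code = pd.Categorical(chrom, categories=list(CHROMS)).codes
    order = np.lexsort((alt.astype(str), ref.astype(str), pos, chrom_code))
    chrom, pos, ref, alt, gene, f = (
        a[order] for a in (chrom, pos, ref, alt, gene, f)
    )
    planted_mask = planted_mask[order]
    planted_rows = np.flatnonzero(planted_mask)
    orig_planted = order[planted_rows] - nb  # index into p_rows

    keys = [f"{c}:{p}:{r}:{a}" for c, p, r, a in zip(chrom, pos, ref, alt)]
    n = len(keys)
    is_x = chrom == "X"

    # ----- genotypes with Mendelian transmission ----------------------
    samples: list[str] = []
    for fam in pedigrees.families:
        samples.extend(m.id for m in pedigrees.families[fam])
    s_index = {sid: j for j, sid in enumerate(samples)}
    ns = len(samples)
    gt = np.zeros((n, ns), dtype=np.int32)

    for fam in pedigrees.families:
        for m in pedigrees.families[fam]:
            j = s_index[m.id]
            male = m.sex == 1
            if m.father is None and m.mother is None:  # founder
                auto = rng.binomial(2, f)
                if male:
                    x = rng.binomial(1, f)
                    gt[:, j] = np.where(is_x, x * GT_HEMI_ALT, auto)
                else:
                    gt[:, j] = np.where(is_x, rng.binomial(2, f), auto)
            else:
                gm = gt[:, s_index[m.mother]]
                gf = gt[:, s_index[m.father]]
                # allele counts usable for transmission probability
                cm = np.where(gm == GT_HEMI_ALT, 1.0, gm / 2.0)
                t_m = (rng.random(n) < cm).astype(np.int32)
                if male:
                    auto_f = (rng.random(n) < np.where(gf == GT_HEMI_ALT, 1.0, gf / 2.0)).astype(np.int32)
                    auto = t_m + auto_f
                    gt[:, j] = np.where(is_x, t_m * GT_HEMI_ALT, auto)
                else:
                    # daughters: paternal X allele is the father's single copy
                    t_f_x = (gf == GT_HEMI_ALT).astype(np.int32)
                    t_f_auto = (rng.random(n) < np.where(gf == GT_HEMI_ALT, 1.0, gf / 2.0)).astype(np.int32)
                    t_f = np.where(is_x, t_f_x, t_f_auto)
                    gt[:, j] = t_m + t_f

    # overwrite planted rows in carrier families
    truth = TruthSet()
    for row_i, orig_i in zip(planted_rows, orig_planted):
        g, fam = p_rows[int(orig_i)]
        members = pedigrees.families[fam]
        affected = [m for m in members if m.affected]
        mother = next((m for m in members if m.mother is None and m.sex == 2), None)
        if plant.carrier_pattern == "all_affected":
            carriers = [m.id for m in affected]
        else:  # random non-empty subset of the affected
            picks = rng.random(len(affected)) < 0.6
            if not picks.any():
                picks[int(rng.integers(0, len(affected)))] = True
            carriers = [m.id for m, keep in zip(affected, picks) if keep]
        # transmitting parent must carry for Mendelian consistency
        carrier_set = set(carriers)
        if mother is not None and any(
            m.mother == mother.id for m in members if m.id in carrier_set
        ):
            carrier_set.add(mother.id)
        for m in members:
            j = s_index[m.id]
            if m.id in carrier_set:
                gt[row_i, j] = GT_HET
            elif gt[row_i, j] != GT_REF and m.id not in carrier_set:
                gt[row_i, j] = GT_REF  # keep the signal exactly where intended
        truth.planted[keys[row_i]] = {
            "gene": g,
            "pathway": plant.target_pathway,
            "family": fam,
            "carriers": sorted(carrier_set),
        }

    # ----- depth / quality / allele depths ----------------------------
    dp = rng.poisson(60, (n, ns)).astype(np.int32)
    gq = np.clip(rng.normal(85, 10, (n, ns)), 0, 99).astype(np.int32)

    def _note_artifacts(mask, kind, stage):
        for vi, sj in zip(*np.nonzero(mask)):
            truth.artifact_calls.append(
                {"key": keys[vi], "sample": samples[sj], "kind": kind, "stage": stage}
            )

    if noise.low_dp_rate > 0:
        m_dp = rng.random((n, ns)) < noise.low_dp_rate
        dp[m_dp] = rng.integers(3, 15, int(m_dp.sum()))
        _note_artifacts(m_dp & (gt > 0), "low_dp", "genotype_qc")
    if noise.low_gq_rate > 0:
        m_gq = rng.random((n, ns)) < noise.low_gq_rate
        gq[m_gq] = rng.integers(0, 20, int(m_gq.sum()))
        _note_artifacts(m_gq & (gt > 0), "low_gq", "genotype_qc")

    het = gt == GT_HET
    alt_reads = np.zeros((n, ns), dtype=np.int32)
    alt_reads[het] = rng.binomial(dp[het], 0.5)
    hom_like = (gt == GT_HOM_ALT) | (gt == GT_HEMI_ALT)
    alt_reads[hom_like] = dp[hom_like]

    if noise.af_skew_rate > 0:
        m_af = het & (rng.random((n, ns)) < noise.af_skew_rate)
        k = int(m_af.sum())
        side = rng.random(k) < 0.5
        frac = np.where(side, rng.uniform(0.02, 0.25, k), rng.uniform(0.88, 0.98, k))
        alt_reads[m_af] = np.round(dp[m_af] * frac).astype(np.int32)
        _note_artifacts(m_af, "af_skew", "alt_fraction")

    ad_alt = np.minimum(alt_reads, dp)
    ad_ref = dp - ad_alt

    # ----- annotations -------------------------------------------------
    base = pd.DataFrame(index=pd.Index(keys, name="key"))
    base["chrom"] = chrom
    base["pos"] = pos
    base["ref"] = ref
    base["alt"] = alt
    base["gene"] = gene

    snv = np.array([len(r) == 1 and len(a) == 1 for r, a in zip(ref, alt)])
    csq = np.empty(n, dtype=object)
    snv_csq = rng.choice(
        ["synonymous", "missense", "stop_gained", "splice_region", "start_lost",
         "stop_lost", "utr"],
        size=int(snv.sum()),
        p=[0.465, 0.40, 0.02, 0.05, 0.005, 0.005, 0.055],
    )
    indel_csq = rng.choice(
        ["frameshift", "inframe_indel"], size=int((~snv).sum()), p=[0.5, 0.5]
    )
    csq[snv] = snv_csq
    csq[~snv] = indel_csq
    csq[planted_mask] = plant.planted_consequence

    missense = csq == "missense"
    sift = np.full(n, None, dtype=object)
    nm = int(missense.sum())
    sift[missense] = np.where(rng.random(nm) < 0.25, "damaging", "tolerated")
    polyphen = np.full(n, None, dtype=object)
    polyphen[missense] = rng.choice(
        ["probably_damaging", "possibly_damaging", "benign"], size=nm, p=[0.12, 0.13, 0.75]
    )
    sift[planted_mask] = "damaging"
    polyphen[planted_mask] = "probably_damaging"

    hgmd = rng.random(n) < 0.0005
    hgmd[planted_mask] = False
    lof = np.isin(csq, ["stop_gained", "frameshift", "start_lost", "stop_lost"])
    cadd = np.where(
        lof, rng.normal(28, 6, n), np.where(missense, rng.normal(18, 6, n), rng.normal(4, 3, n))
    )
    cadd[planted_mask] = rng.normal(27, 2, int(planted_mask.sum()))
    cadd = np.clip(cadd, 0, 60).round(1)

    internal = np.full(n, np.nan)
    have_int = rng.random(n) < 0.4
    internal[have_int] = np.clip(
        f[have_int] * np.exp(rng.normal(0, 0.3, int(have_int.sum()))), 0, 0.999
    )
    if noise.internal_artifact_rate > 0:
        rare_rows = (f < 0.01) & ~planted_mask
        m_int = rare_rows & (rng.random(n) < noise.internal_artifact_rate)
        internal[m_int] = rng.uniform(0.03, 0.2, int(m_int.sum()))
        for vi in np.flatnonzero(m_int):
            truth.artifact_variants[keys[vi]] = "internal_control"
    internal[planted_mask] = np.nan

    base["consequence"] = csq
    base["sift"] = sift
    base["polyphen"] = polyphen
    base["hgmd"] = hgmd
    base["cadd"] = cadd
    base["internal_af"] = internal.round(6)
    for panel in ("KG", "EXAC", "ESP"):
        vals = np.clip(f * np.exp(rng.normal(0, 0.25, n)), 1e-6, 0.999)
        absent = rng.random(n) < 0.15
        vals = np.where(absent, np.nan, vals)
        vals[planted_mask] = plant.planted_maf
        base[f"af_{panel}"] = np.round(vals, 6)

    annotations: dict[str, pd.DataFrame] = {}
    ann_cols = [c for c in base.columns if c not in ("chrom", "pos", "ref", "alt", "gene")]
    for si in range(noise.n_sources):
        src = f"source_{si + 1}"
        frame = base[ann_cols].copy()
        if noise.annotation_discordance > 0:
            idx = np.flatnonzero(rng.random(n) < noise.annotation_discordance)
            s = frame["sift"].to_numpy(dtype=object)
            pp = frame["polyphen"].to_numpy(dtype=object)
            c2 = frame["consequence"].to_numpy(dtype=object)
            sd = s[idx]
            s[idx] = np.where(
                sd == "damaging", "tolerated", np.where(sd == "tolerated", "damaging", sd)
            )
            has_pp = np.array([v is not None for v in pp[idx]])
            pp[idx[has_pp]] = "benign"
            downgrade = (rng.random(len(idx)) < 0.5) & (c2[idx] == "missense")
            c2[idx[downgrade]] = "synonymous"
            truth.discordant.extend({"key": keys[vi], "source": src} for vi in idx)
            frame["sift"] = s
            frame["polyphen"] = pp
            frame["consequence"] = c2
        annotations[src] = frame

    table = CohortTable(
        variants=base,
        samples=samples,
        gt=gt,
        dp=dp,
        gq=gq,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
        annotations=annotations,
    )
    return SimulatedCohort(
        table=table,
        pedigree=pedigrees,
        truth=truth,
        pathways=pathways,
        gene_map=gene_map,
        plant=plant,
        noise=noise,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

_GT_STR = {GT_REF: "0/0", GT_HET: "0/1", GT_HOM_ALT: "1/1", GT_HEMI_ALT: "1", -1: "./."}


def _fmt_float(v) -> str:
    return format(float(v), ".6g")


def write_vcf(table: CohortTable, path) -> None:
    """Emit the cohort as a VCF 4.2 text file (primary annotations in INFO)."""
    v = table.variants
    panels = table.panel_names()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in CHROMS:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">\n')
        fh.write('##INFO=<ID=SIFT,Number=1,Type=String,Description="SIFT prediction">\n')
        fh.write('##INFO=<ID=POLYPHEN,Number=1,Type=String,Description="PolyPhen prediction">\n')
        fh.write('##INFO=<ID=HGMD,Number=0,Type=Flag,Description="HGMD-listed">\n')
        fh.write('##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD score">\n')
        fh.write('##INFO=<ID=INTERNAL_AF,Number=1,Type=Float,Description="Internal control AF">\n')
        for p in panels:
            fh.write(f'##INFO=<ID=AF_{p},Number=1,Type=Float,Description="{p} panel AF">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(table.samples) + "\n")
        cols = {c: v[c].to_numpy() for c in v.columns}
        for i in range(len(v)):
            info = [f"GENE={cols['gene'][i]}", f"CSQ={cols['consequence'][i]}"]
            for name, key in (("sift", "SIFT"), ("polyphen", "POLYPHEN")):
                val = cols[name][i]
                if isinstance(val, str) and val:
                    info.append(f"{key}={val}")
            if bool(cols["hgmd"][i]):
                info.append("HGMD")
            for name, key in (("cadd", "CADD"), ("internal_af", "INTERNAL_AF")):
                val = cols[name][i]
                if pd.notna(val):
                    info.append(f"{key}={_fmt_float(val)}")
            for p in panels:
                val = cols[f"af_{p}"][i]
                if pd.notna(val):
                    info.append(f"AF_{p}={_fmt_float(val)}")
            fields = [
                str(cols["chrom"][i]), str(cols["pos"][i]), ".", str(cols["ref"][i]),
                str(cols["alt"][i]), ".", "PASS", ";".join(info), "GT:DP:GQ:AD",
            ]
            for j in range(table.n_samples):
                fields.append(
                    f"{_GT_STR[int(table.gt[i, j])]}:{table.dp[i, j]}:"
                    f"{table.gq[i, j]}:{table.ad_ref[i, j]},{table.ad_alt[i, j]}"
                )
            fh.write("\t".join(fields) + "\n")


def write_annotation_sidecar(table: CohortTable, source: str, path) -> None:
    """Write one annotation source as a TSV keyed on (chrom, pos, ref, alt)."""
    ann = table.annotations[source]
    frame = pd.concat([table.variants[["chrom", "pos", "ref", "alt"]], ann], axis=1)
    frame.to_csv(path, sep="\t", index=False)
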