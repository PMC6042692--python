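"""Readers/writers for cohort VCFs, pedigrees, gene sets and variant tables.

VCF parsing goes through cyvcf2; multi-allelic sites are split into one
record per alternate allele and indel alleles are put in canonical
trimmed form, so that records are keyed by normalized
``chrom:pos:ref:alt`` throughout the package.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import (
    GT_HEMI_ALT,
    GT_HET,
    GT_HOM_ALT,
    GT_MISSING,
    GT_REF,
    CohortSummary,
    CohortTable,
    Individual,
    PathwayCollection,
    PedigreeSet,
    normalize_variant,
)

log = logging.getLogger(__name__)

# INFO keys recognized when annotations are carried inside the VCF
_INFO_PANELS = {"AF_KG": "KG", "AF_EXAC": "EXAC", "AF_ESP": "ESP", "AF_SISU": "SISU"}
_SIDE_CAR_KEY = ["chrom", "pos", "ref", "alt"]

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class VcfParseError(ValueError):
    pass


def _info_get(variant, key, alt_index, n_alts):
    """INFO field value, taking the alt_index'th entry for per-alt (Number=A) values."""
    val = variant.INFO.get(key)
    if val is None:
        return None
    if isinstance(val, tuple):
        return val[alt_index] if alt_index < len(val) else None
    if isinstance(val, str) and n_alts > 1 and "," in val:
        parts = val.split(",")
        return parts[alt_index] if alt_index < len(parts) else None
    return val


def read_vcf_cohort(
    path,
    annotation_sidecar=None,
    *,
    panels: Iterable[str] = ("KG", "EXAC", "ESP"),
) -> CohortTable:
    """Read a VCF 4.x into a normalized :class:`CohortTable`.

    Multi-allelic sites are split into one record per alternate allele;
    per-sample genotypes are recoded with respect to that allele (other
    alternate alleles count as reference).  DP/GQ/AD are read when
    present and marked absent (-1) otherwise.  ``annotation_sidecar``,
    if given, is a TSV keyed on (chrom, pos, ref, alt) whose annotation
    columns override those parsed from INFO (with a logged warning on
    conflicting values).
    """
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise VcfParseError(f"cannot open VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    panels = list(panels)

    rows = []
    mats: dict[str, list[list[int]]] = {k: [] for k in ("gt", "dp", "gq", "ad_ref", "ad_alt")}
    try:
        for variant in vcf:
            n_alts = len(variant.ALT)
            dp = variant.format("DP")
            gq = variant.format("GQ")
            ad = variant.format("AD")
            genotypes = variant.genotypes
            for ai, alt in enumerate(variant.ALT):
                if alt in (".", "*", "<NON_REF>"):
                    continue
                chrom, pos, ref, nalt = normalize_variant(
                    variant.CHROM, variant.POS, variant.REF, alt
                )
                key = f"{chrom}:{pos}:{ref}:{nalt}"
                row = {
                    "key": key, "chrom": chrom, "pos": pos, "ref": ref, "alt": nalt,
                    "gene": _info_get(variant, "GENE", ai, n_alts),
                    "consequence": _info_get(variant, "CSQ", ai, n_alts),
                    "sift": _info_get(variant, "SIFT", ai, n_alts),
                    "polyphen": _info_get(variant, "POLYPHEN", ai, n_alts),
                    "hgmd": variant.INFO.get("HGMD") is not None,
                    "cadd": _as_float(_info_get(variant, "CADD", ai, n_alts)),
                    "internal_af": _as_float(_info_get(variant, "INTERNAL_AF", ai, n_alts)),
                }
                for info_key, panel in _INFO_PANELS.items():
                    v = _as_float(_info_get(variant, info_key, ai, n_alts))
                    if panel in panels or v is not None:
                        row[f"af_{panel}"] = v
                rows.append(row)

                allele = ai + 1
                gtv, dpv, gqv, adr, ada = [], [], [], [], []
                for j in range(len(samples)):
                    g = genotypes[j]
                    alleles = g[:-1]  # last item is the phased flag
                    if all(a < 0 for a in alleles):
                        gtv.append(GT_MISSING)
                    elif len(alleles) == 1:  # haploid call -> hemizygous
                        gtv.append(GT_HEMI_ALT if alleles[0] == allele else GT_REF)
                    else:
                        c = sum(1 for a in alleles if a == allele)
                        gtv.append((GT_REF, GT_HET, GT_HOM_ALT)[c])
                    dpv.append(_fmt_int(dp, j))
                    gqv.append(_fmt_int(gq, j))
                    if ad is not None and ad.shape[1] > allele:
                        r, a = int(ad[j, 0]), int(ad[j, allele])
                        adr.append(r if r >= 0 else -1)
                        ada.append(a if a >= 0 else -1)
                    else:
                        adr.append(-1)
                        ada.append(-1)
                mats["gt"].append(gtv)
                mats["dp"].append(dpv)
                mats["gq"].append(gqv)
                mats["ad_ref"].append(adr)
                mats["ad_alt"].append(ada)
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"malformed VCF {path!r} near record {len(rows) + 1}: {exc}") from exc

    variants = pd.DataFrame(rows)
    if len(variants):
        dup = variants["key"].duplicated()
        if dup.any():
            raise VcfParseError(
                f"duplicate normalized variant keys in {path!r}: "
                f"{variants.loc[dup, 'key'].head(3).tolist()}"
            )
        variants = variants.set_index("key")
    else:
        variants = variants.reindex(columns=["chrom", "pos", "ref", "alt"])
        variants.index = pd.Index([], name="key")
    for p in panels:
        if f"af_{p}" not in variants.columns:
            variants[f"af_{p}"] = np.nan

    n, s = len(variants), len(samples)

    def _mat(name):
        if n == 0:
            return np.full((0, s), -1, dtype=np.int32)
        return np.asarray(mats[name], dtype=np.int32)

    table = CohortTable(
        variants=variants,
        samples=samples,
        gt=_mat("gt"),
        dp=_mat("dp"),
        gq=_mat("gq"),
        ad_ref=_mat("ad_ref"),
        ad_alt=_mat("ad_alt"),
    )
    if annotation_sidecar is not None:
        apply_sidecar(table, annotation_sidecar)
    return table


def _as_float(v):
    if v is None:
        return None
    try:
        f = float(v)
    except (TypeError, ValueError):
        return None
    return f


def _fmt_int(arr, j):
    if arr is None:
        return -1
    v = int(arr[j, 0]) if arr.ndim == 2 else int(arr[j])
    return v if v >= 0 else -1  # htslib encodes missing as INT32_MIN


def read_annotation_table(path) -> pd.DataFrame:
    """Read a sidecar annotation TSV keyed on (chrom, pos, ref, alt)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = [c for c in _SIDE_CAR_KEY if c not in df.columns]
    if missing:
        raise ValueError(f"annotation sidecar {path!r} lacks key columns {missing}")
    keys = []
    for chrom, pos, ref, alt in zip(df["chrom"], df["pos"], df["ref"], df["alt"]):
        chrom, pos, ref, alt = normalize_variant(str(chrom), int(pos), str(ref), str(alt))
        keys.append(f"{chrom}:{pos}:{ref}:{alt}")
    df = df.drop(columns=_SIDE_CAR_KEY)
    df.index = pd.Index(keys, name="key")
    dups = df.index.duplicated(keep=False)
    if dups.any():
        conflicting = df[dups].groupby(level=0).nunique()
        if (conflicting > 1).any().any():
            raise ValueError(f"sidecar {path!r}: conflicting values for duplicated keys")
        df = df[~df.index.duplicated()]
    if "hgmd" in df.columns:
        df["hgmd"] = df["hgmd"].fillna(False).astype(bool)
    return df


def apply_sidecar(table: CohortTable, sidecar) -> None:
    """Join sidecar annotations onto the cohort; sidecar wins on conflict.

    Rows whose key is absent from the cohort are dropped with a warning.
    """
    df = sidecar if isinstance(sidecar, pd.DataFrame) else read_annotation_table(sidecar)
    unknown = df.index.difference(table.variants.index)
    if len(unknown):
        warnings.warn(
            f"{len(unknown)} sidecar rows annotate variants absent from the cohort "
            f"(e.g. {unknown[:3].tolist()}); dropped"
        )
        df = df.loc[df.index.intersection(table.variants.index)]
    aligned = df.reindex(table.variants.index)
    for col in df.columns:
        if col not in table.variants.columns:
            table.variants[col] = aligned[col]
            continue
        new = aligned[col]
        old = table.variants[col]
        conflict = new.notna() & old.notna() & (new != old)
        if conflict.any():
            log.warning(
                "sidecar overrides %d conflicting values in column %r", int(conflict.sum()), col
            )
        table.variants[col] = new.where(new.notna(), old)


def attach_annotation_source(table: CohortTable, name: str, source) -> None:
    """Attach an alternative annotation export (TSV path or frame) as a named source."""
    df = source if isinstance(source, pd.DataFrame) else read_annotation_table(source)
    aligned = df.reindex(table.variants.index)
    if "hgmd" in aligned.columns:
        aligned["hgmd"] = aligned["hgmd"].fillna(False).astype(bool)
    table.annotations[name] = aligned


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------

def read_pedigree(path) -> PedigreeSet:
    """Parse a 6-column whitespace-delimited PED file.

    Columns: family, individual, father, mother, sex (1=male, 2=female),
    phenotype (2=affected, 1=unaffected, 0/-9=unknown).
    """
    families: dict[str, list[Individual]] = {}
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(f"{path}:{ln}: expected 6 columns, got {len(parts)}")
            fam, iid, father, mother, sex, pheno = parts
            if iid in seen:
                raise ValueError(f"{path}:{ln}: duplicated individual id {iid!r}")
            seen.add(iid)
            if sex not in ("1", "2"):
                raise ValueError(f"{path}:{ln}: unknown sex code {sex!r}")
            if pheno == "2":
                affected = True
            elif pheno == "1":
                affected = False
            elif pheno in ("0", "-9"):
                affected = None
            else:
                raise ValueError(f"{path}:{ln}: unknown phenotype code {pheno!r}")
            families.setdefault(fam, []).append(
                Individual(
                    id=iid,
                    father=None if father == "0" else father,
                    mother=None if mother == "0" else mother,
                    sex=int(sex),
                    affected=affected,
                )
            )
    return PedigreeSet(families)


def write_pedigree(pedigree: PedigreeSet, path) -> None:
    with open(path, "w") as fh:
        for fam in pedigree.families:
            for m in pedigree.families[fam]:
                pheno = {True: "2", False: "1", None: "0"}[m.affected]
                fh.write(
                    f"{fam}\t{m.id}\t{m.father or 0}\t{m.mother or 0}\t{m.sex}\t{pheno}\n"
                )


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def read_gene_sets(
    path,
    universe_mode: str = "union_of_sets",
    *,
    universe_file=None,
    cohort_genes: Optional[Iterable[str]] = None,
) -> PathwayCollection:
    """Read a GMT file (name, description, genes...) into a PathwayCollection.

    ``universe_mode`` is one of ``file`` (read symbols from
    ``universe_file``, one per line), ``union_of_sets``, or
    ``cohort_genes`` (use the supplied iterable; sets are intersected
    with it).
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs name, description, >=1 gene")
            name = parts[0]
            genes = {g.strip().upper() for g in parts[2:] if g.strip()}
            if not genes:
                raise ValueError(f"{path}:{ln}: gene set {name!r} is empty")
            sets[name] = genes

    if universe_mode == "union_of_sets":
        universe = set().union(*sets.values())
    elif universe_mode == "file":
        if universe_file is None:
            raise ValueError("universe_mode='file' requires universe_file")
        with open(universe_file) as fh:
            universe = {line.strip().upper() for line in fh if line.strip()}
    elif universe_mode == "cohort_genes":
        if cohort_genes is None:
            raise ValueError("universe_mode='cohort_genes' requires cohort_genes")
        universe = {g.upper() for g in cohort_genes}
        sets = {n: gs & universe for n, gs in sets.items()}
        sets = {n: gs for n, gs in sets.items() if gs}
    else:
        raise ValueError(f"unknown universe_mode {universe_mode!r}")
    return PathwayCollection(sets, universe)


def write_gene_sets(collection: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")


# ---------------------------------------------------------------------------
# Cohort QC summary
# ---------------------------------------------------------------------------

def summarize_cohort(table: CohortTable) -> CohortSummary:
    """Het/hom-alt ratio (per sample, then averaged) and SNV Ti/Tv."""
    if table.n_variants == 0:
        raise ValueError("cannot summarize an empty cohort")
    het = (table.gt == GT_HET).sum(axis=0)
    hom = (table.gt == GT_HOM_ALT).sum(axis=0)
    ratios = [h / m for h, m in zip(het, hom) if m > 0]
    het_hom = float(np.mean(ratios)) if ratios else None
    het_hom_med = float(np.median(ratios)) if ratios else None

    snv = (table.variants["ref"].str.len() == 1) & (table.variants["alt"].str.len() == 1)
    pairs = list(zip(table.variants.loc[snv, "ref"], table.variants.loc[snv, "alt"]))
    n_ti = sum(1 for p in pairs if p in TRANSITIONS)
    n_tv = len(pairs) - n_ti
    titv = (n_ti / n_tv) if n_tv > 0 else None
    return CohortSummary(
        n_variants=table.n_variants,
        n_samples=table.n_samples,
        het_hom_ratio=het_hom,
        het_hom_median=het_hom_med,
        titv=titv,
        n_transitions=n_ti,
        n_transversions=n_tv,
    )


# ---------------------------------------------------------------------------
# Variant tables (TSV round trip)
# ---------------------------------------------------------------------------

_TABLE_LEAD = ["chrom", "pos", "ref", "alt", "gene", "consequence"]


def write_variant_table(variants: pd.DataFrame, path) -> None:
    """Write a variant frame as TSV with a deterministic column order.

    The frame is indexed by variant key; extra columns (e.g. a filter
    stage disposition) are preserved.  ``read_variant_table`` round-trips
    the result.
    """
    lead = [c for c in _TABLE_LEAD if c in variants.columns]
    rest = sorted(c for c in variants.columns if c not in lead)
    out = variants[lead + rest].copy()
    out.insert(0, "key", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_variant_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    if "key" not in df.columns:
        raise ValueError(f"{path!r} is not a variant table (no 'key' column)")
    df = df.set_index("key")
    if "hgmd" in df.columns:
        df["hgmd"] = df["hgmd"].astype(bool)
    return df
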