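"""A hand-built 12-variant demonstration cohort exercising every filter.

One variant per failure mode, with boundary values on both sides of each
threshold (depth 14/15, quality 19/20, allele fractions 0.25/0.30/0.85/0.90,
panel frequencies 0.5%/2%/absent, synonymous/missense/stop-gained
consequences, internal-control frequencies high and low).  The expected
stage-by-stage survivor counts are enumerated by hand next to each row,
so the cascade can be checked against exhaustive manual enumeration.
"""

from __future__ import annotations

FIXTURE_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">
##INFO=<ID=SIFT,Number=1,Type=String,Description="SIFT prediction">
##INFO=<ID=POLYPHEN,Number=1,Type=String,Description="PolyPhen prediction">
##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD score">
##INFO=<ID=INTERNAL_AF,Number=1,Type=Float,Description="Internal control AF">
##INFO=<ID=AF_KG,Number=1,Type=Float,Description="KG panel AF">
##INFO=<ID=AF_EXAC,Number=1,Type=Float,Description="EXAC panel AF">
##INFO=<ID=AF_ESP,Number=1,Type=Float,Description="ESP panel AF">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""

#: (pos, INFO, sample call) -- all A>G SNVs on chromosome 1
FIXTURE_ROWS = [
    # v1: DP 14 -> fails genotype QC (depth just below 15)
    (100, "GENE=GA;CSQ=missense;SIFT=damaging", "0/1:14:50:7,7"),
    # v2: DP 15 / GQ 20 boundary pass; rare in two panels -> survives
    (200, "GENE=GB;CSQ=missense;SIFT=damaging;AF_KG=0.005;AF_EXAC=0.002", "0/1:15:20:8,7"),
    # v3: GQ 19 -> fails genotype QC
    (300, "GENE=GC;CSQ=missense;SIFT=damaging", "0/1:100:19:50,50"),
    # v4: alt fraction 10/40 = 0.25 -> below the window
    (400, "GENE=GD;CSQ=missense;SIFT=damaging", "0/1:40:99:30,10"),
    # v5: alt fraction 6/20 = 0.30 inclusive lower bound -> survives
    (500, "GENE=GE;CSQ=missense;SIFT=damaging", "0/1:20:80:14,6"),
    # v6: fraction 17/20 = 0.85 inclusive upper bound; stop_gained (LoF) -> survives
    (600, "GENE=GF;CSQ=stop_gained;AF_KG=0.005", "0/1:20:80:3,17"),
    # v7: fraction 18/20 = 0.90 -> above the window
    (700, "GENE=GG;CSQ=missense;SIFT=damaging", "0/1:20:80:2,18"),
    # v8: AF_KG 0.02 >= 1% -> fails rarity
    (800, "GENE=GH;CSQ=missense;SIFT=damaging;AF_KG=0.02", "0/1:40:99:20,20"),
    # v9: synonymous -> no pathogenicity category
    (900, "GENE=GI;CSQ=synonymous", "0/1:40:99:20,20"),
    # v10: missense but benign predictions -> fails damaging gate
    (1000, "GENE=GJ;CSQ=missense;SIFT=tolerated;POLYPHEN=benign", "0/1:40:99:20,20"),
    # v11: internal control AF 0.05 > 0.02 -> fails internal-control stage
    (1100, "GENE=GK;CSQ=missense;SIFT=damaging;INTERNAL_AF=0.05", "0/1:40:99:20,20"),
    # v12: hom-alt bypasses the fraction window (AD 0,40) -> survives
    (1200, "GENE=GL;CSQ=missense;SIFT=damaging;INTERNAL_AF=0.0", "1/1:40:99:0,40"),
]

#: hand enumeration of the cascade on the rows above
FIXTURE_EXPECTED_STAGES = {
    "genotype_qc": 10,       # removes v1 (DP 14), v3 (GQ 19)
    "alt_fraction": 8,       # removes v4 (0.25), v7 (0.90)
    "rarity": 7,             # removes v8 (2% in KG)
    "pathogenicity": 6,      # removes v9 (synonymous)
    "damaging": 5,           # removes v10 (benign predictions)
    "internal_control": 4,   # removes v11 (internal AF 5%)
}
FIXTURE_SURVIVOR_POSITIONS = [200, 500, 600, 1200]


def write_fixture_vcf(path):
    """Write the demonstration VCF; returns the path."""
    with open(path, "w") as fh:
        fh.write(FIXTURE_HEADER)
        for pos, info, call in FIXTURE_ROWS:
            fh.write(f"1\t{pos}\t.\tA\tG\t.\tPASS\t{info}\tGT:DP:GQ:AD\t{call}\n")
    return path
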