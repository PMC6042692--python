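import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from exofam.model import (
    GT_HEMI_ALT,
    GT_HET,
    GT_HOM_ALT,
    GT_REF,
    CohortTable,
    Individual,
    PedigreeSet,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# Hand-built 12-variant fixture exercising every cascade stage; the rows
# and the hand enumeration live in exofam.fixtures.
from exofam.fixtures import (  # noqa: F401  (re-exported for test modules)
    FIXTURE_EXPECTED_STAGES,
    FIXTURE_SURVIVOR_POSITIONS,
    write_fixture_vcf,
)


@pytest.fixture()
def fixture_vcf(tmp_path):
    return write_fixture_vcf(tmp_path / "fixture.vcf")


# ---------------------------------------------------------------------------
# Randomized small cohorts for property tests
# ---------------------------------------------------------------------------

def small_pedigree():
    """Three families: two affected sisters, a sister triad, and a mixed family."""
    return PedigreeSet(
        {
            "F1": [
                Individual("F1_FA", None, None, 1, False),
                Individual("F1_MO", None, None, 2, False),
                Individual("F1_D1", "F1_FA", "F1_MO", 2, True),
                Individual("F1_D2", "F1_FA", "F1_MO", 2, True),
            ],
            "F2": [
                Individual("F2_FA", None, None, 1, False),
                Individual("F2_MO", None, None, 2, True),
                Individual("F2_D1", "F2_FA", "F2_MO", 2, True),
                Individual("F2_D2", "F2_FA", "F2_MO", 2, True),
            ],
            "F3": [
                Individual("F3_FA", None, None, 1, False),
                Individual("F3_MO", None, None, 2, True),
                Individual("F3_D1", "F3_FA", "F3_MO", 2, True),
                Individual("F3_S1", "F3_FA", "F3_MO", 1, False),
            ],
        }
    )


def random_small_cohort(seed, n_variants=40, samples=None):
    """A random CohortTable with messy annotations for property tests."""
    rng = np.random.default_rng(seed)
    if samples is None:
        samples = [m.id for fam in small_pedigree().families.values() for m in fam]
    ns = len(samples)
    n = n_variants
    pos = np.sort(rng.choice(np.arange(100, 100000), size=n, replace=False))
    refs = np.array(list("ACGT"))[rng.integers(0, 4, n)]
    alts = np.array([np.random.default_rng(seed + i).choice([b for b in "ACGT" if b != r])
                     for i, r in enumerate(refs)])
    keys = [f"1:{p}:{r}:{a}" for p, r, a in zip(pos, refs, alts)]
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos,
            "ref": refs,
            "alt": alts,
            "gene": [f"G{int(g):02d}" for g in rng.integers(0, 12, n)],
            "consequence": rng.choice(
                ["missense", "synonymous", "stop_gained", "frameshift", "splice_region", "utr"],
                n, p=[0.4, 0.2, 0.1, 0.1, 0.1, 0.1],
            ),
            "sift": rng.choice(["damaging", "tolerated", None], n, p=[0.3, 0.4, 0.3]),
            "polyphen": rng.choice(
                ["probably_damaging", "possibly_damaging", "benign", None], n,
                p=[0.15, 0.15, 0.4, 0.3],
            ),
            "hgmd": rng.random(n) < 0.05,
            "cadd": np.round(rng.uniform(0, 40, n), 1),
            "internal_af": np.where(rng.random(n) < 0.5, rng.uniform(0, 0.1, n), np.nan),
            "af_KG": np.where(rng.random(n) < 0.7, rng.uniform(0, 0.05, n), np.nan),
            "af_EXAC": np.where(rng.random(n) < 0.7, rng.uniform(0, 0.05, n), np.nan),
            "af_ESP": np.where(rng.random(n) < 0.7, rng.uniform(0, 0.05, n), np.nan),
        },
        index=pd.Index(keys, name="key"),
    )
    gt = rng.choice([GT_REF, GT_HET, GT_HOM_ALT, GT_HEMI_ALT, -1], (n, ns),
                    p=[0.45, 0.3, 0.1, 0.05, 0.1])
    dp = rng.integers(0, 80, (n, ns))
    gq = rng.integers(0, 99, (n, ns))
    ad_alt = np.clip(rng.binomial(np.maximum(dp, 1), 0.5), 0, dp)
    ad_ref = dp - ad_alt
    missing = rng.random((n, ns)) < 0.05
    dp = np.where(missing, -1, dp)
    return CohortTable(variants, list(samples), gt, dp, gq, ad_ref, ad_alt)
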