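"""Small statistics utilities for bench-assay readouts.

Covers the two analyses that accompany this kind of variant study:
a two-group comparison reconstructed from printed summary statistics
(mean +/- SEM, n) via Welch's t-test, and relative qPCR expression by
the delta-delta-Ct method against a housekeeping gene and calibrator.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats as _st


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics for one experimental group (e.g. relative band intensity)."""

    mean: float
    sem: float
    n: int

    def __post_init__(self):
        if self.sem < 0:
            raise ValueError("sem must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def welch_t_from_summary(a: GroupSummary, b: GroupSummary) -> tuple[float, float, float]:
    """Welch two-sample t-test from (mean, SEM, n) summaries.

    Returns (t, df, two_sided_p) with
    ``t = (mean_a - mean_b) / sqrt(sem_a^2 + sem_b^2)`` and the
    Welch-Satterthwaite degrees of freedom computed from the squared
    SEMs.  When both SEMs are zero: equal means give p = 1 by
    convention, different means are degenerate (error).
    """
    se2a, se2b = a.sem**2, b.sem**2
    if se2a == 0.0 and se2b == 0.0:
        if a.mean == b.mean:
            return 0.0, float("inf"), 1.0
        raise ValueError("zero SEMs with differing means: t is undefined")
    t = (a.mean - b.mean) / math.sqrt(se2a + se2b)
    df = (se2a + se2b) ** 2 / (se2a**2 / (a.n - 1) + se2b**2 / (b.n - 1))
    p = 2.0 * float(_st.t.sf(abs(t), df))
    return t, df, p


def relative_expression_ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Fold change by the delta-delta-Ct method.

    ddCt = (Ct_target,sample - Ct_ref,sample)
         - (Ct_target,calibrator - Ct_ref,calibrator);
    fold change = 2 ** (-ddCt).  The reference gene is the housekeeping
    control measured in the same well plate.
    """
    for v in (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return 2.0 ** (-ddct)


def pairwise_welch(groups: pd.DataFrame) -> pd.DataFrame:
    """All pairwise Welch comparisons from a (group, mean, sem, n) table."""
    for col in ("group", "mean", "sem", "n"):
        if col not in groups.columns:
            raise ValueError(f"summary table lacks column {col!r}")
    summaries = {
        str(r["group"]): GroupSummary(float(r["mean"]), float(r["sem"]), int(r["n"]))
        for _, r in groups.iterrows()
    }
    rows = []
    for a, b in itertools.combinations(sorted(summaries), 2):
        t, df, p = welch_t_from_summary(summaries[a], summaries[b])
        rows.append({"group_a": a, "group_b": b, "t": t, "df": df, "p": p})
    return pd.DataFrame(rows, columns=["group_a", "group_b", "t", "df", "p"])


def ddct_from_table(
    cts: pd.DataFrame, target: str, reference: str, calibrator: str
) -> pd.DataFrame:
    """Per-sample fold changes from a long (sample, gene, ct) table.

    Ct values are averaged per (sample, gene); ``calibrator`` names the
    sample used as the comparison baseline and ``reference`` the
    housekeeping gene.
    """
    for col in ("sample", "gene", "ct"):
        if col not in cts.columns:
            raise ValueError(f"Ct table lacks column {col!r}")
    mean_ct = cts.groupby(["sample", "gene"])["ct"].mean()

    def _ct(sample, gene):
        try:
            return float(mean_ct.loc[(sample, gene)])
        except KeyError:
            raise ValueError(f"no Ct for sample {sample!r}, gene {gene!r}") from None

    cal_t, cal_r = _ct(calibrator, target), _ct(calibrator, reference)
    rows = []
    for sample in sorted(cts["sample"].unique()):
        fold = relative_expression_ddct(_ct(sample, target), _ct(sample, reference), cal_t, cal_r)
        rows.append({"sample": sample, "fold_change": fold})
    return pd.DataFrame(rows, columns=["sample", "fold_change"])
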