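"""Post-hoc stratification checks at detected QTSs.

With two subpopulations in the panel, a Pearson chi-square test compares
genotype frequencies (2 x {QQ, Qq, qq} counts, empty genotype columns
dropped with the degrees of freedom adjusted) between subpopulations at
each QTS; the per-test significance level is Bonferroni-adjusted for the
number of markers that defined the structure analysis.  An allele-count
(2 x 2) variant is available.  No continuity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import MISSING, GenotypePanel


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


@dataclass
class SubpopTestResult:
    snp: str
    table: np.ndarray  # subpop x genotype counts (before column dropping)
    statistic: float
    df: int
    p: float
    significant: bool | None = None


def subpop_genotype_chisq(
    panel: GenotypePanel,
    snp: str | int,
    subpop_labels: np.ndarray | None = None,
    table: str = "genotype",
    threshold: float | None = None,
) -> SubpopTestResult:
    """Chi-square test of genotype (or allele) frequency between subpops.

    ``table="genotype"`` uses the 2 x {QQ, Qq, qq} count table (matching a
    genotypic-frequency comparison); ``table="allele"`` collapses to allele
    counts (2 x 2).  Empty columns are dropped and df adjusted; a table
    left with fewer than two non-empty columns yields statistic 0, p 1.
    """
    labels = subpop_labels if subpop_labels is not None else panel.subpop_labels
    if labels is None:
        raise ValueError("no subpopulation labels available")
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("exactly two subpopulations required")
    idx = panel.snp_index(snp) if isinstance(snp, str) else int(snp)
    snp_id = panel.snp_ids[idx]
    codes = panel.codes[:, idx]

    counts = np.zeros((2, 3), dtype=float)
    for r, g in enumerate(groups):
        sub = codes[labels == g]
        sub = sub[sub != MISSING]
        if sub.size == 0:
            raise ValueError(f"subpopulation {g} has no non-missing calls at {snp_id}")
        for c, code in enumerate((2, 1, 0)):  # QQ, Qq, qq
            counts[r, c] = np.sum(sub == code)

    if table == "allele":
        work = np.column_stack(
            [2 * counts[:, 0] + counts[:, 1], 2 * counts[:, 2] + counts[:, 1]]
        )
    elif table == "genotype":
        work = counts
    else:
        raise ValueError("table must be 'genotype' or 'allele'")

    nonzero = work.sum(axis=0) > 0
    work = work[:, nonzero]
    if work.shape[1] < 2:
        stat, df, p = 0.0, 0, 1.0
    else:
        stat, p, df, _exp = stats.chi2_contingency(work, correction=False)
    return SubpopTestResult(
        snp=snp_id,
        table=counts,
        statistic=float(stat),
        df=int(df),
        p=float(p),
        significant=None if threshold is None else bool(p < threshold),
    )


def subpop_scan(
    panel: GenotypePanel,
    snp_ids: list[str],
    subpop_labels: np.ndarray | None = None,
    alpha: float = 0.05,
    n_structure_markers: int | None = None,
    table: str = "genotype",
) -> pd.DataFrame:
    """Chi-square stratification check over a set of QTSs.

    The Bonferroni threshold divides ``alpha`` by ``n_structure_markers``
    (the marker count behind the structure analysis; defaults to the number
    of SNPs tested).
    """
    m = n_structure_markers or len(snp_ids)
    thr = bonferroni_threshold(alpha, m)
    rows = []
    for s in snp_ids:
        res = subpop_genotype_chisq(panel, s, subpop_labels, table=table, threshold=thr)
        rows.append(
            {
                "snp": res.snp,
                "statistic": res.statistic,
                "df": res.df,
                "p": res.p,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)
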