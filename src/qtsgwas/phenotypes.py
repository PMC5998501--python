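"""Phenotype preparation: fatty-acid normalization, replicate QC, trait
matrices and phenotypic correlations.

Fatty-acid contents from gas chromatography are quantified by internal
normalization, X_i = A_i * 100 / sum(A): each peak area as a percentage of
the total peak area of all ingredients.  Replicate agreement is judged by
the rule that the absolute difference of two replications must be below 10%
of their arithmetic mean; the check is advisory (it flags, it does not
drop).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import validate_phenotypes


def internal_normalization(areas: dict[str, float] | pd.Series) -> dict[str, float]:
    """Peak areas -> percentages of total area, order preserved.

    Raises on all-zero (or negative-total) areas.
    """
    items = list(areas.items())
    total = float(sum(v for _k, v in items))
    if total <= 0:
        raise ValueError("total peak area must be positive")
    if any(v < 0 for _k, v in items):
        raise ValueError("peak areas must be >= 0")
    return {k: 100.0 * v / total for k, v in items}


def normalize_chromatograms(df: pd.DataFrame) -> pd.DataFrame:
    """Row-wise internal normalization of a chromatogram table.

    ``df`` columns: accession, rep, then one peak-area column per fatty
    acid.  Returns the same layout with percentages.
    """
    meta = [c for c in ("accession", "rep") if c in df.columns]
    acids = [c for c in df.columns if c not in meta]
    out = df[meta].copy()
    totals = df[acids].sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("every chromatogram needs a positive total area")
    for c in acids:
        out[c] = 100.0 * df[c] / totals
    return out


def replicate_qc(v1: float, v2: float, tolerance: float = 0.10) -> tuple[bool, str]:
    """Check two replicate measurements for agreement.

    Passes iff |v1 - v2| < tolerance * mean(v1, v2).  Returns (passed,
    reason).  A non-positive mean with a nonzero difference fails with an
    explanatory reason.
    """
    if not (np.isfinite(v1) and np.isfinite(v2)):
        raise ValueError("replicate values must be finite")
    diff = abs(v1 - v2)
    mean = (v1 + v2) / 2.0
    if mean <= 0:
        if diff == 0:
            return True, "identical"
        return False, "non-positive mean with nonzero difference"
    if diff < tolerance * mean:
        return True, "within tolerance"
    return False, f"difference {diff:.4g} >= {tolerance:.0%} of mean {mean:.4g}"


def build_trait_matrix(pheno: pd.DataFrame, level: str = "pooled") -> pd.DataFrame:
    """Replicate-averaged trait matrix.

    ``level="per-environment"`` returns one row per (accession, env) with
    one column per trait; ``level="pooled"`` additionally averages over
    environments to one row per accession.  Missing (accession, env, trait)
    combinations stay NaN.
    """
    if level not in ("pooled", "per-environment"):
        raise ValueError("level must be 'pooled' or 'per-environment'")
    validate_phenotypes(pheno)
    per_env = (
        pheno.groupby(["accession", "env", "trait"], sort=True)["value"].mean().unstack("trait")
    )
    if level == "per-environment":
        return per_env.reset_index()
    pooled = per_env.groupby("accession").mean()
    return pooled.reset_index()


def phenotypic_correlation(tm: pd.DataFrame, trait_a: str, trait_b: str) -> float:
    """Pearson correlation r_p between two traits across accessions.

    ``tm`` is a pooled trait matrix (one row per accession).  Requires at
    least 3 accessions with both traits and nonzero variance in each.
    """
    sub = tm[[trait_a, trait_b]].dropna()
    if len(sub) < 3:
        raise ValueError("need >= 3 accessions with both traits")
    a = sub[trait_a].to_numpy(dtype=float)
    b = sub[trait_b].to_numpy(dtype=float)
    if a.var() == 0 or b.var() == 0:
        raise ValueError("zero variance in one of the traits")
    return float(np.corrcoef(a, b)[0, 1])
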