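"""Generalized multifactor dimensionality reduction (GMDR) prescreening.

Stage-one filter before association mapping: candidate SNPs are ranked by a
cross-validated classification statistic on multilocus genotype cells.  For
a quantitative trait the GMDR score is the residual of the phenotype under
the null model — grand-mean centering, or environment-stratified centering
when the environment covariate is included.  Accessions are binned into
multilocus genotype cells; a cell is labeled high-risk when its mean
training score is positive; the testing statistic is the balanced accuracy
of sign(score) against the cell label on held-out folds.

Screening runs two strategies (with and without the environment covariate)
and retains the union of the per-strategy top-k SNPs, mirroring the
two-scan design of the study.  Higher-order combinations (up to three-way)
are explored exhaustively on small panels or through a marginal-beam
heuristic on large ones.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    max_order: int = 3
    cv_folds: int = 10
    include_env_covariate: bool = True
    top_k: int = 1000
    seed: int = 0
    beam_size: int = 20
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if self.max_order not in (1, 2, 3):
            raise ValueError("max_order must be in {1, 2, 3}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass
class CandidateSet:
    """Screened SNPs for one trait: union of both strategies' top-k."""

    trait: str
    retained: list[str]
    support: pd.DataFrame  # snp, support, strategy

    def __post_init__(self) -> None:
        self.retained = sorted(set(self.retained))


def compute_scores(
    pheno: pd.DataFrame, include_env_covariate: bool, trait: str | None = None
) -> pd.DataFrame:
    """Per-observation GMDR scores: null-model residuals of the trait.

    Without the covariate, scores are deviations from the grand mean; with
    it, deviations from the per-environment means (scores then sum to zero
    within every environment).
    """
    df = pheno if trait is None else pheno[pheno["trait"] == trait]
    if len(df) < 2:
        raise ValueError("need at least 2 observations")
    out = df[["accession", "env", "rep"]].copy()
    y = df["value"].to_numpy(dtype=float)
    if np.var(y) == 0:
        warnings.warn("all phenotypes identical; GMDR scores are all zero")
    if include_env_covariate:
        resid = y - df.groupby("env")["value"].transform("mean").to_numpy()
    else:
        resid = y - y.mean()
    out["score"] = resid
    return out


def _accession_scores(panel: GenotypePanel, scores: pd.DataFrame) -> np.ndarray:
    """Mean observation score per accession, in panel row order."""
    means = scores.groupby("accession")["score"].mean()
    try:
        return means.loc[list(panel.accession_ids)].to_numpy(dtype=float)
    except KeyError:
        raise ValueError("scores missing accessions present in the panel") from None


def _fold_assignment(n: int, cv_folds: int, rng) -> np.ndarray:
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % cv_folds
    return folds


def _balanced_accuracy(actual_high: np.ndarray, pred_high: np.ndarray) -> float:
    rates = []
    for cls in (True, False):
        mask = actual_high == cls
        if mask.any():
            rates.append(float((pred_high[mask] == cls).mean()))
    return float(np.mean(rates)) if rates else 0.5


def evaluate_combination(
    panel: GenotypePanel,
    scores: pd.DataFrame,
    loci: tuple[int, ...],
    cv_folds: int = 10,
    seed: int = 0,
) -> tuple[float, int]:
    """Cross-validated testing statistic for one SNP combination.

    Returns (testing statistic, cv consistency).  The statistic is the
    fold-averaged balanced accuracy of sign(score) against the trained cell
    label; consistency counts folds with accuracy above 0.5.  Cells unseen
    in training are labeled low.
    """
    loci = tuple(loci)
    if len(set(loci)) != len(loci):
        raise ValueError("loci must be distinct")
    acc_scores = _accession_scores(panel, scores)
    n = panel.n_accessions
    codes = panel.codes[:, list(loci)].astype(int)
    codes[codes == MISSING] = 3  # missing genotype is its own cell
    cells = np.zeros(n, dtype=int)
    for k in range(codes.shape[1]):
        cells = cells * 4 + codes[:, k]
    rng = np.random.default_rng(seed)
    folds = _fold_assignment(n, cv_folds, rng)
    if np.bincount(folds, minlength=cv_folds).min() < 1:
        raise ValueError("fold sizes must be >= 1")
    stats, wins = [], 0
    actual_high = acc_scores > 0
    for f in range(cv_folds):
        test = folds == f
        train = ~test
        sums = np.bincount(cells[train], weights=acc_scores[train], minlength=4 ** len(loci))
        counts = np.bincount(cells[train], minlength=4 ** len(loci))
        with np.errstate(invalid="ignore"):
            label_high = np.where(counts > 0, sums > 0, False)
        ba = _balanced_accuracy(actual_high[test], label_high[cells[test]])
        stats.append(ba)
        if ba > 0.5:
            wins += 1
    return float(np.mean(stats)), wins


def _marginal_statistics(
    panel: GenotypePanel, acc_scores: np.ndarray, cv_folds: int, rng
) -> np.ndarray:
    """Vectorized order-1 testing statistics for every SNP."""
    n, s = panel.codes.shape
    codes = panel.codes.astype(int)
    codes[codes == MISSING] = 3
    folds = _fold_assignment(n, cv_folds, rng)
    actual_high = acc_scores > 0
    n_folds_used = 0
    acc_stat = np.zeros(s)
    for f in range(cv_folds):
        test = folds == f
        train = ~test
        tp = np.zeros(s)
        tn = np.zeros(s)
        npos = float(actual_high[test].sum())
        nneg = float((~actual_high[test]).sum())
        for c in range(4):
            m_train = codes[train] == c  # (n_train, s)
            sums = m_train.T @ acc_scores[train]
            counts = m_train.sum(axis=0)
            label_high = (counts > 0) & (sums > 0)  # (s,)
            m_test = codes[test] == c
            tp += m_test[actual_high[test]].sum(axis=0) * label_high
            tn += m_test[~actual_high[test]].sum(axis=0) * (~label_high)
        rates = []
        if npos > 0:
            rates.append(tp / npos)
        if nneg > 0:
            rates.append(tn / nneg)
        ba = np.mean(rates, axis=0)
        acc_stat += ba
        n_folds_used += 1
    return acc_stat / n_folds_used


def _strategy_support(
    panel: GenotypePanel,
    pheno: pd.DataFrame,
    config: ScreenConfig,
    include_env: bool,
    trait: str | None,
    seed: int,
) -> pd.DataFrame:
    scores = compute_scores(pheno, include_env, trait)
    acc_scores = _accession_scores(panel, scores)
    rng = np.random.default_rng(seed)
    support = _marginal_statistics(panel, acc_scores, config.cv_folds, rng)
    support = support.copy()

    if config.max_order >= 2:
        if config.exhaustive:
            pool = list(range(panel.n_snps))
        else:
            pool = list(np.argsort(support)[::-1][: config.beam_size])
        for order in range(2, config.max_order + 1):
            for combo in combinations(sorted(pool), order):
                stat, _cons = evaluate_combination(
                    panel, scores, combo, cv_folds=config.cv_folds, seed=seed
                )
                for snp in combo:
                    support[snp] = max(support[snp], stat)
    strategy = "env_covariate" if include_env else "no_covariate"
    return pd.DataFrame({"snp": panel.snp_ids, "support": support, "strategy": strategy})


def screen_snps(
    panel: GenotypePanel,
    pheno: pd.DataFrame,
    config: ScreenConfig | None = None,
    trait: str | None = None,
) -> CandidateSet:
    """Two-strategy GMDR screen; returns the union of per-strategy top-k.

    Strategy one ignores the environment; strategy two includes it as a
    covariate.  Within each strategy SNPs are ranked by their best testing
    statistic over all evaluated combinations containing them.
    """
    config = config or ScreenConfig()
    trait_name = trait or str(pheno["trait"].iloc[0])
    top_k = config.top_k
    if top_k > panel.n_snps:
        warnings.warn("top_k exceeds SNP count; retaining all SNPs")
        top_k = panel.n_snps
    frames, retained = [], []
    for k, include_env in enumerate((False, True)):
        sup = _strategy_support(
            panel, pheno, config, include_env, trait, seed=config.seed + k
        )
        frames.append(sup)
        ranked = sup.sort_values(["support", "snp"], ascending=[False, True])
        retained += ranked["snp"].head(top_k).tolist()
    return CandidateSet(
        trait=trait_name, retained=retained, support=pd.concat(frames, ignore_index=True)
    )
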