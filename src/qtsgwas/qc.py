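"""SNP quality control, LD pruning and LD-decay summaries.

Filtering rules (a SNP violating any rule is removed):

* total sequencing depth above ``depth_max`` or below ``depth_min`` —
  applied only when the panel carries a per-SNP ``depth`` column;
* two adjacent SNPs closer than ``min_adjacent_bp`` — both members of the
  offending adjacency are removed (conservative symmetric reading);
* call rate below ``call_rate_min``;
* heterozygote fraction above ``het_max``;
* minor allele frequency below ``maf_min``.

LD is the squared Pearson correlation of 0/1/2 code vectors over
pairwise-complete accessions.  Pruning is a greedy left-to-right pass per
chromosome against the retained set within a sliding window; the decay
summary bins intrachromosomal pairwise r2 by physical distance and reports
the half-decay distance (first bin whose mean r2 drops to half the maximum
binned mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class QCConfig:
    depth_max: float = 6500.0
    depth_min: float = 60.0
    min_adjacent_bp: int = 5
    call_rate_min: float = 0.70
    het_max: float = 0.30
    maf_min: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.call_rate_min <= 1:
            raise ValueError("call_rate_min must be in (0, 1]")
        if not 0 < self.het_max <= 1:
            raise ValueError("het_max must be in (0, 1]")
        if not 0 < self.maf_min < 0.5:
            raise ValueError("maf_min must be in (0, 0.5)")


def apply_snp_filters(panel: GenotypePanel, qc: QCConfig | None = None):
    """Apply the SNP QC rules; returns (filtered panel, report).

    The report is a DataFrame with one row per rule (``rule``,
    ``n_removed``) plus a ``survivors`` row.  A SNP can count under several
    rules.  The depth rule is skipped (with a log message) when the panel
    has no depth metadata.
    """
    if panel.n_snps == 0:
        raise ValueError("empty panel")
    qc = qc or QCConfig()
    n = panel.n_snps
    viol = {}

    if "depth" in panel.snps.columns:
        depth = panel.snps["depth"].to_numpy(dtype=float)
        viol["depth"] = (depth > qc.depth_max) | (depth < qc.depth_min)
    else:
        logger.warning("no depth metadata; depth rule skipped")
        viol["depth"] = np.zeros(n, dtype=bool)

    adj = np.zeros(n, dtype=bool)
    chrom = panel.snps["chrom"].to_numpy()
    pos = panel.snps["pos"].to_numpy()
    same = chrom[1:] == chrom[:-1]
    close = (pos[1:] - pos[:-1]) < qc.min_adjacent_bp
    bad_gap = same & close
    adj[:-1] |= bad_gap
    adj[1:] |= bad_gap
    viol["adjacent"] = adj

    viol["call_rate"] = panel.call_rate() < qc.call_rate_min
    with np.errstate(invalid="ignore"):
        viol["heterozygosity"] = np.nan_to_num(panel.het_rate()) > qc.het_max
        viol["maf"] = np.nan_to_num(panel.maf(), nan=0.0) < qc.maf_min

    any_viol = np.zeros(n, dtype=bool)
    for mask in viol.values():
        any_viol |= mask
    report = pd.DataFrame(
        {
            "rule": list(viol) + ["survivors"],
            "n_removed": [int(m.sum()) for m in viol.values()] + [int((~any_viol).sum())],
        }
    )
    return panel.take_snps(~any_viol), report


def pairwise_r2(panel: GenotypePanel, i: int, j: int) -> float:
    """Squared Pearson correlation of two SNPs' 0/1/2 code vectors.

    Missing codes are excluded pairwise.  Requires >= 2 complete accessions
    and nonzero variance at both loci.
    """
    gi = panel.codes[:, i].astype(float)
    gj = panel.codes[:, j].astype(float)
    ok = (gi != MISSING) & (gj != MISSING)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 pairwise-complete accessions")
    gi, gj = gi[ok], gj[ok]
    if gi.var() == 0 or gj.var() == 0:
        raise ValueError("zero variance at one of the loci")
    r = np.corrcoef(gi, gj)[0, 1]
    return float(r**2)


def _r2_matrix_complete(codes: np.ndarray) -> np.ndarray:
    """r2 matrix for a block of SNPs, treating -1 as missing pairwise."""
    g = codes.astype(float)
    g[codes == MISSING] = np.nan
    mask = ~np.isnan(g)
    gz = np.nan_to_num(g)
    n = mask.T.astype(float) @ mask
    s = gz.T @ mask
    ss = (gz**2).T @ mask
    cross = gz.T @ gz
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_i = s / n
        cov = cross / n - mean_i * mean_i.T
        var_i = ss / n - mean_i**2
        r2 = cov**2 / (var_i * var_i.T)
    return r2


def ld_prune(panel: GenotypePanel, window_snps: int = 50, r2_max: float = 0.1) -> GenotypePanel:
    """Greedy windowed LD pruning.

    Left-to-right per chromosome: a SNP is dropped when its r2 with any of
    the preceding ``window_snps`` *retained* SNPs exceeds ``r2_max``; order
    is preserved.
    """
    if window_snps < 1:
        raise ValueError("window_snps must be >= 1")
    keep = np.zeros(panel.n_snps, dtype=bool)
    chrom = panel.snps["chrom"].to_numpy()
    g = panel.codes.astype(float)
    g[panel.codes == MISSING] = np.nan
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        retained: list[int] = []
        for snp in idx:
            window = retained[-window_snps:]
            drop = False
            for other in window:
                ok = ~np.isnan(g[:, snp]) & ~np.isnan(g[:, other])
                if ok.sum() < 2:
                    continue
                a, b = g[ok, snp], g[ok, other]
                if a.var() == 0 or b.var() == 0:
                    continue
                if np.corrcoef(a, b)[0, 1] ** 2 > r2_max:
                    drop = True
                    break
            if not drop:
                retained.append(snp)
                keep[snp] = True
    return panel.take_snps(keep)


@dataclass
class LDResult:
    """Binned LD-decay curve and half-decay distance.

    ``curve`` columns: bin_start, bin_end, mean_r2, n_pairs.  ``pairs`` is
    the raw (snp_i, snp_j, distance, r2) table.
    """

    pairs: pd.DataFrame
    curve: pd.DataFrame
    half_decay_bp: float


def ld_decay(panel: GenotypePanel, max_dist: float = 500_000, bin_width: float = 5_000) -> LDResult:
    """Intrachromosomal pairwise r2 binned by distance.

    ``half_decay_bp`` is the midpoint of the first bin whose mean r2 is at
    most half the maximum binned mean r2.
    """
    chrom = panel.snps["chrom"].to_numpy()
    pos = panel.snps["pos"].to_numpy()
    rec = []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        if idx.size < 2:
            continue
        r2m = _r2_matrix_complete(panel.codes[:, idx])
        p = pos[idx]
        ii, jj = np.triu_indices(idx.size, k=1)
        dist = p[jj] - p[ii]
        ok = (dist <= max_dist) & np.isfinite(r2m[ii, jj])
        rec.append(
            pd.DataFrame(
                {
                    "snp_i": idx[ii[ok]],
                    "snp_j": idx[jj[ok]],
                    "distance": dist[ok],
                    "r2": r2m[ii[ok], jj[ok]],
                }
            )
        )
    if not rec:
        raise ValueError("no intra-chromosomal pairs within max_dist")
    pairs = pd.concat(rec, ignore_index=True)
    edges = np.arange(0, max_dist + bin_width, bin_width)
    which = np.clip(np.digitize(pairs["distance"], edges) - 1, 0, len(edges) - 2)
    grp = pairs.groupby(which)["r2"]
    curve = pd.DataFrame(
        {
            "bin_start": edges[grp.mean().index.to_numpy()],
            "bin_end": edges[grp.mean().index.to_numpy() + 1],
            "mean_r2": grp.mean().to_numpy(),
            "n_pairs": grp.size().to_numpy(),
        }
    )
    half = curve["mean_r2"].max() / 2.0
    below = curve[curve["mean_r2"] <= half]
    if below.empty:
        half_bp = float(curve["bin_end"].iloc[-1])
    else:
        row = below.iloc[0]
        half_bp = float((row["bin_start"] + row["bin_end"]) / 2.0)
    return LDResult(pairs=pairs, curve=curve, half_decay_bp=half_bp)
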