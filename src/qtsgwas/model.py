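"""Full QTS model: genome scans, permutation thresholds, Gibbs estimation.

The full model expresses a replicated multi-environment phenotype as

    y = mu + genetic fixed effects (a, d, aa, ad, da, dd per selected QTS
        or QTS pair) + random environment effect + random per-(effect,
        environment) interactions (ae, de, aae, ade, dae, dde) + residual.

Scanning is two-stage: 1-D and 2-D scans use a fast approximation in which
the environment enters as fixed blocks and the joint effect of interest is
tested with a partial F statistic against the residual; experiment-wise
thresholds come from within-environment permutation of the
accession-to-phenotype assignment.  The final model is estimated by a Gibbs
sampler with flat priors on fixed effects and weak inverse-gamma priors on
the variance components; point estimates are posterior means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coding import EPISTASIS_CLASSES, CodedGenotypes
from .heritability import HeritabilityReport, effect_heritability

logger = logging.getLogger(__name__)

_LN10 = np.log(10.0)


def neglog10_p_from_z(z: float) -> float:
    """-log10 of the two-sided normal p-value, safe for very large |z|."""
    return float(-(stats.norm.logsf(abs(z)) + np.log(2.0)) / _LN10)


# ---------------------------------------------------------------------------
# observation alignment
# ---------------------------------------------------------------------------


def align_observations(coded: CodedGenotypes, pheno: pd.DataFrame, trait: str | None = None):
    """Map a long phenotype table onto coded genotype rows.

    Returns (y, acc_idx, env_idx, n_envs) with env_idx 0-based.
    """
    df = pheno
    if trait is not None:
        df = df[df["trait"] == trait]
    elif df["trait"].nunique() > 1:
        raise ValueError("phenotype table holds several traits; pass trait=")
    if df.empty:
        raise ValueError("no phenotype observations")
    y = df["value"].to_numpy(dtype=float)
    env_idx = df["env"].to_numpy(dtype=int) - 1
    return y, df["accession"].to_numpy(), env_idx, int(env_idx.max()) + 1


def _expand(coded: CodedGenotypes, accessions: np.ndarray, acc_ids: list[str]) -> np.ndarray:
    lookup = {a: i for i, a in enumerate(acc_ids)}
    try:
        return np.array([lookup[a] for a in accessions])
    except KeyError as e:
        raise ValueError(f"phenotyped accession {e.args[0]!r} not in panel") from None


def _impute_columns(x: np.ndarray) -> np.ndarray:
    """Mean-impute NaNs per column (scan stage only)."""
    x = x.copy()
    mean = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = np.take(mean, idx[1])
    return x


def _center_within_env(mat: np.ndarray, env_idx: np.ndarray, n_envs: int) -> np.ndarray:
    """Remove per-environment means (absorbs environment fixed blocks)."""
    out = np.asarray(mat, dtype=float).copy()
    for h in range(n_envs):
        rows = env_idx == h
        out[rows] = out[rows] - out[rows].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# 1-D scan
# ---------------------------------------------------------------------------


class _Scan1DWorkspace:
    """Precomputed per-SNP Gram matrices for repeated 1-D scans.

    Joint F test of (a, d) per SNP on environment-centered data; SNPs whose
    dominance column is degenerate (no heterozygotes, or collinear) fall
    back to the additive-only 1-df test.
    """

    def __init__(self, coded: CodedGenotypes, acc_rows: np.ndarray, env_idx: np.ndarray, n_envs: int):
        xa = _impute_columns(coded.x_a)[acc_rows]
        xd = _impute_columns(coded.x_d)[acc_rows]
        self.xa = _center_within_env(xa, env_idx, n_envs)
        self.xd = _center_within_env(xd, env_idx, n_envs)
        self.gaa = (self.xa**2).sum(axis=0)
        self.gad = (self.xa * self.xd).sum(axis=0)
        self.gdd = (self.xd**2).sum(axis=0)
        self.det = self.gaa * self.gdd - self.gad**2
        scale = np.maximum(self.gaa * self.gdd, 1e-300)
        self.joint = self.det > 1e-10 * scale
        self.n_obs = self.xa.shape[0]
        self.n_envs = n_envs
        self.env_idx = env_idx

    def f_stats(self, y_centered: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """F statistics for all SNPs; y_centered is (n_obs,) or (n_obs, P).

        Returns (F, df1, df2) with F of shape (n_snps,) or (n_snps, P).
        """
        yc = np.atleast_2d(y_centered.T).T  # (n_obs, P)
        ay = self.xa.T @ yc  # (S, P)
        dy = self.xd.T @ yc
        sst = (yc**2).sum(axis=0)  # (P,)
        with np.errstate(invalid="ignore", divide="ignore"):
            ssr_joint = (
                self.gdd[:, None] * ay**2
                - 2.0 * self.gad[:, None] * ay * dy
                + self.gaa[:, None] * dy**2
            ) / self.det[:, None]
            ssr_add = ay**2 / np.where(self.gaa > 0, self.gaa, np.nan)[:, None]
        ssr = np.where(self.joint[:, None], ssr_joint, ssr_add)
        ssr = np.nan_to_num(ssr)
        df1 = np.where(self.joint, 2.0, 1.0)
        df2 = self.n_obs - self.n_envs - df1
        sse = np.maximum(sst[None, :] - ssr, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = (ssr / df1[:, None]) / np.where(sse > 0, sse, np.nan) * df2[:, None]
        f = np.nan_to_num(f, nan=np.inf, posinf=np.inf)
        out = f if y_centered.ndim > 1 else f[:, 0]
        return out, df1, df2


def scan_1d_all(coded: CodedGenotypes, pheno: pd.DataFrame, trait: str | None = None) -> pd.DataFrame:
    """1-D genome scan: joint (a, d) partial F test for every SNP.

    Environment enters as fixed blocks; with >= 2 environments a joint test
    of the additive- and dominance-by-environment interaction columns is
    reported alongside (``f_gxe``, ``p_gxe``).
    """
    y, accessions, env_idx, n_envs = align_observations(coded, pheno, trait)
    acc_rows = _expand(coded, accessions, _acc_ids(coded, pheno, trait))
    ws = _Scan1DWorkspace(coded, acc_rows, env_idx, n_envs)
    yc = _center_within_env(y, env_idx, n_envs)
    f, df1, df2 = ws.f_stats(yc)
    p = stats.f.sf(f, df1, df2)
    p = np.clip(p, 1e-300, 1.0)
    out = pd.DataFrame(
        {
            "snp": coded.snp_ids,
            "statistic": f,
            "df1": df1,
            "df2": df2,
            "p": p,
            "neglog10p": -np.log10(p),
        }
    )
    if n_envs >= 2:
        fg, pg = _gxe_scan_1d(ws, yc)
        out["f_gxe"] = fg
        out["p_gxe"] = pg
    return out


def _acc_ids(coded: CodedGenotypes, pheno: pd.DataFrame, trait):
    # accession row order of the coded panel is positional; phenotype
    # accessions are matched by name against this list
    return getattr(coded, "accession_ids", None) or _infer_ids(coded, pheno, trait)


def _infer_ids(coded, pheno, trait):
    # coded genotypes don't carry accession ids; assume the phenotype table
    # uses "acc<i>" ids matching panel row order, else positional ints
    df = pheno if trait is None else pheno[pheno["trait"] == trait]
    uniq = pd.unique(df["accession"])
    if len(uniq) > coded.n_accessions:
        raise ValueError("more phenotyped accessions than panel rows")
    return [f"acc{i + 1}" for i in range(coded.n_accessions)]


def _gxe_scan_1d(ws: _Scan1DWorkspace, yc: np.ndarray):
    """Joint F test of xA*env and xD*env interaction columns per SNP."""
    n_envs, env_idx = ws.n_envs, ws.env_idx
    fs, ps = [], []
    sst = float((yc**2).sum())
    for s in range(ws.xa.shape[1]):
        base = [ws.xa[:, s]] + ([ws.xd[:, s]] if ws.joint[s] else [])
        inter = []
        for h in range(1, n_envs):
            ind = (env_idx == h).astype(float)
            for col in base:
                inter.append(_center_within_env(col * ind, env_idx, n_envs))
        X_red = np.column_stack(base)
        X_full = np.column_stack(base + inter)
        ssr_red = _ssr(X_red, yc)
        ssr_full = _ssr(X_full, yc)
        df1 = len(inter)
        df2 = ws.n_obs - n_envs - X_full.shape[1]
        sse = max(sst - ssr_full, 0.0)
        f = ((ssr_full - ssr_red) / df1) / (sse / df2) if sse > 0 and df1 > 0 else np.inf
        fs.append(f)
        ps.append(float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0)
    return np.array(fs), np.array(ps)


def _ssr(X: np.ndarray, y: np.ndarray) -> float:
    q, _r = np.linalg.qr(X)
    proj = q.T @ y
    return float((proj**2).sum())


def scan_1d(coded: CodedGenotypes, pheno: pd.DataFrame, locus: int | str, trait: str | None = None) -> dict:
    """Single-locus scan entry (see :func:`scan_1d_all`)."""
    idx = coded.index(locus) if isinstance(locus, str) else int(locus)
    res = scan_1d_all(coded, pheno, trait)
    return res.iloc[idx].to_dict()


# ---------------------------------------------------------------------------
# 2-D scan
# ---------------------------------------------------------------------------


def _pair_design(coded: CodedGenotypes, i: int, j: int, acc_rows: np.ndarray, env_idx, n_envs):
    """(reduced columns, epistasis columns kept, their class labels)."""
    xa = _impute_columns(coded.x_a[:, [i, j]])
    xd = _impute_columns(coded.x_d[:, [i, j]])
    base = [xa[:, 0], xd[:, 0], xa[:, 1], xd[:, 1]]
    epi_cols, epi_cls = [], []
    prod = {
        "aa": xa[:, 0] * xa[:, 1],
        "ad": xa[:, 0] * xd[:, 1],
        "da": xd[:, 0] * xa[:, 1],
        "dd": xd[:, 0] * xd[:, 1],
    }
    for cls in EPISTASIS_CLASSES:
        epi_cols.append(prod[cls])
        epi_cls.append(cls)
    expand = lambda c: _center_within_env(c[acc_rows], env_idx, n_envs)  # noqa: E731
    base = [expand(c) for c in base]
    epi = [expand(c) for c in epi_cols]
    # drop base columns that are degenerate, then epistasis columns that add
    # no rank (empty two-locus cells make products collinear)
    tracker = _RankTracker(base[0].shape[0])
    X_red = np.column_stack([c for c in base if tracker.try_add(c)])
    kept_cols, kept_cls = [], []
    for col, cls in zip(epi, epi_cls):
        if tracker.try_add(col):
            kept_cols.append(col)
            kept_cls.append(cls)
        else:
            logger.info("epistasis column %s degenerate for pair (%d, %d); dropped", cls, i, j)
    return X_red, kept_cols, kept_cls


class _RankTracker:
    """Incremental column-independence check via an orthonormal basis."""

    def __init__(self, n_rows: int, tol: float = 1e-8):
        self.q = np.empty((n_rows, 0))
        self.tol = tol

    def try_add(self, col: np.ndarray) -> bool:
        norm = np.linalg.norm(col)
        if norm == 0:
            return False
        resid = col - self.q @ (self.q.T @ col)
        # re-orthogonalize once for numerical safety
        resid = resid - self.q @ (self.q.T @ resid)
        rnorm = np.linalg.norm(resid)
        if rnorm <= self.tol * norm:
            return False
        self.q = np.column_stack([self.q, resid / rnorm])
        return True


def _full_rank(X: np.ndarray) -> np.ndarray:
    tracker = _RankTracker(X.shape[0])
    keep = [k for k in range(X.shape[1]) if tracker.try_add(X[:, k])]
    return X[:, keep]


def scan_2d(
    coded: CodedGenotypes,
    pheno: pd.DataFrame,
    locus_i: int | str,
    locus_j: int | str,
    trait: str | None = None,
) -> dict:
    """Two-locus scan: joint partial F test of the four epistasis terms.

    The reduced model holds both loci's main effects (plus environment
    blocks); degenerate epistasis columns are dropped and df adjusted.
    """
    i = coded.index(locus_i) if isinstance(locus_i, str) else int(locus_i)
    j = coded.index(locus_j) if isinstance(locus_j, str) else int(locus_j)
    if i == j:
        raise ValueError("loci must be distinct")
    if i > j:
        i, j = j, i
    y, accessions, env_idx, n_envs = align_observations(coded, pheno, trait)
    acc_rows = _expand(coded, accessions, _acc_ids(coded, pheno, trait))
    yc = _center_within_env(y, env_idx, n_envs)
    X_red, epi_cols, epi_cls = _pair_design(coded, i, j, acc_rows, env_idx, n_envs)
    sst = float((yc**2).sum())
    ssr_red = _ssr(X_red, yc)
    if not epi_cols:
        return {
            "snp_i": coded.snp_ids[i], "snp_j": coded.snp_ids[j],
            "statistic": 0.0, "df1": 0, "df2": 0, "p": 1.0, "neglog10p": 0.0,
            "classes": [],
        }
    X_full = np.column_stack([X_red] + epi_cols)
    ssr_full = _ssr(X_full, yc)
    df1 = len(epi_cols)
    df2 = len(yc) - n_envs - X_full.shape[1]
    sse = max(sst - ssr_full, 0.0)
    if sse <= 0 or df2 <= 0:
        f, p = np.inf, 1e-300
    else:
        f = ((ssr_full - ssr_red) / df1) / (sse / df2)
        p = float(np.clip(stats.f.sf(f, df1, df2), 1e-300, 1.0))
    return {
        "snp_i": coded.snp_ids[i], "snp_j": coded.snp_ids[j],
        "statistic": float(f), "df1": df1, "df2": df2,
        "p": p, "neglog10p": float(-np.log10(p)), "classes": epi_cls,
    }


def scan_2d_all(coded, pheno, pairs, trait: str | None = None) -> pd.DataFrame:
    return pd.DataFrame([scan_2d(coded, pheno, i, j, trait) for i, j in pairs])


# ---------------------------------------------------------------------------
# permutation thresholds
# ---------------------------------------------------------------------------


def _permutation_indices(pheno_env: np.ndarray, accessions: np.ndarray, n_perm: int, rng) -> np.ndarray:
    """(n_obs, n_perm) index matrix permuting accession-to-phenotype
    assignment within each environment.  With balanced replicates the
    permutation moves whole accession blocks; otherwise it shuffles
    observations within environment."""
    n_obs = pheno_env.shape[0]
    out = np.empty((n_obs, n_perm), dtype=np.int64)
    for h in np.unique(pheno_env):
        rows = np.flatnonzero(pheno_env == h)
        accs_here = accessions[rows]
        uniq, inv = np.unique(accs_here, return_inverse=True)
        counts = np.bincount(inv)
        balanced = counts.min() == counts.max()
        if balanced and uniq.size > 1:
            order = np.argsort(inv, kind="stable")
            blocks = rows[order].reshape(uniq.size, counts[0])
            for p in range(n_perm):
                perm = rng.permutation(uniq.size)
                out[rows[order], p] = blocks[perm].ravel()
        else:
            for p in range(n_perm):
                out[rows, p] = rows[rng.permutation(rows.size)]
    return out


def permutation_threshold(
    coded: CodedGenotypes,
    pheno: pd.DataFrame,
    family: str = "1d",
    loci: list | None = None,
    pairs: list[tuple[int, int]] | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    trait: str | None = None,
    return_null: bool = False,
):
    """Experiment-wise threshold for a scan family.

    Permutes the accession-to-phenotype assignment within environment,
    records the maximum scan statistic over the family per permutation and
    returns the (1 - alpha) upper quantile of that maximum (conservative
    "higher" quantile).  ``family`` is ``"1d"`` (all loci, or ``loci``) or
    ``"2d"`` (requires ``pairs``).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    y, accessions, env_idx, n_envs = align_observations(coded, pheno, trait)
    acc_rows = _expand(coded, accessions, _acc_ids(coded, pheno, trait))
    rng = np.random.default_rng(seed)
    idx = _permutation_indices(env_idx, accessions, n_perm, rng)
    yperm = _center_within_env(y[idx], env_idx, n_envs)

    if family == "1d":
        ws = _Scan1DWorkspace(coded, acc_rows, env_idx, n_envs)
        sel = np.arange(coded.n_snps) if loci is None else np.asarray(loci)
        if sel.size == 0:
            raise ValueError("empty scan family")
        f, _df1, _df2 = ws.f_stats(yperm)
        max_null = f[sel].max(axis=0)
    elif family == "2d":
        if not pairs:
            raise ValueError("2d family requires pairs")
        max_null = np.zeros(n_perm)
        sst = (yperm**2).sum(axis=0)
        for i, j in pairs:
            if i > j:
                i, j = j, i
            X_red, epi_cols, _cls = _pair_design(coded, i, j, acc_rows, env_idx, n_envs)
            if not epi_cols:
                continue
            X_full = np.column_stack([X_red] + epi_cols)
            q_red, _ = np.linalg.qr(X_red)
            q_full, _ = np.linalg.qr(X_full)
            ssr_red = ((q_red.T @ yperm) ** 2).sum(axis=0)
            ssr_full = ((q_full.T @ yperm) ** 2).sum(axis=0)
            df1 = len(epi_cols)
            df2 = yperm.shape[0] - n_envs - X_full.shape[1]
            sse = np.maximum(sst - ssr_full, 1e-12)
            f = ((ssr_full - ssr_red) / df1) / (sse / df2)
            max_null = np.maximum(max_null, f)
    else:
        raise ValueError("family must be '1d' or '2d'")

    thr = float(np.quantile(max_null, 1.0 - alpha, method="higher"))
    return (thr, max_null) if return_null else thr


# ---------------------------------------------------------------------------
# full model (Gibbs)
# ---------------------------------------------------------------------------


@dataclass
class FullModel:
    """Fitted full QTS model.

    ``effects`` columns: term, effect_type, estimate, sd, ci_low, ci_high,
    neglog10p.  ``gxe`` columns: term, effect_type (ae..dde), env,
    estimate, sd.  ``variance_components`` maps component labels ("env",
    "residual", "<term>:<class>e") to realized variances (posterior mean of
    the mean-squared random effect for blocks; posterior mean of sigma2 for
    the residual).
    """

    mu: float
    effects: pd.DataFrame
    gxe: pd.DataFrame
    variance_components: dict[str, float]
    diagnostics: dict[str, float] = field(default_factory=dict)
    qts_alleles: dict[str, tuple[str, str]] = field(default_factory=dict)
    polarize: str = "major"
    v_p: float | None = None

    # -- structure ------------------------------------------------------
    @property
    def qts_ids(self) -> list[str]:
        ids: list[str] = []
        for term in self.effects["term"]:
            ids += str(term).split("&")
        return sorted(set(ids))

    def epistatic_pairs(self) -> list[tuple[str, str]]:
        out = []
        for term in self.effects["term"].unique():
            if "&" in str(term):
                a, b = str(term).split("&")
                out.append((a, b))
        return sorted(set(out))

    def main_effect(self, qts: str, cls: str) -> float:
        sub = self.effects[(self.effects["term"] == qts) & (self.effects["effect_type"] == cls)]
        return float(sub["estimate"].iloc[0]) if len(sub) else 0.0

    def pair_effect(self, qi: str, qj: str, cls: str) -> float:
        term = f"{qi}&{qj}"
        sub = self.effects[(self.effects["term"] == term) & (self.effects["effect_type"] == cls)]
        return float(sub["estimate"].iloc[0]) if len(sub) else 0.0

    def gxe_effect(self, term: str, cls: str, env: int) -> float:
        sub = self.gxe[
            (self.gxe["term"] == term)
            & (self.gxe["effect_type"] == cls)
            & (self.gxe["env"] == env)
        ]
        return float(sub["estimate"].iloc[0]) if len(sub) else 0.0

    @property
    def environments(self) -> list[int]:
        return sorted(self.gxe["env"].unique()) if len(self.gxe) else []

    # -- prediction -----------------------------------------------------
    def genetic_values(self, panel) -> np.ndarray:
        """Total predicted genetic value per accession (main + epistasis)."""
        from .coding import code_genotypes

        coded = code_genotypes(panel, polarize=self.polarize)
        g = np.zeros(panel.n_accessions)
        for _i, row in self.effects.iterrows():
            term, cls, est = str(row["term"]), row["effect_type"], float(row["estimate"])
            if "&" in term:
                qi, qj = term.split("&")
                i, j = coded.index(qi), coded.index(qj)
                col = coded.pair_columns(min(i, j), max(i, j))[cls]
            else:
                k = coded.index(term)
                col = coded.x_a[:, k] if cls == "a" else coded.x_d[:, k]
            g = g + est * np.nan_to_num(col)
        return g

    # -- construction from printed effect tables ------------------------
    @classmethod
    def from_effect_table(cls, table: pd.DataFrame, trait: str | None = None) -> "FullModel":
        """Build a model from a per-effect table (Table 2/3 layout).

        Columns: qts, alleles, effect_type, effect [, h2, neglog10p].
        Environment-specific rows (ae1, de2, ...) become GxE entries.
        """
        df = table if trait is None else table[table["trait"] == trait]
        eff_rows, gxe_rows, alleles = [], [], {}
        for _i, row in df.iterrows():
            et = str(row["effect_type"])
            term = str(row["qts"])
            for q, al in zip(term.split("&"), str(row.get("alleles", "")).split("&")):
                if "/" in al:
                    maj, mino = al.split("/")
                    alleles[q] = (maj, mino)
            if et in ("a", "d") + tuple(EPISTASIS_CLASSES):
                eff_rows.append(
                    {
                        "term": term,
                        "effect_type": et,
                        "estimate": float(row["effect"]),
                        "sd": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "neglog10p": row.get("neglog10p", np.nan),
                    }
                )
            else:
                base = et.rstrip("0123456789")
                env = int(et[len(base):]) if et[len(base):] else 0
                gxe_rows.append(
                    {
                        "term": term,
                        "effect_type": base,
                        "env": env,
                        "estimate": float(row["effect"]),
                        "sd": np.nan,
                    }
                )
        return cls(
            mu=0.0,
            effects=pd.DataFrame(eff_rows),
            gxe=pd.DataFrame(gxe_rows, columns=["term", "effect_type", "env", "estimate", "sd"]),
            variance_components={},
            qts_alleles=alleles,
        )


def _env_contrasts(n_envs: int) -> np.ndarray:
    """Orthonormal basis of the sum-to-zero subspace of R^n_envs.

    Together with the constant vector 1/sqrt(H) these form an orthonormal
    basis, so iid N(0, s2) environment-level effects decompose into an
    overall mean kappa ~ N(0, s2/H) plus contrast coefficients ~ N(0, s2 I).
    The mean component of every random block is confounded with the block's
    parent fixed effect (the interaction columns sum to the parent column),
    so only the contrasts enter the design; kappa is drawn from its prior
    each sweep and folded back into the reported fixed effect.
    """
    h = np.eye(n_envs) - np.full((n_envs, n_envs), 1.0 / n_envs)
    # orthonormalize the centered identity; drop the null direction
    q, r = np.linalg.qr(h)
    keep = np.abs(np.diag(r)) > 1e-10
    return q[:, keep]


def _build_design(coded, qts, pairs, acc_rows, env_idx, n_envs, include_gxe):
    """Fixed + random design for the full model.

    Returns (X, labels, block_ids, block_labels, block_parent, contrast,
    keep_rows) where block_ids assigns -1 to fixed columns and a block
    index to random (contrast) columns; block_parent maps each block to the
    fixed column its mean component is confounded with.
    """
    qts_idx = [coded.index(q) if isinstance(q, str) else int(q) for q in qts]
    pair_idx = []
    for i, j in pairs:
        i = coded.index(i) if isinstance(i, str) else int(i)
        j = coded.index(j) if isinstance(j, str) else int(j)
        pair_idx.append((min(i, j), max(i, j)))

    all_loci = sorted(set(qts_idx) | {k for p in pair_idx for k in p})
    ok_rows = ~np.isnan(coded.x_a[:, all_loci]).any(axis=1) if all_loci else np.ones(
        coded.n_accessions, dtype=bool
    )
    keep = ok_rows[acc_rows]
    if not keep.all():
        logger.info("dropped %d observations with missing genotypes", int((~keep).sum()))

    cols, labels = [], []  # genetic fixed columns (per accession)
    for k in qts_idx:
        cols.append(coded.x_a[:, k])
        labels.append((coded.snp_ids[k], "a"))
        cols.append(coded.x_d[:, k])
        labels.append((coded.snp_ids[k], "d"))
    for i, j in pair_idx:
        prods = coded.pair_columns(i, j)
        term = f"{coded.snp_ids[i]}&{coded.snp_ids[j]}"
        for c in EPISTASIS_CLASSES:
            cols.append(prods[c])
            labels.append((term, c))

    acc_rows = acc_rows[keep]
    env = env_idx[keep]
    n_obs = acc_rows.shape[0]

    X_parts = [np.ones((n_obs, 1))]
    col_labels: list[tuple[str, str, int]] = [("_mu", "mu", 0)]
    block_ids = [-1]
    block_labels: list[str] = []

    genetic_obs = []
    for col, lab in zip(cols, labels):
        genetic_obs.append((col[acc_rows], lab))

    # drop degenerate / collinear fixed columns
    tracker = _RankTracker(n_obs)
    tracker.try_add(np.ones(n_obs))
    kept_genetic = []
    for colv, lab in genetic_obs:
        if tracker.try_add(colv):
            X_parts.append(colv[:, None])
            col_labels.append((lab[0], lab[1], 0))
            block_ids.append(-1)
            kept_genetic.append((colv, lab))
        else:
            logger.info("degenerate fixed column %s:%s dropped", lab[0], lab[1])

    # random blocks in the sum-to-zero contrast basis
    block_parent: list[int] = []
    contrast = _env_contrasts(n_envs) if n_envs >= 2 else None
    if n_envs >= 2:
        env_block = contrast[env]  # (n_obs, H-1)
        X_parts.append(env_block)
        b = len(block_labels)
        block_labels.append("env")
        block_parent.append(0)  # confounded with the intercept
        for k in range(contrast.shape[1]):
            col_labels.append(("_env", "env_c", k))
            block_ids.append(b)
        if include_gxe:
            for idx, (colv, (term, gcls)) in enumerate(kept_genetic):
                block = env_block * colv[:, None]
                X_parts.append(block)
                b = len(block_labels)
                block_labels.append(f"{term}:{gcls}e")
                block_parent.append(1 + idx)  # parent fixed column position
                for k in range(contrast.shape[1]):
                    col_labels.append((term, gcls + "e", k))
                    block_ids.append(b)

    X = np.column_stack(X_parts)
    return X, col_labels, np.array(block_ids), block_labels, block_parent, contrast, keep


def fit_full_model(
    coded: CodedGenotypes,
    pheno: pd.DataFrame,
    qts: list,
    pairs: list[tuple] | None = None,
    n_iter: int = 20_000,
    burn_in: int = 2_000,
    seed: int = 0,
    trait: str | None = None,
    include_gxe: bool = True,
    prior_shape: float = 0.01,
    prior_rate: float = 1e-4,
    prior_block_shape: float = 0.01,
    prior_block_rate: float = 3e-3,
    qts_alleles: dict | None = None,
    polarize: str = "major",
) -> FullModel:
    """Gibbs-sampler fit of the full QTS model.

    Fixed effects get flat priors; the environment block and every
    per-(effect, class) GxE block get their own variance component with a
    weak inverse-gamma prior; residual likewise.  Point estimates are
    posterior means; per-effect -log10 p comes from the posterior mean/sd
    Wald ratio against a standard normal.  Split-chain potential scale
    reduction over fixed effects is reported in ``diagnostics``; values
    above ~1.1 indicate non-convergence (reported, not silenced).
    """
    pairs = pairs or []
    y, accessions, env_idx, n_envs = align_observations(coded, pheno, trait)
    acc_rows = _expand(coded, accessions, _acc_ids(coded, pheno, trait))
    X, col_labels, block_ids, block_labels, block_parent, contrast, keep = _build_design(
        coded, qts, pairs, acc_rows, env_idx, n_envs, include_gxe
    )
    yk = y[keep]
    n, p = X.shape
    n_blocks = len(block_labels)
    rng = np.random.default_rng(seed)

    xtx = X.T @ X
    xty = X.T @ yk
    yty = float(yk @ yk)

    sigma2_e = max(float(np.var(yk)) / 2.0, 1e-8)
    block_var = np.full(n_blocks, max(float(np.var(yk)) / 10.0, 1e-8))
    fixed_mask = block_ids < 0
    fixed_idx = np.flatnonzero(fixed_mask)
    block_cols = [np.flatnonzero(block_ids == b) for b in range(n_blocks)]

    n_save = n_iter - burn_in
    if n_save <= 0:
        raise ValueError("burn_in must be smaller than n_iter")
    # adjusted fixed effects: theta_fixed minus the confounded mean
    # component kappa of each attached random block
    adj_save = np.zeros((n_save, fixed_idx.size))
    block_msq_save = np.zeros((n_save, n_blocks))
    env_eff_sum = np.zeros((n_blocks, n_envs)) if n_envs >= 2 else None
    env_eff_sq = np.zeros((n_blocks, n_envs)) if n_envs >= 2 else None
    sigma2_sum = 0.0

    # variance-component priors: residual gets (prior_shape, prior_rate);
    # H-level blocks get a near-zero (Jeffreys-like) shape: a block variance
    # is learned from only H-1 contrasts, and in the Jeffreys limit the
    # implied posterior for the confounded mean component is an exactly
    # pivotal t with H-1 df, giving calibrated intervals for the parent
    # fixed effect
    block_shape0 = prior_block_shape

    for it in range(n_iter):
        prior_prec = np.zeros(p)
        for b in range(n_blocks):
            prior_prec[block_cols[b]] = 1.0 / block_var[b]
        c_mat = xtx / sigma2_e + np.diag(prior_prec)
        chol = np.linalg.cholesky(c_mat)
        mean = np.linalg.solve(c_mat, xty / sigma2_e)
        z = rng.standard_normal(p)
        theta = mean + np.linalg.solve(chol.T, z)

        adjusted = theta[fixed_idx].copy()
        kappas = np.zeros(n_blocks)
        for b in range(n_blocks):
            # mean component of the block, confounded with its parent fixed
            # effect: sampled from its conditional prior and folded back
            kappa = rng.normal(0.0, np.sqrt(block_var[b] / n_envs))
            kappas[b] = kappa
            parent = block_parent[b]
            pos = int(np.flatnonzero(fixed_idx == parent)[0])
            adjusted[pos] -= kappa
            ub = theta[block_cols[b]]
            shape = block_shape0 + n_envs / 2.0
            # the small block rate keeps the chain off the absorbing
            # near-zero state of a scale-free inverse-gamma prior while
            # adding negligible variance to truly null blocks
            rate = prior_block_rate + (float(ub @ ub) + n_envs * kappa**2) / 2.0
            block_var[b] = rate / rng.gamma(shape)

        sse = yty - 2.0 * float(theta @ xty) + float(theta @ xtx @ theta)
        sse = max(sse, 1e-12)
        sigma2_e = (prior_rate + sse / 2.0) / rng.gamma(prior_shape + n / 2.0)

        if it >= burn_in:
            k = it - burn_in
            adj_save[k] = adjusted
            for b in range(n_blocks):
                ub = theta[block_cols[b]]
                # realized mean-square of the unconstrained block effects
                block_msq_save[k, b] = kappas[b] ** 2 + float(ub @ ub) / n_envs
                if env_eff_sum is not None:
                    eff = kappas[b] + contrast @ ub
                    env_eff_sum[b] += eff
                    env_eff_sq[b] += eff**2
            sigma2_sum += sigma2_e

    post_mean = adj_save.mean(axis=0)
    post_sd = adj_save.std(axis=0)
    ci_low = np.percentile(adj_save, 2.5, axis=0)
    ci_high = np.percentile(adj_save, 97.5, axis=0)
    theta_save = adj_save

    # split-chain potential scale reduction on fixed effects
    half = n_save // 2
    rhats = []
    for k in range(theta_save.shape[1]):
        a, b = theta_save[:half, k], theta_save[half : 2 * half, k]
        w = (a.var(ddof=1) + b.var(ddof=1)) / 2.0
        mvar = np.var([a.mean(), b.mean()], ddof=1) * half
        if w > 0:
            rhats.append(np.sqrt((half - 1) / half + mvar / (w * half)))
    diagnostics = {
        "rhat_max": float(max(rhats)) if rhats else 1.0,
        "n_iter": n_iter,
        "burn_in": burn_in,
        "n_obs": n,
    }
    if diagnostics["rhat_max"] > 1.1:
        logger.warning("possible non-convergence: max split-Rhat %.3f", diagnostics["rhat_max"])

    eff_rows, gxe_rows = [], []
    mu = 0.0
    for k, col in enumerate(fixed_idx):
        term, cls, _env = col_labels[col]
        if cls == "mu":
            mu = float(post_mean[k])
            continue
        z = post_mean[k] / post_sd[k] if post_sd[k] > 0 else np.inf
        eff_rows.append(
            {
                "term": term,
                "effect_type": cls,
                "estimate": float(post_mean[k]),
                "sd": float(post_sd[k]),
                "ci_low": float(ci_low[k]),
                "ci_high": float(ci_high[k]),
                "neglog10p": neglog10_p_from_z(z),
            }
        )

    # posterior median of the realized mean-square per block: robust to the
    # heavy upper tail the few-df variance posterior carries
    block_msq = np.median(block_msq_save, axis=0)
    variance_components = {"residual": sigma2_sum / n_save}
    for b, lab in enumerate(block_labels):
        variance_components[lab] = float(block_msq[b])
        if lab == "env" or env_eff_sum is None:
            continue
        term, gcls = lab.rsplit(":", 1)
        eff_mean = env_eff_sum[b] / n_save
        eff_sd = np.sqrt(np.maximum(env_eff_sq[b] / n_save - eff_mean**2, 0.0))
        for h in range(n_envs):
            gxe_rows.append(
                {
                    "term": term,
                    "effect_type": gcls,
                    "env": h + 1,
                    "estimate": float(eff_mean[h]),
                    "sd": float(eff_sd[h]),
                }
            )

    # phenotypic variance of environment-centered observations
    v_p = float(np.var(_center_within_env(yk, env_idx[keep], n_envs)))

    return FullModel(
        mu=mu,
        effects=pd.DataFrame(
            eff_rows,
            columns=["term", "effect_type", "estimate", "sd", "ci_low", "ci_high", "neglog10p"],
        ),
        gxe=pd.DataFrame(gxe_rows, columns=["term", "effect_type", "env", "estimate", "sd"]),
        variance_components=variance_components,
        diagnostics=diagnostics,
        qts_alleles=qts_alleles or {},
        polarize=polarize,
        v_p=v_p,
    )


def model_heritability(
    model: FullModel,
    coded: CodedGenotypes,
    v_p: float | None = None,
) -> HeritabilityReport:
    """Per-effect heritability report for a fitted model.

    Fixed effects use estimate^2 * Var(column) / V_P; GxE components use
    their realized variance times mean(column^2) / V_P.  V_P defaults to the
    value recorded at fit time (variance of environment-centered
    phenotypes).
    """
    v_p = v_p if v_p is not None else model.v_p
    if not v_p or v_p <= 0:
        raise ValueError("V_P unavailable; pass v_p")
    entries = []

    def column_for(term: str, cls: str) -> np.ndarray:
        if "&" in term:
            qi, qj = term.split("&")
            i, j = coded.index(qi), coded.index(qj)
            return coded.pair_columns(min(i, j), max(i, j))[cls]
        k = coded.index(term)
        return coded.x_a[:, k] if cls == "a" else coded.x_d[:, k]

    for _i, row in model.effects.iterrows():
        col = column_for(str(row["term"]), row["effect_type"])
        entries.append(
            {
                "term": row["term"],
                "effect_type": row["effect_type"],
                "h2": effect_heritability(float(row["estimate"]), col, v_p, kind="fixed"),
            }
        )
    for comp, var in model.variance_components.items():
        if ":" not in comp:
            continue
        term, gcls = comp.split(":")
        parent = gcls[:-1]  # strip trailing 'e'
        col = column_for(term, parent)
        entries.append(
            {
                "term": term,
                "effect_type": gcls,
                "h2": effect_heritability(var, col, v_p, kind="variance"),
            }
        )
    return HeritabilityReport(per_effect=pd.DataFrame(entries), v_p=v_p)
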