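"""Reproducibility benchmarks: self-contained simulation experiments.

These functions re-run the package's core claims from scratch at a scale a
single CPU handles in minutes:

* :func:`fixture_aggregates` — arithmetic identities on the packaged
  heritability/effect tables (class sums, pair totals, row-sum checks);
* :func:`recovery_experiment` — multi-seed parameter recovery of planted
  additive, dominance, dominance x dominance and additive x environment
  components by the full-model Gibbs fit at the study's design shape
  (316 accessions, 3 environments x 3 replicates);
* :func:`experimentwise_fpr` — empirical experiment-wise type-I error of
  1-D scans thresholded by 1000-permutation maxima;
* :func:`ld_half_decay_experiment` — recovery of a known LD decay scale.
"""

from __future__ import annotations

import numpy as np

from .coding import code_genotypes
from .model import fit_full_model, model_heritability, permutation_threshold, scan_1d_all
from .qc import ld_decay
from .simulate import SimConfig, TraitArchitecture, simulate_genotypes, simulate_phenotypes, true_heritabilities
from .structure import bonferroni_threshold
from .tables import load_effect_tables, load_table1, qts_total_heritability, table1_class_columns


# ---------------------------------------------------------------------------
# fixture identities
# ---------------------------------------------------------------------------


def fixture_aggregates() -> dict[str, float]:
    """Aggregation identities computed from the packaged reference tables."""
    t1 = load_table1()
    eff = load_effect_tables()
    out: dict[str, float] = {}

    def row(trait):
        return t1[t1["trait"] == trait].iloc[0]

    # per-trait totals from class-aggregate sums
    for trait in t1["trait"]:
        r = row(trait)
        out[f"{trait.lower()}_h2_total"] = float(
            np.nansum([r[c] for c in table1_class_columns()])
        )
    protein = row("Protein")
    out["protein_epistatic_h2"] = float(
        np.nansum([protein[c] for c in ("h2_AA", "h2_AD", "h2_DA", "h2_DD")])
    )
    myristic = row("Myristic")
    out["myristic_main_h2"] = float(myristic["h2_A"] + myristic["h2_D"])
    out["myristic_main_share_pct"] = float(
        100.0 * out["myristic_main_h2"] / out["myristic_h2_total"]
    )
    out["h2_total_min"] = float(min(out[f"{t.lower()}_h2_total"] for t in t1["trait"]))
    out["h2_total_max"] = float(max(out[f"{t.lower()}_h2_total"] for t in t1["trait"]))

    # key-pair totals from the per-effect tables
    out["oil_key_pair_h2"] = qts_total_heritability(
        eff, "Oil", ["A13_83121382", "A7_110987422"]
    )
    out["palmitic_key_pair_h2"] = qts_total_heritability(
        eff, "Palmitic", ["A7_642514", "D4_10313468"]
    )
    out["palmitic_key_pair_share_pct"] = float(
        round(100.0 * out["palmitic_key_pair_h2"] / out["palmitic_h2_total"], 1)
    )
    stearic = eff[
        (eff["trait"] == "Stearic")
        & (eff["qts"] == "A4_17627308")
        & (eff["effect_type"].str.startswith("ae"))
    ]
    out["stearic_a4_ae_mean_h2"] = float(stearic["h2"].mean())
    out["protein_n_epistatic_pairs"] = float(
        eff[(eff["trait"] == "Protein") & eff["qts"].str.contains("&")]["qts"].nunique()
    )
    out["bonferroni_threshold"] = bonferroni_threshold(0.05, 203_021)
    return out


def table1_row_sum_errors() -> dict[str, float]:
    """|printed h2_T - sum of class aggregates| per trait."""
    t1 = load_table1()
    out = {}
    for _i, r in t1.iterrows():
        total = np.nansum([r[c] for c in table1_class_columns()])
        out[str(r["trait"])] = float(abs(total - r["h2_T"]))
    return out


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

#: planted acceptance architecture: moderate additive+dominance locus, one
#: dominance x dominance pair, a weak additive x environment component
RECOVERY_EFFECTS = {"a": 0.6, "d": 0.5, "dd": 1.5}
RECOVERY_AE_SD = 0.2


def _pick_recovery_loci(panel) -> tuple[int, int, int]:
    """A main locus and a pair with every two-locus genotype cell occupied.

    Loci come from three different chromosomes with MAF > 0.25 so the
    saturated digenic model is identifiable.
    """
    maf = panel.maf()
    chrom = panel.snps["chrom"].to_numpy()
    chroms = [c for c in ("C1", "C2", "C3") if (chrom == c).any()]
    cand = {c: np.flatnonzero((maf > 0.25) & (chrom == c)) for c in chroms}
    loc_a = int(cand[chroms[0]][0])
    for i in cand[chroms[1]][:10]:
        for j in cand[chroms[2]][:10]:
            gi, gj = panel.codes[:, i], panel.codes[:, j]
            cells = {(a, b) for a, b in zip(gi.tolist(), gj.tolist())}
            if len(cells) == 9:
                return loc_a, int(i), int(j)
    raise RuntimeError("no fully occupied two-locus table found")


def recovery_experiment(
    n_seeds: int = 20,
    base_seed: int = 0,
    n_snps: int = 1000,
    n_iter: int = 4000,
    burn_in: int = 800,
) -> dict:
    """Multi-seed parameter recovery of the full-model Gibbs fit.

    For each seed: simulate a 316-accession panel (3 environments x 3
    replicates) with the planted architecture, fit the full model at the
    causal loci, record whether each planted effect lies in its 95%
    credible interval, and accumulate estimated vs. true class
    heritabilities.  Returns coverage counts and seed-averaged h2 errors.
    """
    a_val, d_val, dd_val = (
        RECOVERY_EFFECTS["a"],
        RECOVERY_EFFECTS["d"],
        RECOVERY_EFFECTS["dd"],
    )
    coverage = {"a": 0, "d": 0, "dd": 0}
    h2_est: dict[str, float] = {}
    h2_true: dict[str, float] = {}
    for s in range(n_seeds):
        seed = base_seed + s
        cfg = SimConfig(
            n_accessions=316, n_snps=n_snps, n_chromosomes=5, n_subpops=2,
            divergence=0.15, ld_block_bp=5_000.0, n_envs=3, n_reps=3, seed=seed,
        )
        panel = simulate_genotypes(cfg)
        loc_a, loc_i, loc_j = _pick_recovery_loci(panel)
        arch = TraitArchitecture(
            mu=10.0,
            main_effects=[(loc_a, a_val, d_val)],
            epistatic_effects=[(min(loc_i, loc_j), max(loc_i, loc_j), 0.0, 0.0, 0.0, dd_val)],
            env_sd=1.0,
            gxe_sds={"ae": RECOVERY_AE_SD},
            residual_sd=1.0,
        )
        pheno = simulate_phenotypes(panel, arch, n_envs=3, n_reps=3, seed=10_000 + seed)
        coded = code_genotypes(panel, polarize="counted")
        model = fit_full_model(
            coded, pheno, qts=[loc_a, loc_i, loc_j],
            pairs=[(loc_i, loc_j)], n_iter=n_iter, burn_in=burn_in,
            seed=seed, polarize="counted",
        )
        id_a = panel.snp_ids[loc_a]
        pair = f"{panel.snp_ids[min(loc_i, loc_j)]}&{panel.snp_ids[max(loc_i, loc_j)]}"
        for key, (term, cls, truth) in {
            "a": (id_a, "a", a_val),
            "d": (id_a, "d", d_val),
            "dd": (pair, "dd", dd_val),
        }.items():
            row = model.effects[
                (model.effects["term"] == term) & (model.effects["effect_type"] == cls)
            ].iloc[0]
            if row["ci_low"] <= truth <= row["ci_high"]:
                coverage[key] += 1
        for k, v in model_heritability(model, coded).to_row().items():
            h2_est[k] = h2_est.get(k, 0.0) + v
        for k, v in true_heritabilities(panel, arch).to_row().items():
            h2_true[k] = h2_true.get(k, 0.0) + v

    classes = ("h2_A", "h2_D", "h2_DD", "h2_AE")
    mean_est = {k: h2_est.get(k, 0.0) / n_seeds for k in classes}
    mean_true = {k: h2_true.get(k, 0.0) / n_seeds for k in classes}
    return {
        "n_seeds": n_seeds,
        "coverage": coverage,
        "h2_mean_est": mean_est,
        "h2_mean_true": mean_true,
        "h2_max_abs_error": max(abs(mean_est[k] - mean_true[k]) for k in classes),
        "coverage_min": min(coverage.values()),
    }


# ---------------------------------------------------------------------------
# experiment-wise error
# ---------------------------------------------------------------------------


def experimentwise_fpr(
    n_reps: int = 200,
    n_accessions: int = 200,
    n_snps: int = 200,
    n_perm: int = 1000,
    alpha: float = 0.05,
    base_seed: int = 0,
) -> dict:
    """Empirical experiment-wise false-positive rate of thresholded scans.

    Each replicate simulates an independent null panel/phenotype (single
    environment), derives the permutation threshold for the 1-D scan family
    and records whether any SNP exceeds it.
    """
    rng = np.random.default_rng(base_seed)
    rejections = 0
    for _rep in range(n_reps):
        seed = int(rng.integers(2**31 - 1))
        cfg = SimConfig(
            n_accessions=n_accessions, n_snps=n_snps, n_chromosomes=4,
            n_subpops=1, ld_block_bp=2_000.0, n_envs=1, n_reps=1, seed=seed,
        )
        panel = simulate_genotypes(cfg)
        arch = TraitArchitecture(mu=0.0, residual_sd=1.0)
        pheno = simulate_phenotypes(panel, arch, n_envs=1, n_reps=1, seed=seed + 1)
        coded = code_genotypes(panel, polarize="counted")
        thr = permutation_threshold(
            coded, pheno, family="1d", n_perm=n_perm, alpha=alpha, seed=seed + 2
        )
        observed = scan_1d_all(coded, pheno)["statistic"].max()
        if observed > thr:
            rejections += 1
    return {"n_reps": n_reps, "rate": rejections / n_reps}


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------


def ld_half_decay_experiment(
    ld_block_bp: float = 160_000.0, seed: int = 0, n_snps: int = 300
) -> float:
    """Half-decay distance (bp) recovered from a panel with known LD scale."""
    cfg = SimConfig(
        n_accessions=316, n_snps=n_snps, n_chromosomes=1, n_subpops=1,
        ld_block_bp=ld_block_bp, seed=seed,
    )
    panel = simulate_genotypes(cfg)
    return ld_decay(panel, max_dist=500_000, bin_width=5_000).half_decay_bp
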