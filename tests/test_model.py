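"""Genome scans, permutation thresholds and the Gibbs full-model fit."""

import numpy as np
import pandas as pd
import pytest

from qtsgwas import (
    SimConfig,
    TraitArchitecture,
    code_genotypes,
    fit_full_model,
    permutation_threshold,
    scan_1d,
    scan_1d_all,
    scan_2d,
    simulate_genotypes,
    simulate_phenotypes,
)

from .conftest import toy_panel


def _null_setup(n_acc=200, n_snps=1000, seed=0, n_envs=1, n_reps=1):
    cfg = SimConfig(n_accessions=n_acc, n_snps=n_snps, n_chromosomes=4, n_subpops=1,
                    ld_block_bp=10.0, seed=seed)
    panel = simulate_genotypes(cfg)
    arch = TraitArchitecture(mu=0.0, residual_sd=1.0)
    pheno = simulate_phenotypes(panel, arch, n_envs=n_envs, n_reps=n_reps, seed=seed + 1)
    return panel, code_genotypes(panel, polarize="counted"), pheno


class TestScan1D:
    def test_noiseless_causal_locus_saturates(self, small_panel):
        arch = TraitArchitecture(main_effects=[(7, 1.0, 0.0)], residual_sd=0.0)
        pheno = simulate_phenotypes(small_panel, arch, 1, 1, seed=0)
        coded = code_genotypes(small_panel, polarize="counted")
        entry = scan_1d(coded, pheno, 7)
        assert entry["statistic"] > 1e10
        assert entry["neglog10p"] >= 290

    def test_null_type_one_error(self):
        # all SNP tests share each phenotype draw, so the per-draw rejection
        # fraction is dependent; average over independent phenotype draws
        panel, coded, _ph = _null_setup(n_acc=200, n_snps=1000, seed=31)
        arch = TraitArchitecture(mu=0.0, residual_sd=1.0)
        rates = []
        for s in range(8):
            pheno = simulate_phenotypes(panel, arch, 1, 1, seed=40 + s)
            res = scan_1d_all(coded, pheno)
            rates.append((res["p"] < 0.05).mean())
        assert np.mean(rates) == pytest.approx(0.05, abs=0.02)

    def test_equals_direct_least_squares_fit(self):
        """Partial F for (a, d) equals an independently built OLS F test."""
        cfg = SimConfig(n_accessions=50, n_snps=10, n_chromosomes=1, n_subpops=1,
                        ld_block_bp=100.0, seed=7)
        panel = simulate_genotypes(cfg)
        arch = TraitArchitecture(main_effects=[(2, 0.5, 0.2)], residual_sd=1.0)
        pheno = simulate_phenotypes(panel, arch, n_envs=2, n_reps=2, seed=8)
        coded = code_genotypes(panel, polarize="counted")
        entry = scan_1d(coded, pheno, 2)

        # oracle: explicit design with environment dummies
        y = pheno["value"].to_numpy()
        env = pheno["env"].to_numpy()
        acc = pheno["accession"].map(
            {a: i for i, a in enumerate(panel.accession_ids)}
        ).to_numpy()
        E = np.column_stack([(env == h).astype(float) for h in (1, 2)])
        xa, xd = coded.x_a[acc, 2], coded.x_d[acc, 2]
        X_full = np.column_stack([E, xa, xd])
        X_red = E

        def sse(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return float(r @ r)

        df2 = len(y) - 2 - 2
        f_oracle = ((sse(X_red) - sse(X_full)) / 2) / (sse(X_full) / df2)
        assert entry["statistic"] == pytest.approx(f_oracle, rel=1e-8)
        assert entry["df1"] == 2 and entry["df2"] == df2

    def test_invariant_under_allele_relabeling(self, small_panel):
        arch = TraitArchitecture(main_effects=[(4, 0.6, 0.3)], residual_sd=0.8)
        pheno = simulate_phenotypes(small_panel, arch, 1, 2, seed=5)
        coded = code_genotypes(small_panel, polarize="counted")
        flipped_panel = small_panel.take_snps(np.arange(small_panel.n_snps))
        flipped_panel.codes[:, 4] = 2 - flipped_panel.codes[:, 4]
        coded_f = code_genotypes(flipped_panel, polarize="counted")
        a = scan_1d(coded, pheno, 4)
        b = scan_1d(coded_f, pheno, 4)
        assert a["statistic"] == pytest.approx(b["statistic"], rel=1e-9)


class TestScan2D:
    def test_coefficient_columns_match_hand_products(self):
        panel = toy_panel(np.array([[2, 0], [1, 1], [0, 2], [2, 2]], dtype=np.int8))
        coded = code_genotypes(panel, polarize="counted")
        pc = coded.pair_columns(0, 1)
        xa = panel.codes.astype(float) - 1
        xd = (panel.codes == 1).astype(float)
        assert np.allclose(pc["aa"], xa[:, 0] * xa[:, 1])
        assert np.allclose(pc["ad"], xa[:, 0] * xd[:, 1])
        assert np.allclose(pc["da"], xd[:, 0] * xa[:, 1])
        assert np.allclose(pc["dd"], xd[:, 0] * xd[:, 1])

    def test_planted_dd_detected_at_permutation_threshold(self):
        hits = 0
        n_runs = 10
        for s in range(n_runs):
            cfg = SimConfig(n_accessions=400, n_snps=20, n_chromosomes=2, n_subpops=1,
                            ld_block_bp=100.0, seed=100 + s)
            panel = simulate_genotypes(cfg)
            arch = TraitArchitecture(
                epistatic_effects=[(2, 12, 0.0, 0.0, 0.0, 2.0)], residual_sd=0.5
            )
            pheno = simulate_phenotypes(panel, arch, 1, 1, seed=200 + s)
            coded = code_genotypes(panel, polarize="counted")
            entry = scan_2d(coded, pheno, 2, 12)
            thr = permutation_threshold(
                coded, pheno, family="2d", pairs=[(2, 12)], n_perm=300, seed=300 + s
            )
            if entry["statistic"] > thr:
                hits += 1
        assert hits >= 9  # >= 90% power

    def test_additive_only_truth_near_nominal_rejection(self):
        rejections = 0
        n_runs = 60
        for s in range(n_runs):
            cfg = SimConfig(n_accessions=150, n_snps=6, n_chromosomes=2, n_subpops=1,
                            ld_block_bp=10.0, seed=400 + s)
            panel = simulate_genotypes(cfg)
            arch = TraitArchitecture(main_effects=[(0, 0.8, 0.0), (3, -0.5, 0.0)],
                                     residual_sd=1.0)
            pheno = simulate_phenotypes(panel, arch, 1, 1, seed=500 + s)
            coded = code_genotypes(panel, polarize="counted")
            entry = scan_2d(coded, pheno, 0, 3)
            if entry["p"] < 0.05:
                rejections += 1
        assert rejections / n_runs == pytest.approx(0.05, abs=0.07)

    def test_distinct_loci_required(self, small_panel):
        coded = code_genotypes(small_panel, polarize="counted")
        arch = TraitArchitecture(residual_sd=1.0)
        pheno = simulate_phenotypes(small_panel, arch, 1, 1, seed=0)
        with pytest.raises(ValueError):
            scan_2d(coded, pheno, 3, 3)


class TestPermutationThreshold:
    def test_dominates_pointwise_critical_value(self):
        _p, coded, pheno = _null_setup(n_acc=120, n_snps=50, seed=61)
        thr_family, null_family = permutation_threshold(
            coded, pheno, family="1d", n_perm=300, seed=1, return_null=True
        )
        thr_single = permutation_threshold(
            coded, pheno, family="1d", loci=[0], n_perm=300, seed=1
        )
        assert thr_family >= thr_single

    def test_seeded_determinism(self):
        _p, coded, pheno = _null_setup(n_acc=100, n_snps=30, seed=62)
        a = permutation_threshold(coded, pheno, family="1d", n_perm=200, seed=9)
        b = permutation_threshold(coded, pheno, family="1d", n_perm=200, seed=9)
        assert a == b

    def test_minimum_permutations_enforced(self):
        _p, coded, pheno = _null_setup(n_acc=50, n_snps=10, seed=63)
        with pytest.raises(ValueError):
            permutation_threshold(coded, pheno, n_perm=50)


class TestFullModel:
    def test_intercept_only_recovers_grand_mean(self, small_panel):
        arch = TraitArchitecture(mu=4.2, env_sd=0.5, residual_sd=0.5)
        pheno = simulate_phenotypes(small_panel, arch, 3, 2, seed=2)
        coded = code_genotypes(small_panel, polarize="counted")
        model = fit_full_model(coded, pheno, qts=[], n_iter=1500, burn_in=300, seed=0)
        assert model.mu == pytest.approx(pheno["value"].mean(), abs=0.5)

    def test_noiseless_additive_exact_identification(self, small_panel):
        arch = TraitArchitecture(mu=0.0, main_effects=[(3, 1.0, 0.0)], residual_sd=0.0)
        pheno = simulate_phenotypes(small_panel, arch, 1, 1, seed=0)
        coded = code_genotypes(small_panel, polarize="counted")
        # noiseless data: a vague residual prior lets sigma2 collapse to ~0
        model = fit_full_model(coded, pheno, qts=[3], n_iter=1200, burn_in=200, seed=0,
                               prior_rate=1e-10)
        a_hat = model.main_effect(small_panel.snp_ids[3], "a")
        assert a_hat == pytest.approx(1.0, abs=1e-6)

    def test_parameter_recovery_credible_interval_coverage(self):
        """a=1, d=0.5, dd=2, ae-sd=0.5: planted effects inside the 95% CI
        in at least 18 of 20 seeded replicates."""
        cover = {"a": 0, "d": 0, "dd": 0}
        n_seeds = 20
        for s in range(n_seeds):
            cfg = SimConfig(n_accessions=316, n_snps=60, n_chromosomes=3, n_subpops=2,
                            ld_block_bp=1_000.0, seed=700 + s)
            panel = simulate_genotypes(cfg)
            maf = panel.maf()
            chrom = panel.snps["chrom"].to_numpy()
            loc_a = int(np.flatnonzero((maf > 0.25) & (chrom == "C1"))[0])
            pair = _occupied_pair(panel, maf, chrom)
            arch = TraitArchitecture(
                mu=10.0, main_effects=[(loc_a, 1.0, 0.5)],
                epistatic_effects=[(pair[0], pair[1], 0.0, 0.0, 0.0, 2.0)],
                env_sd=1.0, gxe_sds={"ae": 0.5}, residual_sd=1.0,
            )
            pheno = simulate_phenotypes(panel, arch, 3, 3, seed=800 + s)
            coded = code_genotypes(panel, polarize="counted")
            model = fit_full_model(
                coded, pheno, qts=[loc_a, *pair], pairs=[pair],
                n_iter=2500, burn_in=500, seed=s, polarize="counted",
            )
            id_a = panel.snp_ids[loc_a]
            pid = f"{panel.snp_ids[pair[0]]}&{panel.snp_ids[pair[1]]}"
            for key, (term, cls, truth) in {
                "a": (id_a, "a", 1.0), "d": (id_a, "d", 0.5), "dd": (pid, "dd", 2.0),
            }.items():
                row = model.effects[
                    (model.effects["term"] == term)
                    & (model.effects["effect_type"] == cls)
                ].iloc[0]
                if row["ci_low"] <= truth <= row["ci_high"]:
                    cover[key] += 1
        assert min(cover.values()) >= 18, cover

    def test_gxe_component_shrinks_with_replication(self):
        """With zero true GxE, the estimated ae component decreases as
        replication grows (Monte-Carlo averaged)."""
        def mean_ae(n_reps, seeds=(0, 1, 2, 3, 4)):
            vals = []
            for s in seeds:
                cfg = SimConfig(n_accessions=150, n_snps=10, n_chromosomes=2,
                                n_subpops=1, ld_block_bp=100.0, seed=900 + s)
                panel = simulate_genotypes(cfg)
                arch = TraitArchitecture(main_effects=[(1, 0.8, 0.0)], env_sd=0.5,
                                         residual_sd=1.0)
                pheno = simulate_phenotypes(panel, arch, 3, n_reps, seed=950 + s)
                coded = code_genotypes(panel, polarize="counted")
                model = fit_full_model(coded, pheno, qts=[1], n_iter=1200,
                                       burn_in=200, seed=s, polarize="counted")
                key = f"{panel.snp_ids[1]}:ae"
                vals.append(model.variance_components[key])
            return np.mean(vals)

        assert mean_ae(10) < mean_ae(2)

    def test_residual_variance_below_phenotypic(self, small_panel):
        arch = TraitArchitecture(main_effects=[(2, 1.0, 0.0)], residual_sd=1.0)
        pheno = simulate_phenotypes(small_panel, arch, 2, 2, seed=6)
        coded = code_genotypes(small_panel, polarize="counted")
        model = fit_full_model(coded, pheno, qts=[2], n_iter=1200, burn_in=200, seed=0,
                               polarize="counted")
        assert model.variance_components["residual"] <= np.var(pheno["value"])

    def test_missing_genotype_observations_dropped(self, small_panel):
        panel = small_panel.take_snps(np.arange(small_panel.n_snps))
        panel.codes[:5, 2] = -1
        arch = TraitArchitecture(main_effects=[(3, 1.0, 0.0)], residual_sd=0.5)
        pheno = simulate_phenotypes(small_panel, arch, 1, 1, seed=7)
        coded = code_genotypes(panel, polarize="counted")
        model = fit_full_model(coded, pheno, qts=[2, 3], n_iter=800, burn_in=100, seed=0,
                               polarize="counted")
        assert model.diagnostics["n_obs"] == small_panel.n_accessions - 5


def _occupied_pair(panel, maf, chrom):
    cand_i = np.flatnonzero((maf > 0.25) & (chrom == "C2"))
    cand_j = np.flatnonzero((maf > 0.25) & (chrom == "C3"))
    for i in cand_i[:10]:
        for j in cand_j[:10]:
            cells = set(zip(panel.codes[:, i].tolist(), panel.codes[:, j].tolist()))
            if len(cells) == 9:
                return int(min(i, j)), int(max(i, j))
    raise RuntimeError("no fully occupied pair")
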