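"""Superior-genotype design: prediction, exact optimization, pleiotropy."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from qtsgwas import DesignTarget, design_superior, genetic_value
from qtsgwas.design import pleiotropy_conflict_report
from qtsgwas.model import FullModel


def _model(effects, gxe=(), alleles=None):
    eff = pd.DataFrame(
        [
            {"term": t, "effect_type": c, "estimate": v, "sd": 0.0,
             "ci_low": v, "ci_high": v, "neglog10p": 10.0}
            for t, c, v in effects
        ]
    )
    g = pd.DataFrame(
        [{"term": t, "effect_type": c, "env": e, "estimate": v, "sd": 0.0} for t, c, e, v in gxe],
        columns=["term", "effect_type", "env", "estimate", "sd"],
    )
    return FullModel(mu=0.0, effects=eff, gxe=g, variance_components={},
                     qts_alleles=alleles or {})


class TestGeneticValue:
    def test_single_locus_coefficients(self):
        m = _model([("Q1", "a", 2.0), ("Q1", "d", 1.0)])
        assert genetic_value({"Q1": 2}, m) == 2.0
        assert genetic_value({"Q1": 1}, m) == 1.0
        assert genetic_value({"Q1": 0}, m) == -2.0

    def test_pair_products(self):
        m = _model([("Q1&Q2", "aa", 1.0)])
        assert genetic_value({"Q1": 2, "Q2": 2}, m) == 1.0
        assert genetic_value({"Q1": 2, "Q2": 0}, m) == -1.0
        assert genetic_value({"Q1": 1, "Q2": 2}, m) == 0.0

    def test_oracle_equality_on_random_model(self):
        rng = np.random.default_rng(5)
        ids = [f"Q{k}" for k in range(8)]
        effects = []
        for q in ids:
            effects += [(q, "a", rng.normal()), (q, "d", rng.normal())]
        pairs = [("Q0", "Q1"), ("Q2", "Q3"), ("Q4", "Q5")]
        pair_effects = {}
        for qi, qj in pairs:
            for cls in ("aa", "ad", "da", "dd"):
                v = rng.normal()
                effects.append((f"{qi}&{qj}", cls, v))
                pair_effects[(qi, qj, cls)] = v
        m = _model(effects)

        def oracle(assign):
            xa = {q: assign[q] - 1 for q in ids}
            xd = {q: float(assign[q] == 1) for q in ids}
            val = sum(
                v * (xa[t] if c == "a" else xd[t])
                for t, c, v in effects if "&" not in t
            )
            for (qi, qj, cls), v in pair_effects.items():
                coeff = {
                    "aa": xa[qi] * xa[qj], "ad": xa[qi] * xd[qj],
                    "da": xd[qi] * xa[qj], "dd": xd[qi] * xd[qj],
                }[cls]
                val += v * coeff
            return val

        for _rep in range(100):
            assign = {q: int(rng.integers(0, 3)) for q in ids}
            assert genetic_value(assign, m) == pytest.approx(oracle(assign))

    def test_incomplete_assignment_rejected(self):
        m = _model([("Q1", "a", 1.0), ("Q2", "a", 1.0)])
        with pytest.raises(ValueError):
            genetic_value({"Q1": 2}, m)


class TestDesignSuperior:
    def test_hybrid_beats_line_when_dominance_large(self):
        m = _model([("Q1", "a", 2.0), ("Q1", "d", 3.0)])
        gsl = design_superior(m, DesignTarget("GSL", "max"))
        gsh = design_superior(m, DesignTarget("GSH", "max"))
        assert gsl.assignment["Q1"] == 2 and gsl.value == 2.0
        assert gsh.assignment["Q1"] == 1 and gsh.value == 3.0

    def test_matches_full_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        ids = [f"Q{k}" for k in range(10)]
        effects = []
        for q in ids:
            effects += [(q, "a", rng.normal()), (q, "d", rng.normal())]
        # two 3-locus epistatic components: {Q0,Q1,Q2} and {Q5,Q6,Q7}
        for qi, qj in [("Q0", "Q1"), ("Q1", "Q2"), ("Q5", "Q6"), ("Q6", "Q7")]:
            for cls in ("aa", "ad", "da", "dd"):
                effects.append((f"{qi}&{qj}", cls, rng.normal()))
        m = _model(effects)
        for mode in ("GSH", "GSL"):
            target = DesignTarget(mode, "max")
            res = design_superior(m, target)
            best_val = -np.inf
            for combo in product(target.allowed_genotypes, repeat=len(ids)):
                val = genetic_value(dict(zip(ids, combo)), m)
                best_val = max(best_val, val)
            assert res.value == pytest.approx(best_val)

    def test_hybrid_space_contains_line_space(self):
        rng = np.random.default_rng(10)
        effects = []
        for q in ("Q1", "Q2", "Q3"):
            effects += [(q, "a", rng.normal()), (q, "d", rng.normal())]
        effects += [("Q1&Q2", "dd", rng.normal())]
        m = _model(effects)
        sl = design_superior(m, DesignTarget("GSL", "max"))
        sh = design_superior(m, DesignTarget("GSH", "max"))
        assert sh.value >= sl.value

    def test_min_equals_max_on_sign_flipped_model(self):
        rng = np.random.default_rng(11)
        effects = [("Q1", "a", rng.normal()), ("Q1", "d", rng.normal()),
                   ("Q1&Q2", "aa", rng.normal()), ("Q2", "a", rng.normal())]
        m = _model(effects)
        m_neg = _model([(t, c, -v) for t, c, v in effects])
        mn = design_superior(m, DesignTarget("GSH", "min"))
        mx = design_superior(m_neg, DesignTarget("GSH", "max"))
        assert mn.value == pytest.approx(-mx.value)
        assert mn.assignment == mx.assignment

    def test_optimum_dominates_random_assignments(self):
        rng = np.random.default_rng(12)
        ids = [f"Q{k}" for k in range(6)]
        effects = []
        for q in ids:
            effects += [(q, "a", rng.normal()), (q, "d", rng.normal())]
        effects += [("Q0&Q3", "ad", rng.normal()), ("Q1&Q4", "dd", rng.normal())]
        m = _model(effects)
        res = design_superior(m, DesignTarget("GSH", "max"))
        for _rep in range(1000):
            assign = {q: int(rng.integers(0, 3)) for q in ids}
            assert genetic_value(assign, m) <= res.value + 1e-9

    def test_environment_specific_designs_use_gxe(self):
        m = _model(
            [("Q1", "a", 0.5)],
            gxe=[("Q1", "ae", 1, 2.0), ("Q1", "ae", 2, -2.0)],
        )
        sl1 = design_superior(m, DesignTarget("SL", "max", environment=1))
        sl2 = design_superior(m, DesignTarget("SL", "max", environment=2))
        assert sl1.assignment["Q1"] == 2  # a + ae1 = 2.5 > 0
        assert sl2.assignment["Q1"] == 0  # a + ae2 = -1.5 -> qq preferred
        gsl = design_superior(m, DesignTarget("GSL", "max"))
        assert gsl.per_env_values[1] != gsl.per_env_values[2]

    def test_allele_pair_labels(self):
        m = _model([("Q1", "a", 1.0), ("Q1", "d", 2.0)], alleles={"Q1": ("T", "C")})
        gsh = design_superior(m, DesignTarget("GSH", "max"))
        assert gsh.genotype_labels["Q1"] == "TC"

    def test_target_validation(self):
        with pytest.raises(ValueError):
            DesignTarget("SL", "max")  # env required
        with pytest.raises(ValueError):
            DesignTarget("GSL", "max", environment=1)
        with pytest.raises(ValueError):
            DesignTarget("XX", "max")


class TestPleiotropyReport:
    def test_opposite_sign_conflict_flagged(self):
        ma = _model([("Q1", "a", 1.0)])
        mb = _model([("Q1", "a", -1.0)])
        rep = pleiotropy_conflict_report(
            {"ta": ma, "tb": mb},
            {"ta": DesignTarget("GSL", "max"), "tb": DesignTarget("GSL", "max")},
        )
        assert rep["conflict"].all()
        assert set(rep["genotype"]) == {"QQ", "qq"}

    def test_same_sign_no_conflict(self):
        ma = _model([("Q1", "a", 1.0)])
        mb = _model([("Q1", "a", 0.5)])
        rep = pleiotropy_conflict_report(
            {"ta": ma, "tb": mb},
            {"ta": DesignTarget("GSL", "max"), "tb": DesignTarget("GSL", "max")},
        )
        assert not rep["conflict"].any()

    def test_three_trait_toy_matches_hand_enumeration(self):
        ma = _model([("Q1", "a", 1.0), ("Q2", "a", 1.0)])
        mb = _model([("Q1", "a", -1.0)])
        mc = _model([("Q2", "a", 1.0), ("Q2", "d", 3.0)])
        targets = {t: DesignTarget("GSH", "max") for t in ("ta", "tb", "tc")}
        rep = pleiotropy_conflict_report({"ta": ma, "tb": mb, "tc": mc}, targets)
        rows = {(r["qts"], r["trait"]): r for _i, r in rep.iterrows()}
        # Q1: ta wants QQ, tb wants qq -> conflict
        assert rows[("Q1", "ta")]["genotype"] == "QQ"
        assert rows[("Q1", "tb")]["genotype"] == "qq"
        assert rows[("Q1", "ta")]["conflict"]
        # Q2: ta wants QQ (a only), tc wants Qq (d=3 dominates) -> conflict
        assert rows[("Q2", "ta")]["genotype"] == "QQ"
        assert rows[("Q2", "tc")]["genotype"] == "Qq"
        assert rows[("Q2", "tc")]["conflict"]

    def test_needs_two_traits(self):
        with pytest.raises(ValueError):
            pleiotropy_conflict_report({"ta": _model([("Q1", "a", 1.0)])}, {})
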