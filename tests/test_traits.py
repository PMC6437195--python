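"""Effective trait counts, Bonferroni thresholds, EWAS/PheWAS and
POE-by-covariate interactions."""

import numpy as np
import pandas as pd
import pytest

from poekit import mqtl, simulate as sim, traits


class TestEffectiveTraitCount:
    def test_identical_traits_collapse_to_one(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=200)
        tab = pd.DataFrame({f"t{i}": base for i in range(6)})
        assert traits.effective_trait_count(tab) == 1

    def test_two_perfectly_correlated_blocks(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=200), rng.normal(size=200)
        tab = pd.DataFrame({"a1": a, "a2": a, "b1": b, "b2": b})
        assert traits.effective_trait_count(tab) == 2

    def test_population_identity_correlation_counts_all(self):
        # 20 exactly independent traits: the 95% rule alone says 19, but all
        # trailing eigenvalues equal 1 so the Kaiser check promotes to 20 --
        # the scientifically correct count for 20 independent traits.
        with pytest.warns(UserWarning, match="disagree"):
            n_eff = traits.effective_trait_count(corr=np.eye(20))
        assert n_eff == 20

    @pytest.mark.filterwarnings("ignore:95%-variance")
    def test_sampled_independent_traits_near_full_count(self):
        rng = np.random.default_rng(3)
        tab = pd.DataFrame(rng.normal(size=(150, 20)))
        n_eff = traits.effective_trait_count(tab)
        assert 14 <= n_eff <= 20

    def test_invariance_to_order_and_affine_rescale(self):
        rng = np.random.default_rng(4)
        tab = pd.DataFrame(rng.normal(size=(120, 8)),
                           columns=[f"t{i}" for i in range(8)])
        tab["t0"] = tab["t0"] + 0.7 * tab["t1"]
        base = traits.effective_trait_count(tab)
        shuffled = tab[tab.columns[::-1]]
        scaled = tab * 3.5 + 11.0
        assert traits.effective_trait_count(shuffled) == base
        assert traits.effective_trait_count(scaled) == base

    def test_rank_zero_rejected(self):
        with pytest.raises(ValueError):
            traits.effective_trait_count(corr=np.zeros((3, 3)))


class TestBonferroni:
    @pytest.mark.parametrize("n,expect", [
        (26_568, 1.88e-6),
        (984, 5.08e-5),
        (212, 2.36e-4),
        (1, 0.05),
    ])
    def test_thresholds(self, n, expect):
        assert traits.bonferroni_threshold(n) == pytest.approx(expect,
                                                               rel=5e-3)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            traits.bonferroni_threshold(0)


@pytest.fixture(scope="module")
def trait_cpg_data():
    ped = sim.simulate_pedigree(sim.PedigreeSpec(1000, 1, seed=5))
    rng = np.random.default_rng(6)
    meth = pd.DataFrame({"cpg0": rng.normal(size=ped.n),
                         "cpg1": rng.normal(size=ped.n)}, index=ped.ids)
    return ped, meth


class TestEWAS:
    def test_trait_equal_to_cpg_slope_one(self, trait_cpg_data):
        ped, meth = trait_cpg_data
        tr = pd.DataFrame({"trait0": meth["cpg0"]}, index=meth.index)
        recs = traits.ewas(tr, meth, n_eff=1)
        rec = next(r for r in recs if r.predictor == "cpg0")
        assert rec.estimate == pytest.approx(1.0, abs=1e-10)
        assert rec.p < 1e-100
        assert rec.tier == "multi-trait"

    def test_slope_equals_correlation_on_standardised_data(self,
                                                           trait_cpg_data):
        ped, meth = trait_cpg_data
        rng = np.random.default_rng(7)
        y = 0.3 * meth["cpg0"].to_numpy() + rng.normal(size=ped.n)
        x = (meth["cpg0"] - meth["cpg0"].mean()) / meth["cpg0"].std(ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        tr = pd.DataFrame({"trait0": ys}, index=meth.index)
        mx = pd.DataFrame({"cpg0": x}, index=meth.index)
        rec = traits.ewas(tr, mx, n_eff=1)[0]
        r = np.corrcoef(x, ys)[0, 1]
        assert rec.estimate == pytest.approx(r, abs=1e-12)

    def test_planted_slope_recovered(self, trait_cpg_data):
        ped, meth = trait_cpg_data
        rng = np.random.default_rng(8)
        y = 0.3 * meth["cpg1"].to_numpy() + rng.normal(size=ped.n)
        tr = pd.DataFrame({"trait0": y}, index=meth.index)
        rec = next(r for r in traits.ewas(tr, meth, n_eff=1)
                   if r.predictor == "cpg1")
        assert rec.estimate == pytest.approx(0.3, abs=2.5 * rec.se)

    def test_tier_thresholds_ordered(self, trait_cpg_data):
        _, meth = trait_cpg_data
        assert traits.bonferroni_threshold(27 * 984) <= \
            traits.bonferroni_threshold(984)


class TestPheWAS:
    def test_matches_poe_regression(self):
        rng = np.random.default_rng(9)
        pat = rng.integers(0, 2, 500)
        mat = rng.integers(0, 2, 500)
        codings = mqtl.encode_poe(pat, mat)
        y = rng.normal(size=500)
        tr = pd.DataFrame({"trait0": y})
        recs = traits.phewas(tr, {"snp0": codings}, n_eff=1)
        direct = mqtl.poe_regression(y, codings)
        assert recs[0].beta["poe"] == pytest.approx(direct.beta["poe"])
        assert recs[0].p["poe"] == pytest.approx(direct.p["poe"])

    def test_complex_imprinting_visible_only_through_poe(self):
        # additive GWAS-blind scenario: reciprocal heterozygotes differ,
        # homozygotes identical
        rng = np.random.default_rng(10)
        pat = rng.integers(0, 2, 2000)
        mat = rng.integers(0, 2, 2000)
        codings = mqtl.encode_poe(pat, mat)
        y = 0.4 * (pat - mat) + rng.normal(size=2000)
        tr = pd.DataFrame({"wc": y})
        rec = traits.phewas(tr, {"rs0": codings}, n_eff=1)[0]
        assert rec.p["poe"] < 1e-6
        assert rec.p["add"] > 0.001
        assert abs(rec.beta["add"]) < 0.1

    def test_null_trait_calibrated(self):
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            pat = rng.integers(0, 2, 200)
            mat = rng.integers(0, 2, 200)
            codings = mqtl.encode_poe(pat, mat)
            rec = mqtl.poe_regression(rng.normal(size=200), codings)
            hits += rec.p["poe"] < 0.05
        assert hits / n_rep < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)


class TestInteractions:
    def _codings(self, rng, n):
        pat = rng.integers(0, 2, n)
        mat = rng.integers(0, 2, n)
        return mqtl.encode_poe(pat, mat)

    def test_sex_specific_effect_detected(self):
        rng = np.random.default_rng(12)
        n = 3000
        c = self._codings(rng, n)
        female = rng.integers(0, 2, n)
        y = 0.4 * c.poe * female + rng.normal(size=n)
        res = traits.poe_interaction_test(y, c, female)
        assert res.p < 0.01
        assert res.estimate == pytest.approx(0.4, abs=3 * res.se)

    def test_equal_effect_in_both_sexes_no_interaction(self):
        rng = np.random.default_rng(13)
        n = 3000
        c = self._codings(rng, n)
        female = rng.integers(0, 2, n)
        y = 0.4 * c.poe + rng.normal(size=n)
        res = traits.poe_interaction_test(y, c, female)
        assert abs(res.estimate) < 3 * res.se

    def test_single_level_moderator_rejected(self):
        rng = np.random.default_rng(14)
        c = self._codings(rng, 100)
        with pytest.raises(ValueError, match="two levels"):
            traits.poe_interaction_test(rng.normal(size=100), c,
                                        np.ones(100))

    def test_age_decile_profile(self):
        rng = np.random.default_rng(15)
        n = 4000
        c = self._codings(rng, n)
        age = rng.uniform(18, 80, n)
        effect = np.where(age > np.quantile(age, 0.9), 0.8, 0.0)
        y = effect * c.poe + rng.normal(size=n)
        tab = traits.poe_by_age_decile(y, c, age)
        assert len(tab) == 10
        top = tab[tab["decile"] == 10].iloc[0]
        rest = tab[tab["decile"] < 10]
        assert top["p_poe"] < 0.01
        assert (rest["p_poe"] < 0.01).sum() <= 1
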