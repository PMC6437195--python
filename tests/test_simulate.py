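"""Structural and statistical checks of the synthetic-data generator."""

import numpy as np
import pandas as pd
import pytest

from poekit import simulate as sim


class TestPedigree:
    def test_single_family_pair_counts_forced(self):
        ped = sim.simulate_pedigree(sim.PedigreeSpec(1, 2, seed=0))
        assert ped.pair_counts() == {"full_sib": 1, "father_offspring": 2,
                                     "mother_offspring": 2, "couple": 1}

    def test_same_seed_identical_pedigrees(self):
        spec = sim.PedigreeSpec(30, {1: 0.3, 2: 0.5, 3: 0.2}, seed=42)
        a = sim.simulate_pedigree(spec)
        b = sim.simulate_pedigree(spec)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_pair_counts_match_spec_expectation(self):
        spec = sim.PedigreeSpec(400, {2: 0.5, 3: 0.5}, seed=5)
        ped = sim.simulate_pedigree(spec)
        got = ped.pair_counts()
        want = sim.expected_pair_counts(spec)
        # sib pairs: mean 2 per family, binomial-ish spread around 800
        assert abs(got["full_sib"] - want["full_sib"]) < 4 * np.sqrt(400)
        assert got["couple"] == want["couple"]

    def test_parent_masking_creates_duos(self):
        spec = sim.PedigreeSpec(
            200, 1, seed=9,
            genotyped_parent_pattern={"trio": 0.25, "father_duo": 0.25,
                                      "mother_duo": 0.25, "none": 0.25})
        ped = sim.simulate_pedigree(spec)
        counts = ped.pair_counts(genotyped_only=True)
        # roughly half the parents of each sex are masked
        assert 50 < counts["father_offspring"] < 150
        assert 50 < counts["mother_offspring"] < 150
        assert counts["couple"] < counts["father_offspring"] + 50

    def test_invalid_proportions_rejected(self):
        with pytest.raises(sim.ConfigurationError):
            sim.PedigreeSpec(10, 2, genotyped_parent_pattern={"trio": 0.5,
                                                              "none": 0.1})

    def test_pedigree_validation_rejects_bad_parent_sex(self):
        tab = pd.DataFrame({
            "fid": ["f", "f"], "iid": ["a", "b"], "father": ["0", "a"],
            "mother": ["0", "a"], "sex": [1, 1], "genotyped": [True, True]})
        with pytest.raises(ValueError, match="inconsistent sex"):
            sim.Pedigree(tab)


class TestGenotypes:
    def test_opposite_homozygote_parents_force_heterozygous_offspring(self):
        ped = sim.simulate_pedigree(sim.PedigreeSpec(50, 2, seed=1))
        geno = sim.simulate_genotypes(ped, 80, (0.3, 0.5), seed=2)
        dos = geno.dosages()
        checked = 0
        for _, row in ped.table.iterrows():
            fa, mo = ped.parents_of(row["iid"])
            if fa is None:
                continue
            o = ped.index_of(row["iid"])
            fd, md = dos[ped.index_of(fa)], dos[ped.index_of(mo)]
            opp = (fd == 0) & (md == 2)  # father AA, mother aa
            if opp.any():
                assert np.all(dos[o, opp] == 1)
                assert np.all(geno.haplotypes[o, opp, 0] == 0)  # paternal = A
                assert np.all(geno.haplotypes[o, opp, 1] == 1)  # maternal = a
                checked += int(opp.sum())
        assert checked > 50

    def test_mendelian_consistency_everywhere(self):
        ped = sim.simulate_pedigree(sim.PedigreeSpec(40, 2, seed=3))
        geno = sim.simulate_genotypes(ped, 100, seed=4)
        dos = geno.dosages()
        for _, row in ped.table.iterrows():
            fa, mo = ped.parents_of(row["iid"])
            if fa is None:
                continue
            o = ped.index_of(row["iid"])
            pat = geno.haplotypes[o, :, 0]
            mat = geno.haplotypes[o, :, 1]
            fd = dos[ped.index_of(fa)]
            md = dos[ped.index_of(mo)]
            # transmitted allele must be carried by the corresponding parent
            assert np.all(np.where(pat == 1, fd > 0, fd < 2))
            assert np.all(np.where(mat == 1, md > 0, md < 2))

    def test_founder_allele_frequency_binomial(self):
        ped = sim.simulate_pedigree(sim.PedigreeSpec(300, 1, seed=5))
        geno = sim.simulate_genotypes(ped, 1000, (0.3, 0.3), seed=6)
        founders = [i for i, r in ped.table.iterrows()
                    if r["father"] == sim.MISSING_PARENT]
        freq = geno.haplotypes[founders].mean()
        n_haps = len(founders) * 2 * 1000
        se = np.sqrt(0.3 * 0.7 / n_haps)
        # pooled over SNPs; allow generous slack for per-SNP pooling
        assert abs(freq - 0.3) < 30 * se

    def test_determinism_and_maf_bounds(self):
        ped = sim.simulate_pedigree(sim.PedigreeSpec(10, 2, seed=7))
        a = sim.simulate_genotypes(ped, 60, seed=8)
        b = sim.simulate_genotypes(ped, 60, seed=8)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        with pytest.raises(sim.ConfigurationError):
            sim.simulate_genotypes(ped, 10, (0.001, 0.5), seed=1)


class TestMethylation:
    def test_null_plan_gives_iid_phenotype(self):
        ped = sim.simulate_pedigree(sim.PedigreeSpec(500, 2, seed=9))
        plan = sim.EffectPlan(sigma2_g=0, sigma2_k=0, sigma2_f=0, sigma2_s=0,
                              sigma2_c=0, seed=10)
        y = sim.simulate_methylation(ped, None, plan)
        sib = np.array([[y[ped.index_of(a)], y[ped.index_of(b)]]
                        for a, b in ped.full_sib_pairs()])
        r = np.corrcoef(sib[:, 0], sib[:, 1])[0, 1]
        assert abs(r) < 0.1
        assert abs(np.var(y) - 1.0) < 0.1

    def test_complex_pattern_noise_free_genotype_means(self):
        ped = sim.simulate_pedigree(sim.PedigreeSpec(300, 1, seed=11))
        geno = sim.simulate_genotypes(ped, 5, (0.3, 0.3), seed=12,
                                      n_chromosomes=1)
        beta = 0.7
        plan = sim.EffectPlan(sigma2_g=0, sigma2_k=0, sigma2_f=0, sigma2_s=0,
                              sigma2_c=0, sigma2_e=0.0, poe_model="complex",
                              causal_snp=0, poe_effect_size=beta, seed=13)
        y = sim.simulate_methylation(ped, geno, plan)
        hp = geno.haplotypes[:, 0, :]
        means = {}
        for pat, mat, name in [(0, 0, "AA"), (0, 1, "Aa"), (1, 0, "aA"),
                               (1, 1, "aa")]:
            m = (hp[:, 0] == pat) & (hp[:, 1] == mat)
            means[name] = float(y[m].mean())
        assert means["AA"] == pytest.approx(0.0, abs=1e-12)
        assert means["aa"] == pytest.approx(0.0, abs=1e-12)
        assert means["Aa"] == pytest.approx(-beta, abs=1e-12)
        assert means["aA"] == pytest.approx(+beta, abs=1e-12)

    def test_maternal_imprinting_covariance_ordering(self):
        # maternal allele silenced -> phenotype tracks the paternal allele,
        # which fathers share with offspring but mothers do not
        ped = sim.simulate_pedigree(sim.PedigreeSpec(800, 2, seed=14))
        geno = sim.simulate_genotypes(ped, 5, (0.4, 0.4), seed=15,
                                      n_chromosomes=1)
        plan = sim.EffectPlan(sigma2_g=0, sigma2_k=0, sigma2_f=0, sigma2_s=0,
                              sigma2_c=0, sigma2_e=0.2,
                              poe_model="maternal_imprinting", causal_snp=0,
                              poe_effect_size=1.0, seed=16)
        y = sim.simulate_methylation(ped, geno, plan)

        def _cov(pairs):
            a = np.array([y[ped.index_of(p)] for p, _ in pairs])
            b = np.array([y[ped.index_of(q)] for _, q in pairs])
            return float(np.cov(a, b)[0, 1])

        fo = _cov(ped.parent_offspring_pairs("father"))
        mo = _cov(ped.parent_offspring_pairs("mother"))
        ss = _cov(ped.full_sib_pairs())
        assert fo > mo
        assert ss > mo

    def test_maternal_reciprocal_heterozygotes_differ_by_2beta(self):
        ped = sim.simulate_pedigree(sim.PedigreeSpec(200, 1, seed=17))
        geno = sim.simulate_genotypes(ped, 3, (0.4, 0.4), seed=18,
                                      n_chromosomes=1)
        beta = 0.6
        plan = sim.EffectPlan(sigma2_g=0, sigma2_k=0, sigma2_f=0, sigma2_s=0,
                              sigma2_c=0, sigma2_e=0.0,
                              poe_model="maternal_imprinting", causal_snp=1,
                              poe_effect_size=beta, seed=19)
        y = sim.simulate_methylation(ped, geno, plan)
        hp = geno.haplotypes[:, 1, :]
        m_aA = y[(hp[:, 0] == 1) & (hp[:, 1] == 0)].mean()
        m_Aa = y[(hp[:, 0] == 0) & (hp[:, 1] == 1)].mean()
        assert m_aA - m_Aa == pytest.approx(2 * beta, abs=1e-12)

    def test_sib_variance_fraction_recovered_in_sib_correlation(self):
        # e_s^2 = 0.3, everything else residual: sib phenotype correlation 0.3
        spec = sim.PedigreeSpec(600, 3, seed=20)
        ped = sim.simulate_pedigree(spec)
        plan = sim.EffectPlan(sigma2_g=0, sigma2_k=0, sigma2_f=0, sigma2_s=0.3,
                              sigma2_c=0, seed=21)
        y = sim.simulate_methylation(ped, None, plan)
        pairs = ped.full_sib_pairs()
        assert len(pairs) >= 1000
        a = np.array([y[ped.index_of(p)] for p, _ in pairs])
        b = np.array([y[ped.index_of(q)] for _, q in pairs])
        r = np.corrcoef(a, b)[0, 1]
        assert abs(r - 0.3) < 0.05

    def test_overfull_variance_fractions_rejected(self):
        with pytest.raises(sim.ConfigurationError):
            sim.EffectPlan(sigma2_g=0.7, sigma2_s=0.5)


class TestTraits:
    def test_independent_traits_have_near_zero_correlation(self):
        ped = sim.simulate_pedigree(sim.PedigreeSpec(500, 2, seed=22))
        tab = sim.simulate_traits(ped, 10, seed=23)
        c = tab.corr().to_numpy()
        off = c[~np.eye(10, dtype=bool)]
        assert np.abs(off).mean() < 0.05

    def test_rank_one_correlation_gives_identical_traits(self):
        ped = sim.simulate_pedigree(sim.PedigreeSpec(50, 1, seed=24))
        corr = np.ones((4, 4))
        tab = sim.simulate_traits(ped, 4, corr, seed=25)
        for j in range(1, 4):
            np.testing.assert_allclose(tab.iloc[:, j], tab.iloc[:, 0],
                                       atol=1e-10)

    def test_planted_predictor_slope_recovered(self):
        ped = sim.simulate_pedigree(sim.PedigreeSpec(1000, 1, seed=26))
        rng = np.random.default_rng(27)
        x = rng.normal(size=ped.n)
        tab = sim.simulate_traits(ped, 1, seed=28, predictor=x, slopes=0.5)
        y = tab["trait0"].to_numpy()
        slope = np.cov(x, y)[0, 1] / np.var(x, ddof=1)
        se = np.sqrt(1.0 / (len(x) * np.var(x, ddof=1)))
        assert abs(slope - 0.5) < 2.5 * se

    def test_non_psd_correlation_rejected(self):
        ped = sim.simulate_pedigree(sim.PedigreeSpec(5, 1, seed=29))
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(sim.ConfigurationError):
            sim.simulate_traits(ped, 3, bad, seed=30)
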