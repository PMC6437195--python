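"""POE-aware association codings, regression, classification, permutation
FDR and clumping."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poekit import mqtl


def balanced_codings():
    """Equal counts of the four ordered genotype classes, 10 each."""
    pat = np.repeat([0, 0, 1, 1], 10)
    mat = np.repeat([0, 1, 0, 1], 10)
    return mqtl.encode_poe(pat, mat)


class TestEncoding:
    @pytest.mark.parametrize("pat,mat,expect", [
        (0, 0, (0, 0, 0)),    # AA
        (0, 1, (1, 1, -1)),   # Aa: paternal A, maternal a
        (1, 0, (1, 1, +1)),   # aA: paternal a, maternal A
        (1, 1, (2, 0, 0)),    # aa
    ])
    def test_coding_map(self, pat, mat, expect):
        c = mqtl.encode_poe(np.array([pat]), np.array([mat]))
        assert (c.add[0], c.dom[0], c.poe[0]) == expect
        assert c.valid[0]

    def test_ambiguous_origin_masked(self):
        c = mqtl.encode_poe(np.array([-1, 1]), np.array([0, 0]),
                            np.array(["ambiguous", "assigned"]))
        assert not c.valid[0] and c.valid[1]

    def test_balanced_classes_give_orthogonal_codings(self):
        c = balanced_codings()
        cols = c.design() - c.design().mean(axis=0)
        gram = cols.T @ cols
        off = gram[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-10)


class TestRegression:
    def test_complex_pattern_forced_solution(self):
        # group means (AA, Aa, aA, aa) = (0, -1, +1, 0)
        c = balanced_codings()
        means = {(0, 0): 0.0, (0, 1): -1.0, (1, 0): 1.0, (1, 1): 0.0}
        y = np.array([means[(p, m)] for p, m in
                      zip(np.repeat([0, 0, 1, 1], 10),
                          np.repeat([0, 1, 0, 1], 10))])
        rec = mqtl.poe_regression(y, c)
        assert rec.beta["add"] == pytest.approx(0.0, abs=1e-10)
        assert rec.beta["dom"] == pytest.approx(0.0, abs=1e-10)
        assert rec.beta["poe"] == pytest.approx(1.0, abs=1e-10)

    def test_paternal_silenced_equal_magnitude_opposite_sign(self):
        # phenotype = maternal a count: means (0, 1, 0, 1)
        c = balanced_codings()
        y = np.repeat([0.0, 1.0, 0.0, 1.0], 10)
        rec = mqtl.poe_regression(y, c)
        assert rec.beta["add"] == pytest.approx(0.5, abs=1e-10)
        assert rec.beta["dom"] == pytest.approx(0.0, abs=1e-10)
        assert rec.beta["poe"] == pytest.approx(-0.5, abs=1e-10)

    def test_poe_equals_half_reciprocal_het_difference(self):
        rng = np.random.default_rng(1)
        pat = rng.integers(0, 2, 200)
        mat = rng.integers(0, 2, 200)
        c = mqtl.encode_poe(pat, mat)
        groups = {(p, m): rng.normal() for p in (0, 1) for m in (0, 1)}
        y = np.array([groups[(p, m)] for p, m in zip(pat, mat)])
        rec = mqtl.poe_regression(y, c)
        half_diff = 0.5 * (groups[(1, 0)] - groups[(0, 1)])
        assert rec.beta["poe"] == pytest.approx(half_diff, abs=1e-10)

    def test_no_minor_homozygotes_drops_dominance(self):
        pat = np.repeat([0, 0, 1], 20)
        mat = np.repeat([0, 1, 0], 20)  # no aa class
        c = mqtl.encode_poe(pat, mat)
        rng = np.random.default_rng(2)
        rec = mqtl.poe_regression(rng.normal(size=60), c)
        assert "dom" in rec.dropped
        assert np.isnan(rec.beta["dom"])
        assert not rec.flagged

    def test_null_calibration_of_poe_pvalue(self):
        rng = np.random.default_rng(3)
        pat = rng.integers(0, 2, 300)
        mat = rng.integers(0, 2, 300)
        c = mqtl.encode_poe(pat, mat)
        hits = sum(mqtl.poe_regression(rng.normal(size=300), c).p["poe"] < 0.05
                   for _ in range(300))
        assert abs(hits / 300 - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 300)

    def test_too_few_individuals_flagged(self):
        c = mqtl.encode_poe(np.array([0, 1, 1]), np.array([0, 0, 1]))
        rec = mqtl.poe_regression(np.array([0.0, 1.0, 2.0]), c)
        assert rec.flagged


class TestCisTrans:
    @pytest.mark.parametrize("schrom,spos,cchrom,cpos,expect", [
        ("chr1", 1_500_000, "chr1", 1_000_000, "cis"),       # 500 kb
        ("chr1", 4_000_000, "chr1", 1_000_000, "excluded"),  # 3 Mb
        ("chr11", 2_705_343, "chr18", 5_000_000, "trans"),   # other chromosome
        ("chr2", 10_000_000, "chr2", 2_000_000, "trans"),    # 8 Mb
        ("chr3", 2_000_000, "chr3", 1_000_000, "excluded"),  # exactly 1 Mb
        ("chr3", 6_000_000, "chr3", 1_000_000, "excluded"),  # exactly 5 Mb
    ])
    def test_classification(self, schrom, spos, cchrom, cpos, expect):
        assert mqtl.classify_cis_trans(schrom, spos, cchrom, cpos) == expect

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.sampled_from(["chr1", "chr2"]),
           st.integers(min_value=1, max_value=20_000_000),
           st.sampled_from(["chr1", "chr2"]),
           st.integers(min_value=1, max_value=20_000_000))
    def test_every_pair_in_exactly_one_class(self, sc, sp, cc, cp):
        assert mqtl.classify_cis_trans(sc, sp, cc, cp) in {"cis", "trans",
                                                           "excluded"}


class TestPermutationFDR:
    def test_no_signal_no_threshold(self):
        rng = np.random.default_rng(4)
        obs = rng.uniform(0.5, 1.0, 100)
        perms = [rng.uniform(size=100) for _ in range(10)]
        assert mqtl.permutation_fdr(obs, perms, q=0.05) is None

    def test_planted_signal_recovered(self):
        rng = np.random.default_rng(5)
        obs = np.concatenate([np.full(50, 1e-8), rng.uniform(size=950)])
        perms = [rng.uniform(size=1000) for _ in range(10)]
        t = mqtl.permutation_fdr(obs, perms, q=0.05)
        assert t is not None
        n_called = np.sum(obs <= t)
        assert n_called >= 50
        est_fdr = np.mean([np.sum(p <= t) for p in perms]) / n_called
        assert est_fdr <= 0.05

    def test_threshold_matches_bruteforce_ratio(self):
        rng = np.random.default_rng(6)
        obs = rng.uniform(size=40) ** 2
        perms = [rng.uniform(size=40) for _ in range(5)]
        t = mqtl.permutation_fdr(obs, perms, q=0.2)
        # brute force over the sorted observed grid
        best = None
        for cand in np.sort(obs):
            r = np.sum(obs <= cand)
            v = np.mean([np.sum(p <= cand) for p in perms])
            if r and v / r <= 0.2:
                best = cand
        assert (t is None) == (best is None)
        if t is not None:
            assert t == pytest.approx(best)

    def test_degenerate_q_one_accepts_everything(self):
        obs = np.array([0.2, 0.9, 0.99])
        perms = [np.array([0.1, 0.5, 0.7])]
        t = mqtl.permutation_fdr(obs, perms, q=1.0)
        assert t == pytest.approx(0.99)


def clump_oracle(pos, p, r2, chrom, window, r2_cut, p_cut):
    """Direct restatement of the greedy rule, kept independent of the
    implementation's vectorised bookkeeping."""
    n = len(pos)
    assignment = [-1] * n
    free = [i for i in range(n) if p[i] <= p_cut]
    while free:
        idx = min(free, key=lambda i: p[i])
        members = [i for i in free
                   if chrom[i] == chrom[idx] and abs(pos[i] - pos[idx]) <= window
                   and r2[idx][i] >= r2_cut]
        if idx not in members:
            members.append(idx)
        for i in members:
            assignment[i] = idx
        free = [i for i in free if i not in members]
    return assignment


class TestClump:
    def test_correlated_nearby_pair_single_clump(self):
        pos = np.array([100_000, 200_000])
        p = np.array([1e-8, 1e-6])
        r2 = np.array([[1.0, 0.5], [0.5, 1.0]])
        a = mqtl.clump(pos, p, r2)
        assert list(a) == [0, 0]

    def test_uncorrelated_pair_two_indices(self):
        pos = np.array([100_000, 200_000])
        p = np.array([1e-8, 1e-6])
        r2 = np.array([[1.0, 0.05], [0.05, 1.0]])
        assert list(mqtl.clump(pos, p, r2)) == [0, 1]

    def test_outside_window_two_indices(self):
        pos = np.array([100_000, 700_000])
        p = np.array([1e-8, 1e-6])
        r2 = np.array([[1.0, 0.9], [0.9, 1.0]])
        assert list(mqtl.clump(pos, p, r2)) == [0, 1]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=2, max_value=15), st.integers(0, 2 ** 31 - 1))
    def test_matches_exhaustive_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        pos = rng.integers(0, 1_000_000, size=n)
        p = rng.uniform(size=n)
        corr = rng.uniform(size=(n, n))
        r2 = (corr + corr.T) / 2
        np.fill_diagonal(r2, 1.0)
        chrom = rng.integers(0, 2, size=n)
        got = mqtl.clump(pos, p, r2, chrom=chrom, window=300_000,
                         r2_cut=0.3, p_cut=0.9)
        want = clump_oracle(pos, p, r2, chrom, 300_000, 0.3, 0.9)
        assert list(got) == want
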