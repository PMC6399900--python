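import itertools
from math import comb, sqrt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolscan.poolseq_inference import (FoldedSFS, PoolModel,
                                        estimate_sfs_em,
                                        folded_site_likelihood,
                                        ml_frequency_lookup,
                                        ml_site_frequency,
                                        nucleotide_diversity,
                                        pool_read_likelihood,
                                        posterior_frequency_lookup,
                                        posterior_site_frequency,
                                        tajimas_d)


def brute_force_read_likelihood(k, r, y, n, eps):
    """Oracle: enumerate every (true allele, error) configuration of the
    ordered reads; a read shows the focal allele if it sampled a focal
    chromosome and was read correctly, or a non-focal one read wrongly."""
    total = 0.0
    for trues in itertools.product([0, 1], repeat=r):
        for flips in itertools.product([0, 1], repeat=r):
            shown = tuple(t ^ f for t, f in zip(trues, flips))
            if sum(shown) != k or any(shown[:k]) == 0 and k > 0:
                pass
            # require the first k reads focal, rest non-focal (ordered)
            if shown != tuple([1] * k + [0] * (r - k)):
                continue
            p = 1.0
            for t, f in zip(trues, flips):
                p *= (y / n) if t else (1 - y / n)
                p *= eps if f else (1 - eps)
            total += p
    return total


class TestPoolReadLikelihood:
    def test_all_reads_derived_certain(self):
        m = PoolModel(n=40, epsilon=0.0)
        assert pool_read_likelihood(6, 6, 40, m) == pytest.approx(1.0)

    def test_half_pool_symmetry(self):
        for eps in (0.0, 0.01, 0.2):
            m = PoolModel(n=40, epsilon=eps)
            for k, r in ((0, 4), (2, 4), (7, 9)):
                assert pool_read_likelihood(k, r, 20, m) == \
                    pytest.approx(0.5 ** r, rel=1e-12)

    def test_worked_example(self):
        m = PoolModel(n=40, epsilon=0.01)
        expect = 0.255 ** 2 * 0.745 ** 2
        assert pool_read_likelihood(2, 4, 10, m) == \
            pytest.approx(expect, rel=1e-12)

    @pytest.mark.parametrize("eps", [0.0, 0.001, 0.05, 0.3])
    @pytest.mark.parametrize("r", [1, 3, 5])
    def test_matches_per_read_enumeration(self, r, eps):
        m = PoolModel(n=8, epsilon=eps)
        for y in (0, 1, 4, 8):
            for k in range(r + 1):
                oracle = brute_force_read_likelihood(k, r, y, 8, eps)
                assert pool_read_likelihood(k, r, y, m) == \
                    pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize("r", [1, 4, 8, 12])
    def test_completeness_over_k(self, r):
        for eps in (0.0, 0.01, 0.3):
            m = PoolModel(n=40, epsilon=eps)
            for y in (0, 1, 13, 40):
                s = sum(comb(r, k) * pool_read_likelihood(k, r, y, m)
                        for k in range(r + 1))
                assert s == pytest.approx(1.0, abs=1e-12)

    def test_domain_violations_raise(self):
        m = PoolModel(n=40, epsilon=0.01)
        with pytest.raises(ValueError):
            pool_read_likelihood(5, 4, 10, m)
        with pytest.raises(ValueError):
            pool_read_likelihood(1, 4, 41, m)


class TestFoldedLikelihood:
    def test_symmetric_case_unchanged(self):
        m = PoolModel(n=40, epsilon=0.07)
        assert folded_site_likelihood(3, 6, 20, m) == \
            pytest.approx(0.5 ** 6, rel=1e-12)

    def test_boundary_half(self):
        m = PoolModel(n=40, epsilon=0.0)
        assert folded_site_likelihood(0, 5, 0, m) == pytest.approx(0.5)

    @given(st.integers(0, 10), st.integers(0, 40),
           st.floats(0.0, 0.4))
    @settings(deadline=None, max_examples=50)
    def test_fold_swap_identity(self, k, y, eps):
        r = 10
        m = PoolModel(n=40, epsilon=eps)
        lhs = folded_site_likelihood(k, r, y, m)
        rhs = 0.5 * (pool_read_likelihood(k, r, y, m)
                     + pool_read_likelihood(r - k, r, y, m))
        assert lhs == pytest.approx(rhs, rel=1e-12)
        assert folded_site_likelihood(r - k, r, y, m) == \
            pytest.approx(lhs, rel=1e-12)


def brute_force_ml(k, r, model):
    lls = [pool_read_likelihood(k, r, y, model)
           for y in range(model.n + 1)]
    best = max(lls)
    ties = [y for y, v in enumerate(lls) if v >= best * (1 - 1e-12)]
    return min(ties) if k / r <= 0.5 else max(ties)


class TestMLSiteFrequency:
    def test_zero_reads_zero_count(self):
        m = PoolModel(n=40, epsilon=0.0)
        assert ml_site_frequency(0, 10, m).y_hat == 0

    def test_exact_half(self):
        m = PoolModel(n=40, epsilon=0.0)
        assert ml_site_frequency(5, 10, m).y_hat == 20

    def test_all_derived_with_error(self):
        m = PoolModel(n=40, epsilon=0.01)
        assert ml_site_frequency(30, 30, m).y_hat == 40

    @pytest.mark.parametrize("eps", [0.0, 0.001, 0.05])
    def test_matches_brute_force(self, eps):
        m = PoolModel(n=20, epsilon=eps)
        rng = np.random.default_rng(3)
        for _ in range(40):
            r = int(rng.integers(1, 60))
            k = int(rng.integers(0, r + 1))
            assert ml_site_frequency(k, r, m).y_hat == \
                brute_force_ml(k, r, m)

    def test_lookup_table_matches_single_site(self):
        m = PoolModel(n=40, epsilon=0.001)
        lut = ml_frequency_lookup(25, m)
        rng = np.random.default_rng(5)
        for _ in range(60):
            r = int(rng.integers(1, 26))
            k = int(rng.integers(0, r + 1))
            assert lut[r, k] == ml_site_frequency(k, r, m).y_hat

    def test_high_coverage_converges_to_read_fraction(self):
        m = PoolModel(n=40, epsilon=0.0)
        for frac in (0.1, 0.33, 0.74):
            r = 4000
            k = int(round(frac * r))
            assert ml_site_frequency(k, r, m).y_hat == round(40 * k / r)


class TestPosteriorFrequency:
    def _prior(self, n=40):
        phi = np.zeros(n // 2 + 1)
        phi[0] = 0.9
        phi[1:] = 0.1 / (n // 2)
        return FoldedSFS(n=n, phi=phi)

    def test_extreme_reads_stay_near_boundary(self):
        m = PoolModel(n=40, epsilon=0.001)
        prior = self._prior()
        assert posterior_site_frequency(34, 34, m, prior) > 0.95
        assert posterior_site_frequency(0, 34, m, prior) < 0.05

    def test_lower_estimation_error_than_ml(self):
        """On data drawn from the prior mixture the posterior mean has a
        smaller mean-squared error than the integer ML estimate — the
        variance reduction that keeps per-site F_ST unbiased."""
        m = PoolModel(n=40, epsilon=0.001)
        prior = self._prior()
        rng = np.random.default_rng(17)
        S, r = 20_000, 20
        c = rng.choice(len(prior.phi), size=S, p=prior.phi)
        y = np.where(rng.random(S) < 0.5, c, 40 - c)
        k = rng.binomial(r, m.read_prob(y))
        post_lut = posterior_frequency_lookup(r, m, prior)
        ml_lut = ml_frequency_lookup(r, m)
        p_true = y / 40.0
        mse_post = np.mean((post_lut[r, k] - p_true) ** 2)
        mse_ml = np.mean((ml_lut[r, k] / 40.0 - p_true) ** 2)
        assert mse_post < mse_ml

    def test_lookup_monotone_in_k(self):
        m = PoolModel(n=40, epsilon=0.001)
        lut = posterior_frequency_lookup(30, m, self._prior())
        row = lut[30, :31]
        assert np.all(np.diff(row) > 0)


class TestEstimateSfsEM:
    def test_monomorphic_data(self):
        m = PoolModel(n=40, epsilon=0.0)
        sfs = estimate_sfs_em([(0, 30)] * 200, m)
        assert sfs.phi[0] == pytest.approx(1.0, abs=1e-6)
        assert sfs.prop_polymorphic == pytest.approx(0.0, abs=1e-6)

    def test_single_site_one_em_step_matches_hand_posterior(self):
        m = PoolModel(n=4, epsilon=0.01)
        k, r = 2, 6
        sfs = estimate_sfs_em([(k, r)], m, max_iter=1)
        classes = [0, 1, 2]
        lik = []
        for c in classes:
            fold = folded_site_likelihood(k, r, c, m) if 2 * c != 4 else \
                pool_read_likelihood(k, r, c, m)
            lik.append(comb(r, k) * fold)
        post = np.array(lik) / sum(lik)  # uniform prior cancels
        np.testing.assert_allclose(sfs.phi, post, atol=1e-12)

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(11)
        m = PoolModel(n=40, epsilon=0.001)
        k = rng.integers(0, 31, size=400)
        recs = np.column_stack([k, np.full(400, 30)])
        sfs = estimate_sfs_em(recs, m)
        assert np.all(np.diff(sfs.loglik_path) >= -1e-8)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            estimate_sfs_em([], PoolModel())


class TestNucleotideDiversity:
    def test_no_polymorphism(self):
        assert nucleotide_diversity(np.zeros(10), n=40, L=100) == 0.0

    def test_single_intermediate_site(self):
        got = nucleotide_diversity(np.array([0.5]), n=40, L=1000)
        assert got == pytest.approx((40 / 39) * 0.5 / 1000, rel=1e-9)
        assert got == pytest.approx(5.128e-4 / 1000 * 1000, abs=1e-7)

    def test_folding_invariance(self):
        p = np.array([0.1, 0.3, 0.45])
        a = nucleotide_diversity(p, n=40, L=10)
        b = nucleotide_diversity(1 - p, n=40, L=10)
        assert a == pytest.approx(b, rel=1e-12)

    def test_from_folded_sfs(self):
        phi = np.zeros(21)
        phi[0], phi[20] = 0.9, 0.1
        sfs = FoldedSFS(n=40, phi=phi)
        assert nucleotide_diversity(sfs) == \
            pytest.approx(0.1 * (40 / 39) * 0.5, rel=1e-12)

    def test_L_smaller_than_polymorphic_count_rejected(self):
        with pytest.raises(ValueError):
            nucleotide_diversity(np.array([0.5, 0.5]), n=40, L=1)


def tajima_oracle(xi, n):
    """Independent re-derivation of Tajima's test statistic."""
    xi = np.asarray(xi, dtype=float)
    S = xi.sum()
    pi = 0.0
    for i, count in enumerate(xi, start=1):
        pi += count * i * (n - i)
    pi /= comb(n, 2)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1.0) / (3 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1, e2 = c1 / a1, c2 / (a1 ** 2 + a2)
    return (pi - S / a1) / sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        assert np.isnan(tajimas_d(np.zeros(9), n=10))

    def test_neutral_expectation_gives_zero(self):
        n, theta = 10, 10.0
        xi = theta / np.arange(1, n)
        assert tajimas_d(xi, n) == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_independent_oracle(self):
        assert tajimas_d([3, 1, 1], n=4) == \
            pytest.approx(tajima_oracle([3, 1, 1], 4), abs=1e-12)
        rng = np.random.default_rng(2)
        for n in (5, 12, 40):
            xi = rng.integers(0, 20, size=n - 1)
            if xi.sum() == 0:
                xi[0] = 1
            assert tajimas_d(xi, n) == \
                pytest.approx(tajima_oracle(xi, n), abs=1e-12)

    def test_folded_input_equivalent(self):
        # pairwise-difference terms are symmetric in i <-> n-i
        n = 10
        unfolded = np.array([4, 2, 1, 0, 3, 0, 1, 2, 4], dtype=float)
        folded = np.zeros(5)
        for i in range(1, n):
            folded[min(i, n - i) - 1] += unfolded[i - 1]
        assert tajimas_d(unfolded, n) == \
            pytest.approx(tajimas_d(folded, n), rel=1e-12)
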