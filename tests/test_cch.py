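"""Cross-correlogram baseline: counts, smoothing, significance, p_trans."""

import numpy as np
import pytest

from refractiv.cch import (
    Correlogram, cross_correlogram, hollow_gaussian_baseline,
    poisson_continuity_pvalue, significance_tests, transmission_probability,
    cch_estimate,
)


def brute_force_counts(pre, post, max_lag):
    counts = np.zeros(2 * max_lag + 1, dtype=int)
    for s in pre:
        for t in post:
            if abs(t - s) <= max_lag:
                counts[t - s + max_lag] += 1
    return counts


class TestCrossCorrelogram:
    def test_identical_trains_peak_at_zero(self):
        spikes = np.arange(0, 1000, 113)
        cch = cross_correlogram(spikes, spikes, max_lag=5)
        assert cch.at(0) == spikes.size

    def test_pure_shift(self):
        pre = np.arange(0, 2000, 151)
        cch = cross_correlogram(pre, pre + 3, max_lag=5)
        assert cch.at(3) == pre.size
        assert cch.counts.sum() == pre.size

    def test_enumerated_example(self):
        cch = cross_correlogram([0, 10], [3, 13, 14], max_lag=5)
        assert cch.at(3) == 2
        assert cch.at(4) == 1
        assert cch.counts.sum() == 3

    def test_empty_trains(self):
        cch = cross_correlogram([], [1, 2], max_lag=4)
        assert not cch.counts.any()

    def test_total_matches_brute_force_pair_count(self, rng):
        pre = np.sort(rng.choice(3000, 80, replace=False))
        post = np.sort(rng.choice(3000, 90, replace=False))
        cch = cross_correlogram(pre, post, max_lag=20)
        assert np.array_equal(cch.counts,
                              brute_force_counts(pre, post, 20))


class TestHollowGaussianBaseline:
    def test_flat_counts_preserved(self):
        cch = Correlogram(np.full(101, 7), max_lag=50, n_presyn=10)
        base = hollow_gaussian_baseline(cch)
        assert np.allclose(base, 7.0)

    def test_zero_hollow_is_plain_gaussian(self, rng):
        counts = rng.poisson(5, 101)
        cch = Correlogram(counts, max_lag=50, n_presyn=10)
        base = hollow_gaussian_baseline(cch, kernel_sd=3.0, hollow_fraction=0.0)
        # direct-convolution oracle with reflection padding
        radius = int(np.ceil(9.0))
        taps = np.exp(-0.5 * (np.arange(-radius, radius + 1) / 3.0) ** 2)
        taps /= taps.sum()
        padded = np.pad(counts.astype(float), radius, mode="reflect")
        oracle = np.convolve(padded, taps, mode="valid")
        assert np.allclose(base, oracle)

    def test_single_peak_hollowed_center(self):
        counts = np.zeros(101, dtype=int)
        counts[50] = 1
        cch = Correlogram(counts, max_lag=50, n_presyn=1)
        base = hollow_gaussian_baseline(cch, kernel_sd=10.0,
                                        hollow_fraction=0.6)
        radius = 30
        g = np.exp(-0.5 * (np.arange(-radius, radius + 1) / 10.0) ** 2)
        hollowed = g.copy()
        hollowed[radius] *= 0.4
        assert base[50] == pytest.approx(0.4 * g[radius] / hollowed.sum())


class TestPoissonPvalue:
    def test_edge_cases(self):
        assert poisson_continuity_pvalue(0, 0.0) == pytest.approx(0.5)
        assert poisson_continuity_pvalue(1, 0.0) == pytest.approx(0.0)

    def test_strong_excess(self):
        # direct summation: 1 - CDF(9; 1) - pmf(10; 1)/2 = 6.074e-8
        assert poisson_continuity_pvalue(10, 1.0) == pytest.approx(
            6.074e-8, rel=1e-3)

    def test_matches_direct_summation_oracle(self):
        from math import exp, factorial

        for N, lam in [(0, 2.0), (3, 2.5), (10, 1.0), (40, 50.0), (100, 50.0)]:
            direct = (1.0
                      - sum(exp(-lam) * lam**k / factorial(k)
                            for k in range(N))
                      - exp(-lam) * lam**N / (2 * factorial(N)))
            direct = min(max(direct, 0.0), 1.0)
            assert poisson_continuity_pvalue(N, lam) == pytest.approx(
                direct, abs=1e-10)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            poisson_continuity_pvalue(-1, 1.0)
        with pytest.raises(ValueError):
            poisson_continuity_pvalue(1, -1.0)


class TestSignificance:
    def test_all_zero_correlogram(self):
        cch = Correlogram(np.zeros(41, dtype=int), max_lag=20, n_presyn=0)
        base = hollow_gaussian_baseline(cch)
        assert significance_tests(cch, base) == (1.0, 1.0)

    def test_symmetric_correlogram_not_directed(self, rng):
        counts = rng.poisson(20, 41)
        counts = counts + counts[::-1]  # force symmetry
        cch = Correlogram(counts, max_lag=20, n_presyn=100)
        base = hollow_gaussian_baseline(cch)
        _, p_diff = significance_tests(cch, base)
        # peak equals its mirror: N = lambda gives p >= ~0.5
        assert p_diff >= 0.4

    def test_strong_causal_peak_detected(self):
        counts = np.full(41, 5)
        counts[20 + 3] = 50
        cch = Correlogram(counts, max_lag=20, n_presyn=100)
        base = hollow_gaussian_baseline(cch)
        p_fast, p_diff = significance_tests(cch, base)
        assert p_fast < 1e-15
        assert p_diff < 1e-15


class TestTransmissionProbability:
    def test_zero_when_counts_equal_baseline(self):
        cch = Correlogram(np.full(101, 9), max_lag=50, n_presyn=40)
        base = hollow_gaussian_baseline(cch)
        assert transmission_probability(cch, base) == pytest.approx(0.0)

    def test_excess_counts_per_presyn_spike(self):
        counts = np.full(101, 10)
        for m in (3, 4, 5, 6):
            counts[50 + m] += 5
        cch = Correlogram(counts, max_lag=50, n_presyn=100)
        base = np.full(101, 10.0)  # fixed baseline isolates the excess
        assert transmission_probability(cch, base) == pytest.approx(0.2)

    def test_homogeneity_in_n(self):
        counts = np.full(101, 10)
        counts[53] += 8
        base = np.full(101, 10.0)
        a = transmission_probability(
            Correlogram(counts, 50, n_presyn=100), base)
        b = transmission_probability(
            Correlogram(counts * 2, 50, n_presyn=200), base * 2)
        assert a == pytest.approx(b)

    def test_common_offset_invariance(self):
        counts = np.full(101, 10)
        counts[54] += 6
        base = np.full(101, 10.0)
        a = transmission_probability(Correlogram(counts, 50, 100), base)
        b = transmission_probability(Correlogram(counts + 50, 50, 100),
                                     base + 50)
        assert a == pytest.approx(b, abs=1e-10)

    def test_undefined_without_presyn_spikes(self):
        cch = Correlogram(np.zeros(101, dtype=int), max_lag=50, n_presyn=0)
        assert np.isnan(transmission_probability(cch, np.zeros(101)))


def test_false_positive_rate_on_independent_trains(rng):
    """Significance gate fires at <= ~1% on uncoupled Poisson-like pairs."""
    n_pairs, horizon, rate = 400, 30_000, 0.01
    fired = 0
    for _ in range(n_pairs):
        pre = np.flatnonzero(rng.random(horizon) < rate)
        post = np.flatnonzero(rng.random(horizon) < rate)
        res = cch_estimate(pre, post, max_lag=50)
        fired += res.significant
    p = 0.01
    bound = n_pairs * p + 3 * np.sqrt(n_pairs * p * (1 - p))
    assert fired <= bound
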