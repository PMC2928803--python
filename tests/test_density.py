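"""Adaptive binning, histogram densities, finite-sampling weights, sparse ECDF."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cmefit as cf
from cmefit.density import BinnedDensity, BinningScheme, lookup_probs


class TestBuildBins:
    def test_exactly_filled_unit_bins_stay(self):
        samples = np.repeat(np.arange(10), 10)
        scheme = cf.build_bins(samples, min_count=10)
        np.testing.assert_array_equal(scheme.edges, np.arange(11.0))

    def test_underfilled_collapses_to_single_bin(self):
        scheme = cf.build_bins([5] * 5, min_count=10)
        assert scheme.n_bins == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cf.build_bins([], min_count=10)

    def test_merged_bins_meet_occupancy(self):
        rng = np.random.default_rng(3)
        samples = rng.poisson(4.0, size=500)
        scheme = cf.build_bins(samples, min_count=10)
        assert np.all(scheme.counts(samples) >= 10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-5, 30), min_size=1, max_size=200),
           st.randoms(use_true_random=False))
    def test_permutation_invariant(self, values, rnd):
        shuffled = list(values)
        rnd.shuffle(shuffled)
        e1 = cf.build_bins(values).edges
        e2 = cf.build_bins(shuffled).edges
        np.testing.assert_array_equal(e1, e2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 50), min_size=1, max_size=300))
    def test_occupancy_rule_holds_or_single_bin(self, values):
        scheme = cf.build_bins(values, min_count=10)
        counts = scheme.counts(values)
        assert scheme.n_bins == 1 or np.all(counts >= 10)


class TestPdfCdf:
    def test_counts_to_probabilities(self):
        scheme = BinningScheme([0.0, 1.0, 2.0])
        samples = np.array([0] * 60 + [1] * 40)
        pdf = cf.pdf_from_samples(samples, scheme)
        np.testing.assert_allclose(pdf.probs, [0.6, 0.4])
        np.testing.assert_allclose(pdf.variances, [0.0024, 0.0024])
        cdf = cf.cdf_from_pdf(pdf)
        np.testing.assert_allclose(cdf.probs, [0.6, 1.0])
        assert cdf.variances[-1] == 0.0

    def test_pdf_normalization_random_samples(self):
        rng = np.random.default_rng(0)
        samples = rng.poisson(7, 400)
        pdf = cf.pdf_from_samples(samples, cf.build_bins(samples))
        assert pdf.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_counted_into_edge_bins(self):
        scheme = BinningScheme([0.0, 1.0, 2.0])
        pdf = cf.pdf_from_samples([-5, 0, 1, 99], scheme)
        np.testing.assert_allclose(pdf.probs, [0.5, 0.5])

    def test_convergence_in_total_variation(self):
        """Histogram converges to the sampled law as N grows 1e2 -> 1e5."""
        from scipy import stats

        rng = np.random.default_rng(42)
        lam = 6.0
        tv = []
        for n in [100, 1000, 10_000, 100_000]:
            samples = rng.poisson(lam, n)
            scheme = BinningScheme(np.arange(0.0, 26.0))  # fixed unit bins
            pdf = cf.pdf_from_samples(samples, scheme)
            truth = stats.poisson.pmf(np.arange(25), lam)
            tv.append(0.5 * np.abs(pdf.probs - truth / truth.sum()).sum())
        assert tv[-1] < tv[0] and tv[-1] < 0.01


class TestBinomialVariance:
    def test_closed_form_values(self):
        assert cf.binomial_variance(0.5, 100) == pytest.approx(0.0025)
        assert cf.binomial_variance(0.6, 100) == pytest.approx(0.0024)
        assert cf.binomial_variance(0.0, 17) == 0.0
        assert cf.binomial_variance(1.0, 17) == 0.0

    def test_matches_bootstrap_bin_frequency_variance(self):
        rng = np.random.default_rng(7)
        n, p = 500, 0.6
        freqs = rng.binomial(n, p, size=10_000) / n
        assert np.var(freqs) == pytest.approx(cf.binomial_variance(p, n), rel=0.1)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            cf.binomial_variance(1.5, 10)

    def test_cdf_cov_monotone_decreasing(self):
        """CoV sqrt((1-F)/(N F)) falls as F rises: deep CDF levels are the
        best-resolved, the motivation for the CDF-distance criterion."""
        f = np.linspace(0.01, 0.99, 200)
        cov = np.sqrt(cf.binomial_variance(f, 1000)) / f
        assert np.all(np.diff(cov) < 0)


class TestSparseECDF:
    def test_plotting_positions_m10(self):
        e = cf.sparse_ecdf(np.arange(10))
        np.testing.assert_allclose(e.positions, np.arange(0.05, 1.0, 0.1))

    def test_single_replicate(self):
        e = cf.sparse_ecdf([4])
        np.testing.assert_allclose(e.positions, [0.5])

    def test_sorting_and_hand_positions(self):
        e = cf.sparse_ecdf([3, 1, 2])
        np.testing.assert_array_equal(e.values, [1, 2, 3])
        np.testing.assert_allclose(e.positions, [1 / 6, 1 / 2, 5 / 6])

    def test_ties_keep_consecutive_positions(self):
        e = cf.sparse_ecdf([2, 2, 2, 1])
        np.testing.assert_allclose(e.positions, [0.125, 0.375, 0.625, 0.875])
        assert np.all(np.diff(e.positions) > 0)


class TestLikelihoodLookup:
    def _pdf(self, probs, n):
        edges = np.arange(len(probs) + 1, dtype=float)
        return BinnedDensity("pdf", BinningScheme(edges), np.asarray(probs), n)

    def test_simple_bin_probability(self):
        assert cf.likelihood_lookup(self._pdf([0.8, 0.2], 100), 1.5) == pytest.approx(0.2)

    def test_floor_outside_support(self):
        pdf = self._pdf([1.0, 0.0], 10_000)
        assert cf.likelihood_lookup(pdf, 99) == pytest.approx(1e-5)
        assert cf.likelihood_lookup(pdf, -3) == pytest.approx(1e-5)

    def test_floor_in_zero_probability_bin(self):
        pdf = self._pdf([1.0, 0.0], 1000)
        assert cf.likelihood_lookup(pdf, 1.2) == pytest.approx(1.0 / 10_000)

    def test_shared_edge_goes_right(self):
        pdf = self._pdf([0.3, 0.7], 100)
        assert cf.likelihood_lookup(pdf, 1.0) == pytest.approx(0.7)

    def test_vectorized_matches_scalar(self):
        pdf = self._pdf([0.5, 0.3, 0.2], 50)
        obs = np.array([-1, 0, 1, 2, 3, 7])
        vec = lookup_probs(pdf, obs)
        scalar = [cf.likelihood_lookup(pdf, o) for o in obs]
        np.testing.assert_allclose(vec, scalar)
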