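"""Estimation criteria: hand-checked values, invariants, and discrimination."""

import numpy as np
import pytest

import cmefit as cf
from cmefit.density import BinnedDensity, BinningScheme
from cmefit.objectives import interp_cdf
from conftest import two_bin_pair


class TestNegLogLikelihood:
    def _pdf(self, probs, n=1000):
        edges = np.arange(len(probs) + 1, dtype=float)
        return BinnedDensity("pdf", BinningScheme(edges), np.asarray(probs), n)

    def test_certain_bins_give_zero(self):
        pdf = self._pdf([1.0])
        assert cf.neg_log_likelihood(np.zeros((5, 1), dtype=int), [pdf]) == 0.0

    def test_single_observation_closed_form(self):
        pdf = self._pdf([0.1, 0.9])
        val = cf.neg_log_likelihood(np.array([[0]]), [pdf])
        assert val == pytest.approx(2.302585, abs=1e-6)

    def test_two_replicates_hand_sum(self):
        pdf = self._pdf([0.5, 0.25, 0.25])
        val = cf.neg_log_likelihood(np.array([[0], [1]]), [pdf])
        assert val == pytest.approx(np.log(2) + np.log(4), abs=1e-9)

    def test_finite_for_unexplained_observations(self):
        pdf = self._pdf([1.0], n=100)
        val = cf.neg_log_likelihood(np.array([[500]]), [pdf])
        assert np.isfinite(val) and val == pytest.approx(-np.log(1e-3))


class TestDfdPdf:
    def test_identical_densities_zero(self):
        d, _ = two_bin_pair()
        assert cf.dfd_pdf(d, d) == 0.0

    def test_two_bin_hand_value(self):
        d, m = two_bin_pair()
        assert cf.dfd_pdf(d, m) == pytest.approx(4.1666667, abs=1e-6)

    def test_last_bin_excluded(self):
        # normalization ties the last bin to the others, so only the first
        # L-1 bins enter: the bin-3 discrepancy here contributes nothing
        scheme = BinningScheme([0.0, 1.0, 2.0, 3.0])
        d = BinnedDensity("pdf", scheme, np.array([0.5, 0.3, 0.2]), 100)
        m = BinnedDensity("pdf", scheme, np.array([0.5, 0.2, 0.3]), 100)
        expected = 0.1**2 / (0.3 * 0.7 / 100)
        assert cf.dfd_pdf(d, m) == pytest.approx(expected)

    def test_mismatched_schemes_rejected(self):
        d, _ = two_bin_pair()
        other = BinnedDensity("pdf", BinningScheme([0.0, 2.0, 4.0]), np.array([0.6, 0.4]), 100)
        with pytest.raises(ValueError, match="binning"):
            cf.dfd_pdf(d, other)

    def test_zero_variance_agreement_contributes_nothing(self):
        scheme = BinningScheme([0.0, 1.0, 2.0])
        d = BinnedDensity("pdf", scheme, np.array([0.0, 1.0]), 100)
        m = BinnedDensity("pdf", scheme, np.array([0.0, 1.0]), 100)
        assert cf.dfd_pdf(d, m) == 0.0

    def test_zero_variance_disagreement_uses_floor(self):
        scheme = BinningScheme([0.0, 1.0, 2.0])
        d = BinnedDensity("pdf", scheme, np.array([0.0, 1.0]), 100)
        m = BinnedDensity("pdf", scheme, np.array([0.3, 0.7]), 100)
        # floor variance 1/(4 N^2): (0.3)^2 / (1/40000)
        assert cf.dfd_pdf(d, m) == pytest.approx(0.09 * 4 * 100**2)


class TestDfdCdf:
    def test_two_bin_hand_value(self):
        scheme = BinningScheme([0.0, 1.0, 2.0])
        d = BinnedDensity("cdf", scheme, np.array([0.6, 1.0]), 100)
        m = BinnedDensity("cdf", scheme, np.array([0.5, 1.0]), 100)
        assert cf.dfd_cdf(d, m) == pytest.approx(4.1666667, abs=1e-6)
        assert cf.dfd_cdf(d, d) == 0.0

    def test_sparse_mode_model_mass_below_data(self):
        """All simulated mass below the smallest datum: model CDF reads 1
        at every order statistic and each of the m terms enters."""
        data = cf.sparse_ecdf(np.arange(100, 110))
        scheme = BinningScheme([0.0, 1.0, 2.0])
        model = BinnedDensity("cdf", scheme, np.array([0.4, 1.0]), 1000)
        pos = data.positions
        expected = np.sum((pos - 1.0) ** 2 / (pos * (1 - pos) / 10))
        assert cf.dfd_cdf([data], [model]) == pytest.approx(expected)

    def test_sparse_mode_perfect_interpolation_is_small(self):
        rng = np.random.default_rng(0)
        samples = rng.poisson(20, 5000)
        scheme = cf.build_bins(samples)
        model = cf.cdf_from_pdf(cf.pdf_from_samples(samples, scheme))
        data = cf.sparse_ecdf(np.quantile(samples, np.arange(0.05, 1.0, 0.1),
                                          method="nearest"))
        # same underlying law: distance far below the all-wrong case
        assert cf.dfd_cdf([data], [model]) < 5.0


class TestDfdMax:
    def test_identical_zero(self):
        d, _ = two_bin_pair()
        assert cf.dfd_max(d, d, "pdf") == 0.0

    def test_two_bin_hand_value(self):
        d, m = two_bin_pair()
        assert cf.dfd_max(d, m, "pdf") == pytest.approx(2.0412415, abs=1e-6)

    def test_sums_per_timepoint_maxima(self):
        d, m = two_bin_pair()
        assert cf.dfd_max([d, d], [m, m], "pdf") == pytest.approx(2 * 2.0412415, abs=1e-5)


def test_interp_cdf_saturates_outside_support():
    scheme = BinningScheme([10.0, 11.0, 12.0])
    model = BinnedDensity("cdf", scheme, np.array([0.5, 1.0]), 100)
    vals = interp_cdf(model, np.array([0.0, 10.25, 50.0]))
    assert vals[0] == 0.0 and vals[2] == 1.0
    assert 0.0 < vals[1] < 0.5


def test_all_objectives_nonnegative_and_zero_at_coincidence():
    rng = np.random.default_rng(5)
    samples = rng.poisson(8, 2000)
    scheme = cf.build_bins(samples)
    pdf = cf.pdf_from_samples(samples, scheme)
    cdf = cf.cdf_from_pdf(pdf)
    assert cf.dfd_pdf(pdf, pdf) == 0.0
    assert cf.dfd_cdf(cdf, cdf) == 0.0
    assert cf.dfd_max(pdf, pdf, "pdf") == 0.0
    assert cf.dfd_max(cdf, cdf, "cdf") == 0.0
    other = cf.pdf_from_samples(rng.poisson(9, 2000), scheme)
    assert cf.dfd_pdf(pdf, other) > 0.0


class TestDatasetRoundTrip:
    def test_tsv_round_trip(self, tmp_path):
        ds = cf.generate_case_study("ecoli_rna", m=8, seed=3)
        path = tmp_path / "ds.tsv"
        ds.to_tsv(path)
        again = cf.Dataset.from_tsv(path)
        assert again.species == ds.species
        np.testing.assert_array_equal(again.observations["RNA"], ds.observations["RNA"])
        np.testing.assert_allclose(again.sample_times, ds.sample_times)
        assert again.provenance["true_values"] == ds.provenance["true_values"]


@pytest.mark.parametrize("method", ["ml", "dfd_pdf", "dfd_cdf", "dfd_pdf_max", "dfd_cdf_max"])
def test_truth_beats_scaled_parameters_in_expectation(birth_death, method):
    """For immigration-death data, the expected objective (20 seeds) at the
    true rates is smaller than at rates scaled by 2x or 0.5x, for every
    criterion: each distance actually discriminates parameters."""
    from cmefit.pipeline import make_objective

    truth = np.array([5.0, 1.0])
    ens = cf.simulate_ensemble(birth_death, truth, [0], 0.0, [2.0, 20.0], 2000, 777)
    ds = cf.Dataset(
        observations={"X": ens.observe("X")},
        sample_times=[2.0, 20.0],
        provenance={"model": "birth_death_test", "true_values": {"k": 5.0, "gamma": 1.0},
                    "initial_state": {}, "t0": 0.0},
    )
    spec = cf.ObjectiveSpec(method=method, n_ssa_realizations=400,
                            common_random_numbers=False)
    means = {}
    for scale in [1.0, 2.0, 0.5]:
        vals = []
        for seed in range(20):
            obj, _, _ = make_objective(ds, birth_death, spec, seed)
            vals.append(obj(truth * scale))
        means[scale] = np.mean(vals)
    assert means[1.0] < means[2.0]
    assert means[1.0] < means[0.5]
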