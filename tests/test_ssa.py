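"""Correctness of the direct-method SSA against analytic laws."""

import numpy as np
import pytest
from scipy import stats

import cmefit as cf
from cmefit.ssa import simulate_with_counts


def test_frozen_system_stays_at_x0(birth_death):
    # all propensities zero at the start (k=0 and no molecules to die)
    states = cf.simulate(birth_death, [0.0, 1.0], [0], 0.0, [1.0, 5.0, 10.0], 3)
    np.testing.assert_array_equal(states, 0)


def test_pure_birth_matches_poisson_moments(birth_death):
    """Counting process at rate k: X(t) ~ Poisson(k t)."""
    n = 10_000
    ens = cf.simulate_ensemble(birth_death, [1.0, 0.0], [0], 0.0, [10.0], n, 11)
    x = ens.observe("X")[:, 0]
    lam = 10.0
    se_mean = np.sqrt(lam / n)
    assert abs(x.mean() - lam) < 3 * se_mean
    # var of sample variance for Poisson ~ (mu4 - sigma^4)/n; mu4 = 3l^2 + l
    se_var = np.sqrt((3 * lam**2 + lam - lam**2) / n)
    assert abs(x.var(ddof=1) - lam) < 4 * se_var


def test_immigration_death_stationary_poisson(birth_death):
    """k=5, gamma=1 sampled far past relaxation: X ~ Poisson(5)."""
    n = 10_000
    ens = cf.simulate_ensemble(birth_death, [5.0, 1.0], [0], 0.0, [20.0], n, 12)
    x = ens.observe("X")[:, 0]
    kmax = int(x.max())
    observed = np.bincount(x, minlength=kmax + 1).astype(float)
    expected = stats.poisson.pmf(np.arange(kmax + 1), 5.0) * n
    # pool the sparse tail so every class has expected count >= 5
    cut = np.searchsorted(np.cumsum(expected[::-1]), 5.0)
    hi = kmax + 1 - cut
    obs = np.append(observed[:hi], observed[hi:].sum())
    exp = np.append(expected[:hi], expected[hi:].sum())
    exp *= obs.sum() / exp.sum()
    gof = stats.chisquare(obs, exp)
    assert gof.pvalue > 0.01


def test_birth_death_mean_trajectory_matches_ode(birth_death):
    """Linear chain: E[X](t) = (k/g)(1 - exp(-g t)) within 3 MC SEs."""
    k, g = 5.0, 1.0
    times = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
    n = 4000
    ens = cf.simulate_ensemble(birth_death, [k, g], [0], 0.0, times, n, 13)
    x = ens.observe("X")
    expected = (k / g) * (1 - np.exp(-g * times))
    se = x.std(axis=0, ddof=1) / np.sqrt(n)
    assert np.all(np.abs(x.mean(axis=0) - expected) < 3 * np.maximum(se, 1e-9))


def test_ensemble_reproducible_and_rows_match_substreams(birth_death):
    ens1 = cf.simulate_ensemble(birth_death, [5.0, 1.0], [0], 0.0, [1.0, 2.0], 5, 99)
    ens2 = cf.simulate_ensemble(birth_death, [5.0, 1.0], [0], 0.0, [1.0, 2.0], 5, 99)
    np.testing.assert_array_equal(ens1.states, ens2.states)
    # realization i is exactly a single simulate call on child stream i
    children = np.random.SeedSequence(99).spawn(5)
    for i, child in enumerate(children):
        row = cf.simulate(birth_death, [5.0, 1.0], [0], 0.0, [1.0, 2.0], child)
        np.testing.assert_array_equal(row, ens1.states[i])


def test_disjoint_streams_agree_within_mc_error(birth_death):
    n = 4000
    m1 = cf.simulate_ensemble(birth_death, [5.0, 1.0], [0], 0.0, [20.0], n, 1).observe("X").mean()
    m2 = cf.simulate_ensemble(birth_death, [5.0, 1.0], [0], 0.0, [20.0], n, 2).observe("X").mean()
    assert m1 != m2  # genuinely different streams
    assert abs(m1 - m2) < 4 * np.sqrt(2 * 5.0 / n)


def test_event_count_conservation(birth_death):
    states, firings = simulate_with_counts(
        birth_death, [5.0, 1.0], [0], 0.0, [30.0], 7
    )
    nu = birth_death.stoichiometry
    np.testing.assert_array_equal(states[-1], 0 + firings @ nu)


def test_python_engine_matches_kernel_distribution(birth_death):
    """The generic engine and the compiled kernel sample the same law."""
    times = np.array([20.0])
    a = cf.simulate_ensemble(birth_death, [5.0, 1.0], [0], 0.0, times, 3000, 21)
    # force the python path via an expression-propensity clone
    clone = cf.ReactionNetwork(
        species_names=["X"],
        reactions=[
            cf.Reaction("birth", {"X": 1}, cf.ExpressionPropensity("k")),
            cf.Reaction("death", {"X": -1}, cf.ExpressionPropensity("gamma * X")),
        ],
        parameter_names=["k", "gamma"],
        parameter_bounds=[(0, 10), (0, 10)],
    )
    assert not clone.kernel_compatible
    b = cf.simulate_ensemble(clone, [5.0, 1.0], [0], 0.0, times, 3000, 22)
    res = stats.ks_2samp(a.observe("X")[:, 0], b.observe("X")[:, 0])
    assert res.pvalue > 0.01


def test_event_count_scales_with_rate(birth_death):
    """Workload grows linearly with the event count (pure birth: ~ k t)."""
    totals = []
    for k in [1.0, 4.0]:
        _, firings = simulate_with_counts(birth_death, [k, 0.0], [0], 0.0, [100.0], 5)
        totals.append(firings.sum())
    assert 2.5 < totals[1] / totals[0] < 6.0


def test_ensemble_serialization_round_trip(tmp_path, birth_death):
    ens = cf.simulate_ensemble(birth_death, [5.0, 1.0], [0], 0.0, [1.0, 2.0], 10, 3)
    npz = tmp_path / "ens.npz"
    ens.to_npz(npz)
    again = cf.Ensemble.from_npz(npz)
    np.testing.assert_array_equal(again.states, ens.states)
    assert again.species_names == ens.species_names
    ens.to_csv(tmp_path / "ens.csv")
    import pandas as pd

    df = pd.read_csv(tmp_path / "ens.csv")
    assert set(df.columns) == {"realization", "time", "species", "count"}
    assert len(df) == 10 * 2 * 1


def test_sample_times_before_t0_rejected(birth_death):
    with pytest.raises(cf.NetworkError):
        cf.simulate(birth_death, [1.0, 1.0], [0], 5.0, [1.0], 0)


class TestMeasurementNoise:
    def _ens(self, value=10, n=10_000):
        states = np.full((n, 1, 1), value, dtype=np.int64)
        return cf.Ensemble(sample_times=[1.0], states=states, species_names=["X"])

    def test_zero_variance_is_identity(self):
        ens = self._ens()
        out = cf.add_measurement_noise(ens, cf.NoiseModel(0.0), 0)
        np.testing.assert_array_equal(out.states, ens.states)
        assert out.noisy

    def test_rounded_gaussian_preserves_mean_and_integrality(self):
        ens = self._ens(value=10)
        out = cf.add_measurement_noise(ens, cf.NoiseModel(0.25), 5)
        obs = out.states[:, 0, 0]
        assert obs.dtype.kind == "i"
        assert abs(obs.mean() - 10) < 3 * 0.5 / np.sqrt(obs.size)

    def test_negative_observations_possible_at_zero(self):
        ens = self._ens(value=0)
        out = cf.add_measurement_noise(ens, cf.NoiseModel(0.25), 6)
        assert out.states.min() <= -1  # not clipped

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            cf.NoiseModel(-1.0)

    def test_double_noise_rejected(self):
        ens = cf.add_measurement_noise(self._ens(), cf.NoiseModel(0.1), 0)
        with pytest.raises(ValueError):
            cf.add_measurement_noise(ens, cf.NoiseModel(0.1), 0)
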