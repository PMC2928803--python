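"""Exact stochastic simulation (Gillespie direct method) of reaction networks.

Two engines share one sampling convention (the state recorded at a sample
time is the state holding over the inter-event interval containing it):

* a numba kernel for networks whose propensities are mass-action or Hill
  (all built-in models), used for ensemble-scale work;
* a plain-Python engine that additionally handles expression propensities
  and can record per-reaction firing counts.  It also serves as an
  independent implementation to cross-check the kernel in the test suite.

Randomness is always explicit: every entry point takes a seed or
:class:`numpy.random.SeedSequence`, and ensembles draw one independent
child stream per realization, so results are reproducible bit-for-bit
and realizations are statistically independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernel
from .networks import NetworkError, PropensityEvaluationError, ReactionNetwork

SeedLike = "int | np.random.SeedSequence"


def as_seedseq(rng) -> np.random.SeedSequence:
    if isinstance(rng, np.random.SeedSequence):
        return rng
    if isinstance(rng, (int, np.integer)):
        return np.random.SeedSequence(int(rng))
    raise TypeError(f"expected an int seed or SeedSequence, got {type(rng)!r}")


@dataclass(frozen=True)
class NoiseModel:
    """Zero-mean i.i.d. Gaussian measurement noise on molecule counts."""

    variance: float

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("noise variance must be >= 0")


@dataclass
class Ensemble:
    """n_realizations x n_times x n_species integer state samples."""

    sample_times: np.ndarray
    states: np.ndarray
    species_names: list[str]
    noisy: bool = False
    seed_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.states = np.asarray(self.states)
        if self.states.ndim != 3 or self.states.shape[2] != len(self.species_names):
            raise ValueError("states must be (n_realizations, n_times, n_species)")
        if np.any(np.diff(self.sample_times) < 0):
            raise ValueError("sample_times must be non-decreasing")

    @property
    def n_realizations(self) -> int:
        return self.states.shape[0]

    def observe(self, species: str) -> np.ndarray:
        """(n_realizations, n_times) counts of one species."""
        return self.states[:, :, self.species_names.index(species)]

    def to_npz(self, path: str | Path) -> None:
        """Compact binary container (numpy .npz)."""
        np.savez_compressed(
            path,
            sample_times=self.sample_times,
            states=self.states,
            species_names=np.array(self.species_names),
            noisy=np.array(self.noisy),
        )

    @classmethod
    def from_npz(cls, path: str | Path) -> "Ensemble":
        with np.load(path) as data:
            return cls(
                sample_times=data["sample_times"],
                states=data["states"],
                species_names=[str(s) for s in data["species_names"]],
                noisy=bool(data["noisy"]),
            )

    def to_csv(self, path: str | Path) -> None:
        """Long format: realization, time, species, count."""
        r, n, _ = self.states.shape
        frames = []
        for s_i, name in enumerate(self.species_names):
            frames.append(
                pd.DataFrame(
                    {
                        "realization": np.repeat(np.arange(r), n),
                        "time": np.tile(self.sample_times, r),
                        "species": name,
                        "count": self.states[:, :, s_i].ravel(),
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _check_inputs(network, x0, t0, sample_times):
    x0 = np.asarray(x0, dtype=np.int64)
    if x0.shape != (network.n_species,):
        raise NetworkError(f"x0 has shape {x0.shape}, expected ({network.n_species},)")
    if np.any(x0 < 0):
        raise NetworkError("x0 must be non-negative")
    sample_times = np.asarray(sample_times, dtype=float)
    if sample_times.ndim != 1 or sample_times.size == 0:
        raise NetworkError("sample_times must be a non-empty 1-D vector")
    if np.any(sample_times < t0):
        raise NetworkError("all sample_times must be >= t0")
    if np.any(np.diff(sample_times) < 0):
        raise NetworkError("sample_times must be non-decreasing")
    return x0, sample_times


def _child_seeds(ss: np.random.SeedSequence, n: int) -> tuple[list, np.ndarray]:
    children = ss.spawn(n)
    seeds = np.array([c.generate_state(1, dtype=np.uint32)[0] for c in children],
                     dtype=np.int64)
    return children, seeds


def simulate(
    network: ReactionNetwork,
    params,
    x0,
    t0: float,
    sample_times,
    rng,
) -> np.ndarray:
    """One SSA realization, sampled at fixed observation times.

    Returns an ``(n_times, n_species)`` integer array.  Waiting times are
    exponential with rate ``a0 = sum_j a_j``; the firing reaction is
    chosen with probability ``a_j / a0``.  Once ``a0`` reaches zero the
    state is frozen for all remaining sample times.
    """
    x0, sample_times = _check_inputs(network, x0, t0, sample_times)
    ss = as_seedseq(rng)
    if network.kernel_compatible:
        kinds, coefs, sp = network.kernel_tables(params)
        out = np.empty((1, sample_times.size, network.n_species), dtype=np.int64)
        seed = np.array([ss.generate_state(1, dtype=np.uint32)[0]], dtype=np.int64)
        _kernel.run_ensemble(
            network.stoichiometry, kinds, coefs, sp, x0, float(t0), sample_times,
            seed, out,
        )
        return out[0]
    states, _ = _simulate_python(network, params, x0, t0, sample_times,
                                 np.random.default_rng(ss))
    return states


def simulate_with_counts(
    network: ReactionNetwork, params, x0, t0, sample_times, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Python-engine realization that also returns per-reaction firing counts."""
    x0, sample_times = _check_inputs(network, x0, t0, sample_times)
    gen = np.random.default_rng(as_seedseq(rng))
    return _simulate_python(network, params, x0, t0, sample_times, gen)


def _simulate_python(network, params, x0, t0, sample_times, gen):
    params = network.params_array(params)
    nu = network.stoichiometry
    n_times = sample_times.size
    out = np.empty((n_times, network.n_species), dtype=np.int64)
    firings = np.zeros(network.n_reactions, dtype=np.int64)
    x = x0.astype(np.int64).copy()
    t = float(t0)
    i_t = 0
    while i_t < n_times:
        try:
            a = network.evaluate_propensities(x, params)
        except PropensityEvaluationError as exc:
            raise PropensityEvaluationError(f"{exc} (t={t:.6g})") from exc
        a0 = a.sum()
        if a0 <= 0.0:
            out[i_t:] = x
            break
        t_next = t + gen.exponential(1.0 / a0)
        while i_t < n_times and sample_times[i_t] < t_next:
            out[i_t] = x
            i_t += 1
        if i_t >= n_times:
            break
        j = np.searchsorted(np.cumsum(a), gen.random() * a0, side="right")
        j = min(j, network.n_reactions - 1)
        x = x + nu[j]
        firings[j] += 1
        t = t_next
    return out, firings


def simulate_ensemble(
    network: ReactionNetwork,
    params,
    x0,
    t0: float,
    sample_times,
    n_realizations: int,
    rng,
) -> Ensemble:
    """Independent SSA realizations on partitioned RNG sub-streams.

    Realization ``i`` uses the ``i``-th spawned child of the supplied
    seed sequence, so ``simulate`` on that child reproduces row ``i``
    exactly, and the same seed always yields a bit-identical ensemble.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    x0, sample_times = _check_inputs(network, x0, t0, sample_times)
    ss = as_seedseq(rng)
    children, seeds = _child_seeds(ss, n_realizations)
    if network.kernel_compatible:
        kinds, coefs, sp = network.kernel_tables(params)
        out = np.empty((n_realizations, sample_times.size, network.n_species),
                       dtype=np.int64)
        _kernel.run_ensemble(
            network.stoichiometry, kinds, coefs, sp, x0, float(t0), sample_times,
            seeds, out,
        )
    else:
        out = np.stack(
            [
                _simulate_python(network, params, x0, t0, sample_times,
                                 np.random.default_rng(c))[0]
                for c in children
            ]
        )
    return Ensemble(
        sample_times=sample_times,
        states=out,
        species_names=list(network.species_names),
        noisy=False,
        seed_info={"entropy": ss.entropy, "n_children": n_realizations},
    )


def add_measurement_noise(
    ensemble: Ensemble,
    noise: NoiseModel,
    rng,
    species: Sequence[str] | None = None,
) -> Ensemble:
    """Apply ``o = round(x + eps)``, ``eps ~ N(0, sigma^2)`` i.i.d.

    Noise models fluorescence-normalization error of the measured
    reporter(s); *species* restricts it to those observables (default:
    every species in the ensemble).  Values are deliberately not clipped,
    so small negative observed counts can occur and are preserved.
    """
    if ensemble.noisy:
        raise ValueError("ensemble already carries measurement noise")
    out = ensemble.states.copy()
    if noise.variance > 0:
        gen = np.random.default_rng(as_seedseq(rng))
        idx = (
            range(len(ensemble.species_names))
            if species is None
            else [ensemble.species_names.index(s) for s in species]
        )
        sd = float(np.sqrt(noise.variance))
        for s_i in idx:
            eps = gen.normal(0.0, sd, size=out[:, :, s_i].shape)
            out[:, :, s_i] = np.rint(out[:, :, s_i] + eps).astype(np.int64)
    return replace(ensemble, states=out, noisy=True)


def noisy_observations(counts: np.ndarray, variance: float, rng) -> np.ndarray:
    """Vector/matrix form of the rounding noise model, for objective hot paths."""
    if variance < 0:
        raise ValueError("noise variance must be >= 0")
    if variance == 0:
        return counts
    gen = np.random.default_rng(as_seedseq(rng))
    return np.rint(counts + gen.normal(0.0, np.sqrt(variance), size=counts.shape)).astype(
        np.int64
    )
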