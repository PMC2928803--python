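"""End-to-end estimation: data -> binning -> objective -> DE -> report.

The objective closure built here is the bridge between a measured
:class:`~cmefit.objectives.Dataset` and a candidate parameter vector:
simulate an SSA ensemble, overlay the dataset's measurement-noise model,
bin under the method's reference rule, and evaluate the chosen
criterion, summed over observed species.

By default the SSA sub-streams and noise draws are frozen across the
whole optimization (common random numbers), so objective differences
between candidates reflect the parameters rather than Monte Carlo
resampling; ``ObjectiveSpec(common_random_numbers=False)`` re-draws per
evaluation instead.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from . import _kernel
from .case_studies import recovery_score
from .de import DEConfig, DEResult, de_minimize
from .density import (
    BinnedDensity,
    SparseECDF,
    build_bins,
    cdf_from_pdf,
    pdf_from_samples,
    sparse_ecdf,
)
from .networks import ReactionNetwork
from .objectives import (
    Dataset,
    ObjectiveSpec,
    dfd_cdf,
    dfd_max,
    dfd_pdf,
    neg_log_likelihood,
)
from .ssa import as_seedseq, simulate_ensemble


class ConfigError(ValueError):
    """Estimation settings incompatible with the dataset or network."""


# --------------------------------------------------------------------------
# objective construction
# --------------------------------------------------------------------------

def _dataset_x0_t0(dataset: Dataset, network: ReactionNetwork):
    x0 = np.zeros(network.n_species, dtype=np.int64)
    for sp, c in dataset.provenance.get("initial_state", {}).items():
        x0[network.species_index(sp)] = int(c)
    return x0, float(dataset.provenance.get("t0", 0.0))


def _check_applicability(dataset: Dataset, spec: ObjectiveSpec) -> bool:
    """Returns True when the CDF criterion must run in sparse mode."""
    sparse = dataset.m < spec.population_threshold
    if sparse and spec.method in ("dfd_pdf", "dfd_pdf_max", "dfd_cdf_max") and not (
        spec.allow_sparse_pdf
    ):
        raise ConfigError(
            f"{spec.method} needs at least {spec.population_threshold} replicates for a "
            f"reliable data histogram (got m={dataset.m}); set allow_sparse_pdf to override"
        )
    return sparse and spec.method == "dfd_cdf"


class _EnsembleSampler:
    """Reusable SSA sampler with frozen (CRN) or fresh sub-streams."""

    def __init__(self, network, x0, t0, sample_times, n_real, ss, crn: bool):
        self.network = network
        self.x0 = x0
        self.t0 = float(t0)
        self.sample_times = np.asarray(sample_times, dtype=float)
        self.n_real = n_real
        self.crn = crn
        self._ss = ss
        self._fast = network.kernel_compatible
        if self._fast:
            self._stoich = network.stoichiometry
            self._out = np.empty(
                (n_real, self.sample_times.size, network.n_species), dtype=np.int64
            )
        if crn:
            self._seeds = self._draw_seeds()

    def _draw_seeds(self):
        children = self._ss.spawn(self.n_real)
        return np.array(
            [c.generate_state(1, dtype=np.uint32)[0] for c in children], dtype=np.int64
        )

    def sample(self, params) -> np.ndarray:
        """(n_real, n_times, n_species) states at one candidate vector."""
        if not self._fast:
            if self.crn:
                # fresh copy with the original spawn counter, so the same
                # child streams are re-drawn on every call
                ss = np.random.SeedSequence(
                    entropy=self._ss.entropy, spawn_key=self._ss.spawn_key
                )
            else:
                ss = self._ss.spawn(1)[0]
            ens = simulate_ensemble(
                self.network, params, self.x0, self.t0, self.sample_times,
                self.n_real, ss,
            )
            return ens.states
        seeds = self._seeds if self.crn else self._draw_seeds()
        kinds, coefs, sp = self.network.kernel_tables(params)
        _kernel.run_ensemble(
            self._stoich, kinds, coefs, sp, self.x0, self.t0, self.sample_times,
            seeds, self._out,
        )
        return self._out


def make_objective(
    dataset: Dataset,
    network: ReactionNetwork,
    spec: ObjectiveSpec,
    rng,
    free_params: Sequence[str] | None = None,
    fixed: Mapping[str, float] | None = None,
) -> tuple[Callable[[np.ndarray], float], list[str], np.ndarray]:
    """Build the objective over a (possibly restricted) parameter vector.

    Returns ``(objective, free_names, bounds)``.  Parameters not in
    *free_params* are held at the values in *fixed* (defaulting to the
    dataset's recorded truth, when present).
    """
    unknown = set(dataset.species) - set(network.species_names)
    if unknown:
        raise ConfigError(f"dataset observes species unknown to the network: {unknown}")
    sparse = _check_applicability(dataset, spec)
    noise_var = (
        dataset.noise_variance if spec.noise_variance is None else spec.noise_variance
    )

    # data-side densities, built once
    data_side: dict[str, list] = {}
    for sp_name in dataset.species:
        obs = dataset.observations[sp_name]
        per_tp = []
        for i in range(dataset.n_times):
            col = obs[:, i]
            if spec.method == "ml":
                per_tp.append(None)  # likelihood needs no data-side density
            elif sparse:
                per_tp.append(sparse_ecdf(col))
            else:
                scheme = build_bins(col, spec.min_count, reference="experimental")
                pdf = pdf_from_samples(col, scheme)
                per_tp.append(
                    cdf_from_pdf(pdf) if spec.method in ("dfd_cdf", "dfd_cdf_max") else pdf
                )
        data_side[sp_name] = per_tp

    # free/fixed split
    names = network.parameter_names
    free = list(names) if free_params is None else list(free_params)
    bad = set(free) - set(names)
    if bad:
        raise ConfigError(f"unknown free parameters {bad}")
    template = np.full(len(names), np.nan)
    fixed = dict(fixed or {})
    truth = dataset.provenance.get("true_values", {})
    for i, nm in enumerate(names):
        if nm in free:
            continue
        if nm in fixed:
            template[i] = float(fixed[nm])
        elif nm in truth:
            template[i] = float(truth[nm])
        else:
            raise ConfigError(f"no fixed value available for non-free parameter {nm!r}")
    free_idx = np.array([names.index(nm) for nm in free], dtype=int)
    bounds = network.bounds_array[free_idx]

    x0, t0 = _dataset_x0_t0(dataset, network)
    ss = as_seedseq(rng)
    sim_ss, noise_ss = ss.spawn(2)
    sampler = _EnsembleSampler(
        network, x0, t0, dataset.sample_times, spec.n_ssa_realizations, sim_ss,
        spec.common_random_numbers,
    )
    sp_idx = {s: network.species_index(s) for s in dataset.species}

    # frozen noise draws (CRN); redrawn per call otherwise
    def draw_noise(gen):
        if noise_var <= 0:
            return None
        sd = float(np.sqrt(noise_var))
        return {
            s: gen.normal(0.0, sd, size=(spec.n_ssa_realizations, dataset.n_times))
            for s in dataset.species
        }

    frozen_noise = draw_noise(np.random.default_rng(noise_ss)) if (
        spec.common_random_numbers
    ) else None
    noise_counter = [0]

    def objective(x: np.ndarray) -> float:
        full = template.copy()
        full[free_idx] = np.asarray(x, dtype=float)
        states = sampler.sample(full)
        if spec.common_random_numbers:
            noise = frozen_noise
        else:
            noise_counter[0] += 1
            noise = draw_noise(
                np.random.default_rng(noise_ss.spawn(noise_counter[0])[-1])
            )
        total = 0.0
        for s_name in dataset.species:
            sim = states[:, :, sp_idx[s_name]]
            if noise is not None:
                sim = np.rint(sim + noise[s_name]).astype(np.int64)
            total += _species_objective(
                spec, sparse, dataset.observations[s_name], data_side[s_name], sim
            )
        return total

    return objective, free, bounds


def _species_objective(spec, sparse, obs, data_tp, sim) -> float:
    n_times = obs.shape[1]
    if spec.method == "ml":
        pdfs = [
            pdf_from_samples(
                sim[:, i], build_bins(sim[:, i], spec.min_count, reference="simulation")
            )
            for i in range(n_times)
        ]
        return neg_log_likelihood(obs, pdfs)
    if sparse:  # dfd_cdf sparse mode: model binned on SSA realizations
        model = [
            cdf_from_pdf(
                pdf_from_samples(
                    sim[:, i],
                    build_bins(sim[:, i], spec.min_count, reference="simulation"),
                )
            )
            for i in range(n_times)
        ]
        return dfd_cdf(data_tp, model)
    # dense modes share the data-referenced binning
    model = [pdf_from_samples(sim[:, i], data_tp[i].scheme) for i in range(n_times)]
    if spec.method == "dfd_pdf":
        return dfd_pdf(data_tp, model)
    if spec.method == "dfd_pdf_max":
        return dfd_max(data_tp, model, "pdf")
    model = [cdf_from_pdf(p) for p in model]
    if spec.method == "dfd_cdf":
        return dfd_cdf(data_tp, model)
    return dfd_max(data_tp, model, "cdf")


# --------------------------------------------------------------------------
# estimation runs
# --------------------------------------------------------------------------

@dataclass
class EstimationRun:
    """Everything needed to report and replay one estimation."""

    spec: ObjectiveSpec
    de_config: DEConfig
    free_params: list[str]
    estimates: dict[str, float]
    result: DEResult
    recovery: dict | None
    dataset_provenance: dict = field(default_factory=dict)

    def config_dict(self) -> dict:
        d = asdict(self.spec)
        seed = self.de_config.seed
        if isinstance(seed, np.random.SeedSequence):
            seed = seed.entropy
        cfg = {
            "objective": d,
            "de": {
                "population_size": self.de_config.population_size,
                "generations": self.de_config.generations,
                "f": self.de_config.f,
                "cr": self.de_config.cr,
                "seed": seed,
                "spread_tol": self.de_config.spread_tol,
            },
            "free_params": self.free_params,
        }
        return cfg

    def to_json(self, path) -> None:
        out = {
            "config": self.config_dict(),
            "estimates": self.estimates,
            "best_value": self.result.best_value,
            "n_evaluations": self.result.n_evaluations,
            "recovery": self.recovery,
            "dataset_provenance": {
                k: v for k, v in self.dataset_provenance.items() if k != "true_values"
            },
        }
        with open(path, "w") as fh:
            json.dump(out, fh, indent=2, default=float)


def estimate(
    dataset: Dataset,
    network: ReactionNetwork,
    spec: ObjectiveSpec,
    de_config: DEConfig,
    free_params: Sequence[str] | None = None,
    fixed: Mapping[str, float] | None = None,
) -> EstimationRun:
    """Fit network parameters to a dataset with the chosen criterion.

    ``de_config.seed`` drives every random element (DE initialisation
    and the frozen SSA/noise streams inside the objective), so a run is
    fully reproducible from its configuration.  ``de_config.bounds`` may
    be left empty — the network's parameter bounds are used.
    """
    ss = as_seedseq(de_config.seed)
    de_ss, obj_ss = ss.spawn(2)
    objective, free, bounds = make_objective(
        dataset, network, spec, obj_ss, free_params=free_params, fixed=fixed
    )
    cfg = replace(de_config, bounds=[tuple(b) for b in bounds], seed=de_ss)
    result = de_minimize(objective, cfg)
    estimates = dict(zip(free, result.best_params))
    truth = dataset.provenance.get("true_values", {})
    recovery = None
    if all(nm in truth for nm in free):
        recovery = recovery_score(
            result.best_params, [truth[nm] for nm in free], parameter_names=free
        )
    return EstimationRun(
        spec=spec,
        de_config=de_config,
        free_params=free,
        estimates=estimates,
        result=result,
        recovery=recovery,
        dataset_provenance=dict(dataset.provenance),
    )


# --------------------------------------------------------------------------
# objective-landscape scans
# --------------------------------------------------------------------------

def scan_objective(
    network: ReactionNetwork,
    dataset: Dataset,
    spec: ObjectiveSpec,
    grid: Mapping[str, Sequence[float]],
    fixed: Mapping[str, float] | None = None,
    rng=0,
) -> tuple[list[str], list[np.ndarray], np.ndarray]:
    """Objective values on a 1-D or 2-D parameter grid, min-normalized.

    Every grid node is evaluated with the same frozen random streams, so
    surface roughness reflects finite-sampling noise across parameter
    space, not resampling between nodes.  Values are divided by the grid
    minimum (the minimum maps to 1); an all-zero minimum normalizes
    zeros to 1.

    Returns ``(axis_names, axis_values, surface)`` with ``surface``
    shaped like the grid.
    """
    if not grid:
        raise ValueError("empty scan grid")
    if len(grid) > 2:
        raise ValueError("at most two scan dimensions supported")
    axis_names = list(grid)
    axis_values = [np.asarray(v, dtype=float) for v in grid.values()]
    if any(v.size == 0 for v in axis_values):
        raise ValueError("empty scan grid axis")
    objective, free, _ = make_objective(
        dataset, network, spec, rng, free_params=axis_names, fixed=fixed
    )
    shape = tuple(v.size for v in axis_values)
    surface = np.empty(shape)
    for flat_idx in np.ndindex(*shape):
        x = np.array([axis_values[d][flat_idx[d]] for d in range(len(shape))])
        surface[flat_idx] = objective(x)
    vmin = surface.min()
    if vmin > 0:
        surface = surface / vmin
    else:
        surface = np.where(surface == vmin, 1.0, np.inf)
    return axis_names, axis_values, surface


def scan_roughness(surface: np.ndarray) -> float:
    """Mean absolute difference between adjacent grid nodes."""
    diffs = []
    for axis in range(surface.ndim):
        d = np.abs(np.diff(surface, axis=axis))
        diffs.append(d.ravel())
    return float(np.concatenate(diffs).mean())


def detrended_roughness(axis_values: Sequence[np.ndarray], surface: np.ndarray) -> float:
    """Finite-sampling roughness of a 2-D scan, separated from its trend.

    A least-squares quadratic in the two scan parameters captures the
    smooth local shape of the objective; the RMS residual around it,
    relative to the spread of the fitted trend itself, is a
    noise-to-signal ratio: how much Monte Carlo jitter obscures the
    parameter dependence.  It shrinks as the SSA realization count
    grows.  Meaningful when nodes are simulated with independent
    streams (``ObjectiveSpec(common_random_numbers=False)``); frozen
    streams make the surface smooth in the parameters by construction.
    """
    if surface.ndim != 2:
        raise ValueError("detrended_roughness expects a 2-D scan")
    a, b = np.meshgrid(axis_values[0], axis_values[1], indexing="ij")
    design = np.column_stack(
        [
            np.ones(a.size), a.ravel(), b.ravel(),
            a.ravel() ** 2, b.ravel() ** 2, (a * b).ravel(),
        ]
    )
    y = surface.ravel()
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    trend = design @ beta
    resid = y - trend
    return float(np.sqrt(np.mean(resid**2)) / np.std(trend))
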