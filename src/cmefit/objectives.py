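"""Estimation criteria: maximum likelihood and density-function distances.

All criteria compare measured replicate counts with the distribution a
stochastic model predicts (reconstructed from a finite SSA ensemble):

* ``ml`` — negative log-likelihood of the observations under the
  model-side histogram PDF;
* ``dfd_pdf`` — binomial-variance-weighted squared distance between the
  data and model histogram PDFs;
* ``dfd_cdf`` — the same on cumulative distributions; for sparse data
  the data side is the order-statistic ECDF and the model CDF is
  evaluated at the observed values;
* ``dfd_pdf_max`` / ``dfd_cdf_max`` — per-timepoint maximum standardized
  deviation instead of the quadratic sum.

For the quadratic criteria the last bin of every timepoint is excluded:
normalization makes it linearly dependent on the others, so it carries
no extra information.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .density import BinnedDensity, SparseECDF, lookup_probs

METHODS = ("ml", "dfd_pdf", "dfd_cdf", "dfd_pdf_max", "dfd_cdf_max")

DATASET_FORMAT_VERSION = 1


@dataclass
class Dataset:
    """Replicate-by-timepoint integer observations of reporter species.

    ``observations`` maps each observed species to an ``(m, n)`` integer
    matrix (m replicates, n timepoints).  ``provenance`` records how the
    data were produced (model name, true parameters for synthetic data,
    noise variance, initial state, seed) and travels with the dataset
    through serialization.
    """

    observations: dict[str, np.ndarray]
    sample_times: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        if not self.observations:
            raise ValueError("dataset needs at least one observed species")
        if np.any(np.diff(self.sample_times) <= 0) and self.sample_times.size > 1:
            raise ValueError("sample_times must be strictly increasing")
        shapes = set()
        for k, v in self.observations.items():
            v = np.asarray(v)
            if v.ndim != 2 or v.shape[1] != self.sample_times.size:
                raise ValueError(f"observations[{k!r}] must be (m, n_times)")
            self.observations[k] = v
            shapes.add(v.shape)
        if len(shapes) != 1:
            raise ValueError("all observed species must share the replicate count")

    @property
    def m(self) -> int:
        return next(iter(self.observations.values())).shape[0]

    @property
    def n_times(self) -> int:
        return self.sample_times.size

    @property
    def species(self) -> list[str]:
        return list(self.observations)

    @property
    def noise_variance(self) -> float:
        return float(self.provenance.get("noise_variance", 0.0))

    # -- serialization: wide TSV per species + JSON sidecar -----------------

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        frames = []
        for sp, obs in self.observations.items():
            df = pd.DataFrame(obs, columns=[f"t={t:g}" for t in self.sample_times])
            df.insert(0, "replicate", np.arange(obs.shape[0]))
            df.insert(0, "species", sp)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
        sidecar = {
            "format_version": DATASET_FORMAT_VERSION,
            "sample_times": self.sample_times.tolist(),
            "species": self.species,
            "provenance": self.provenance,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Dataset":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        if sidecar.get("format_version") != DATASET_FORMAT_VERSION:
            raise ValueError("unsupported dataset format version")
        df = pd.read_csv(path, sep="\t")
        times = np.asarray(sidecar["sample_times"], dtype=float)
        cols = [f"t={t:g}" for t in times]
        obs = {
            sp: sub.sort_values("replicate")[cols].to_numpy(dtype=np.int64)
            for sp, sub in df.groupby("species")
        }
        return cls(observations={sp: obs[sp] for sp in sidecar["species"]},
                   sample_times=times, provenance=sidecar.get("provenance", {}))


@dataclass(frozen=True)
class ObjectiveSpec:
    """Which criterion to evaluate and under what simulation settings."""

    method: Literal["ml", "dfd_pdf", "dfd_cdf", "dfd_pdf_max", "dfd_cdf_max"]
    n_ssa_realizations: int = 10_000
    min_count: int = 10
    noise_variance: float | None = None  # None: inherit from the dataset
    population_threshold: int = 1000
    allow_sparse_pdf: bool = False
    common_random_numbers: bool = True

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.n_ssa_realizations < 1:
            raise ValueError("n_ssa_realizations must be >= 1")


# --------------------------------------------------------------------------
# criterion primitives (per observed species; time sums inside)
# --------------------------------------------------------------------------

def _as_list(d):
    return [d] if isinstance(d, (BinnedDensity, SparseECDF)) else list(d)


def _check_shared_scheme(a: BinnedDensity, b: BinnedDensity) -> None:
    if a.scheme.n_bins != b.scheme.n_bins or not np.array_equal(a.scheme.edges, b.scheme.edges):
        raise ValueError("data and model densities must share one binning scheme")


def _effective_variance(diff: np.ndarray, var: np.ndarray, n: int) -> np.ndarray:
    """Zero-variance bins: no contribution if the densities agree there,
    otherwise fall back to the floor 1/(4N^2) to keep the ratio finite."""
    floor = 1.0 / (4.0 * n * n)
    var = np.where(var > 0, var, np.where(diff != 0.0, floor, np.inf))
    return var


def neg_log_likelihood(observations: np.ndarray, model_pdfs) -> float:
    """``sum_ij -log P(o_ij, t_i)`` with the zero-probability floor.

    *observations* is the ``(m, n)`` replicate matrix of one species and
    *model_pdfs* one histogram PDF per timepoint, built from SSA
    realizations (with the dataset's measurement noise applied).
    """
    model_pdfs = _as_list(model_pdfs)
    obs = np.atleast_2d(np.asarray(observations))
    if obs.shape[1] != len(model_pdfs):
        raise ValueError("one model pdf per timepoint required")
    total = 0.0
    for i, pdf in enumerate(model_pdfs):
        total -= np.log(lookup_probs(pdf, obs[:, i])).sum()
    return float(total)


def dfd_pdf(data_pdfs, model_pdfs) -> float:
    """Weighted squared PDF distance, last bin excluded per timepoint."""
    data_pdfs, model_pdfs = _as_list(data_pdfs), _as_list(model_pdfs)
    total = 0.0
    for d, m in zip(data_pdfs, model_pdfs, strict=True):
        _check_shared_scheme(d, m)
        diff = (d.probs - m.probs)[:-1]
        var = _effective_variance(diff, np.asarray(d.variances)[:-1], d.n_samples)
        total += float(np.sum(diff * diff / var))
    return total


def dfd_cdf(data, model_cdfs) -> float:
    """Weighted squared CDF distance (dense histograms or sparse ECDF).

    Dense mode: both sides share the data-referenced bins and the last
    bin (identically 1) is dropped.  Sparse mode: the data side is an
    order-statistic ECDF; the model CDF — binned on the SSA realizations
    — is linearly interpolated at the sorted observed values and every
    order statistic contributes, weighted by ``F_e(1-F_e)/m``.
    """
    data, model_cdfs = _as_list(data), _as_list(model_cdfs)
    total = 0.0
    for d, m in zip(data, model_cdfs, strict=True):
        if isinstance(d, SparseECDF):
            f_model = interp_cdf(m, d.values)
            diff = d.positions - f_model
            var = _effective_variance(diff, d.positions * (1.0 - d.positions) / d.m, d.m)
            total += float(np.sum(diff * diff / var))
        else:
            if d.kind != "cdf" or m.kind != "cdf":
                raise ValueError("dense dfd_cdf expects cdf densities")
            _check_shared_scheme(d, m)
            diff = (d.probs - m.probs)[:-1]
            var = _effective_variance(diff, np.asarray(d.variances)[:-1], d.n_samples)
            total += float(np.sum(diff * diff / var))
    return total


def dfd_max(data_densities, model_densities, kind: Literal["pdf", "cdf"]) -> float:
    """Sum over timepoints of the maximum standardized bin deviation.

    The denominator is the binomial standard deviation (not variance);
    the last bin is excluded as in the quadratic criteria.
    """
    data_densities, model_densities = _as_list(data_densities), _as_list(model_densities)
    total = 0.0
    for d, m in zip(data_densities, model_densities, strict=True):
        if d.kind != kind or m.kind != kind:
            raise ValueError(f"expected {kind} densities")
        _check_shared_scheme(d, m)
        diff = (d.probs - m.probs)[:-1]
        var = _effective_variance(diff, np.asarray(d.variances)[:-1], d.n_samples)
        with np.errstate(divide="ignore"):
            ratio = np.abs(diff) / np.sqrt(var)
        total += float(ratio.max()) if ratio.size else 0.0
    return total


def interp_cdf(model_cdf: BinnedDensity, values: np.ndarray) -> np.ndarray:
    """Model CDF linearly interpolated at arbitrary observed values.

    Anchored at (lower support edge, 0) and saturating at 1 above the
    last bin centre, so observations below/above the simulated support
    read 0/1.
    """
    if model_cdf.kind != "cdf":
        raise ValueError("expected a cdf density")
    xp = np.concatenate(([model_cdf.scheme.edges[0]], model_cdf.scheme.centers))
    fp = np.concatenate(([0.0], model_cdf.probs))
    return np.interp(np.asarray(values, dtype=float), xp, fp, left=0.0, right=1.0)


def log_evaluation(path, *, method: str, params, value: float, seed, n_ssa: int) -> None:
    """Append one JSON line describing an objective evaluation."""
    rec = {
        "method": method,
        "params": np.asarray(params, dtype=float).tolist(),
        "value": value,
        "seed": seed,
        "n_ssa": n_ssa,
    }
    with open(path, "a") as fh:
        fh.write(json.dumps(rec) + "\n")
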