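"""Histogram densities with finite-sampling weights.

Model and data distributions are compared through histograms whose bins
adapt to the sample: starting from unit-width integer bins, undersized
bins are merged until each holds at least ``min_count`` samples (default
10), balancing binning bias against small-count noise.  The sampling
noise of each bin probability is quantified by the binomial variance
``p(1-p)/N`` (and ``F(1-F)/N`` for cumulative probabilities), which the
distance objectives use as inverse weights.  For sparse data (few
replicates) the empirical CDF is instead represented by the plotting
positions ``(l - 0.5)/m`` of the order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinningScheme",
    "BinnedDensity",
    "SparseECDF",
    "build_bins",
    "pdf_from_samples",
    "cdf_from_pdf",
    "binomial_variance",
    "sparse_ecdf",
    "likelihood_lookup",
]


def binomial_variance(p, n: int):
    """Finite-sampling variance of a bin (or cumulative) frequency: p(1-p)/N."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if n < 1:
        raise ValueError("sample size must be >= 1")
    out = p * (1.0 - p) / n
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BinningScheme:
    """Bin edges over the observed-count axis for one timepoint.

    Intervals are half-open ``[e_l, e_{l+1})`` with the last bin closed.
    ``reference`` records whether the experimental data or the SSA
    simulation defined the edges (the estimation criteria differ in
    which side anchors the binning).
    """

    edges: np.ndarray
    reference: Literal["experimental", "simulation"] = "experimental"
    min_count: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", np.asarray(self.edges, dtype=float))
        if self.edges.size < 2 or np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing with >= 2 entries")

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def assign(self, samples) -> np.ndarray:
        """Bin index per sample; out-of-range samples go to the edge bins."""
        idx = np.searchsorted(self.edges, np.asarray(samples, dtype=float), side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)

    def counts(self, samples) -> np.ndarray:
        return np.bincount(self.assign(samples), minlength=self.n_bins)


def build_bins(samples, min_count: int = 10,
               reference: Literal["experimental", "simulation"] = "experimental"
               ) -> BinningScheme:
    """Adaptive integer binning: merge until every bin holds >= min_count.

    Starts from unit-width bins spanning ``[min, max]`` of the sample and
    sweeps left to right, merging each undersized bin into its
    smaller-count neighbour (ties merge rightward) until all bins satisfy
    the occupancy rule or a single bin remains.  The result depends only
    on the multiset of values, not their order.
    """
    samples = np.asarray(samples)
    if samples.size == 0:
        raise ValueError("cannot bin an empty sample")
    lo = int(np.floor(samples.min()))
    hi = int(np.floor(samples.max()))
    edges = list(range(lo, hi + 2))
    counts = np.bincount((samples.astype(np.int64) - lo), minlength=hi - lo + 1).tolist()
    while len(counts) > 1:
        under = [i for i, c in enumerate(counts) if c < min_count]
        if not under:
            break
        i = under[0]  # leftmost-first sweep
        if i == 0:
            j = 1
        elif i == len(counts) - 1:
            j = i - 1
        else:
            j = i + 1 if counts[i + 1] <= counts[i - 1] else i - 1
        a, b = sorted((i, j))
        counts[a] += counts[b]
        del counts[b]
        del edges[b]
    return BinningScheme(np.asarray(edges, dtype=float), reference=reference,
                         min_count=min_count)


@dataclass(frozen=True)
class BinnedDensity:
    """Histogram PDF or CDF for one timepoint, with binomial variances."""

    kind: Literal["pdf", "cdf"]
    scheme: BinningScheme
    probs: np.ndarray
    n_samples: int
    variances: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.shape != (self.scheme.n_bins,):
            raise ValueError("one probability per bin required")
        if self.variances is None:
            object.__setattr__(self, "variances", binomial_variance(probs, self.n_samples))
        if self.kind == "pdf" and abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"pdf must sum to 1, got {probs.sum()!r}")
        if self.kind == "cdf":
            if np.any(np.diff(probs) < -1e-12) or abs(probs[-1] - 1.0) > 1e-9:
                raise ValueError("cdf must be non-decreasing and end at 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.scheme.edges[:-1],
                "bin_high": self.scheme.edges[1:],
                "probability": self.probs,
                "variance": self.variances,
            }
        )


def pdf_from_samples(samples, scheme: BinningScheme) -> BinnedDensity:
    """Histogram probabilities ``count_l / N`` under a given scheme."""
    samples = np.asarray(samples)
    n = samples.size
    counts = scheme.counts(samples)
    return BinnedDensity("pdf", scheme, counts / n, n)


def cdf_from_pdf(pdf: BinnedDensity) -> BinnedDensity:
    """Cumulative sums of the PDF, re-weighted with cumulative variances."""
    if pdf.kind != "pdf":
        raise ValueError("expected a pdf density")
    cum = np.minimum(np.cumsum(pdf.probs), 1.0)
    cum[-1] = 1.0
    return BinnedDensity("cdf", pdf.scheme, cum, pdf.n_samples)


@dataclass(frozen=True)
class SparseECDF:
    """Order statistics with plotting positions ``(l - 0.5)/m``.

    Ties keep consecutive positions (duplicate values get distinct
    cumulative levels, i.e. zero-width steps).
    """

    values: np.ndarray
    positions: np.ndarray

    @property
    def m(self) -> int:
        return self.values.size


def sparse_ecdf(replicates) -> SparseECDF:
    values = np.sort(np.asarray(replicates))
    m = values.size
    if m < 1:
        raise ValueError("need at least one replicate")
    positions = (np.arange(1, m + 1) - 0.5) / m
    return SparseECDF(values=values, positions=positions)


def likelihood_lookup(pdf: BinnedDensity, observation, timepoint: int | None = None
                      ) -> float:
    """Probability of the bin containing *observation*.

    Observations falling in a zero-probability bin, or outside the
    simulated support entirely, return the floor ``1/(10 N)`` instead of
    0 so that a log-likelihood stays finite while still penalizing
    unexplained observations heavily.
    """
    if pdf.kind != "pdf":
        raise ValueError("expected a pdf density")
    floor = 1.0 / (10.0 * pdf.n_samples)
    obs = float(observation)
    if obs < pdf.scheme.edges[0] or obs >= pdf.scheme.edges[-1]:
        # last bin is closed: its upper edge still belongs to the support
        if obs != pdf.scheme.edges[-1]:
            return floor
    idx = int(pdf.scheme.assign([obs])[0])
    p = pdf.probs[idx]
    return float(p) if p > 0.0 else floor


def lookup_probs(pdf: BinnedDensity, observations: np.ndarray) -> np.ndarray:
    """Vectorized :func:`likelihood_lookup` for objective hot paths."""
    floor = 1.0 / (10.0 * pdf.n_samples)
    obs = np.asarray(observations, dtype=float)
    p = pdf.probs[pdf.scheme.assign(obs)]
    outside = (obs < pdf.scheme.edges[0]) | (obs > pdf.scheme.edges[-1])
    p = np.where(outside | (p <= 0.0), floor, p)
    return p


def densities_to_tsv(times: Sequence[float], densities: Iterable[BinnedDensity],
                     path: str | Path) -> None:
    """Export per-timepoint densities as TSV (time, bin edges, prob, var)."""
    frames = []
    for t, d in zip(times, densities):
        f = d.to_frame()
        f.insert(0, "time", t)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
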