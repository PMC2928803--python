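"""Differential Evolution (DE/rand/1/bin) for noisy box-constrained objectives.

The distance landscapes produced by finite SSA ensembles are rough and
non-differentiable, so the minimizer is a population-based global search:
each generation builds a mutant ``v = x_r1 + F (x_r2 - x_r3)`` from three
distinct random members, crosses it over binomially with rate CR (one
coordinate always taken from the mutant), reflects out-of-bounds
coordinates back into the box, and keeps the trial only if it does not
worsen the objective.  Termination is a fixed generation count; an
optional population-spread threshold can stop earlier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DEConfig:
    """Optimizer settings.

    Defaults follow the canonical recommendations: differential weight
    ``f=0.5``, crossover rate ``cr=0.9``, and a population of ten times
    the number of parameters (pass ``population_size=None`` for that
    rule).
    """

    bounds: Sequence[tuple[float, float]]
    generations: int
    population_size: int | None = None
    f: float = 0.5
    cr: float = 0.9
    seed: int | np.random.SeedSequence = 0
    strategy: str = "rand/1/bin"
    spread_tol: float | None = None  # early stop when max-min objective < tol

    def __post_init__(self) -> None:
        if self.strategy != "rand/1/bin":
            raise ValueError("only the rand/1/bin strategy is implemented")
        if not 0.0 < self.f <= 2.0:
            raise ValueError("differential weight F must be in (0, 2]")
        if not 0.0 <= self.cr <= 1.0:
            raise ValueError("crossover rate CR must be in [0, 1]")
        if self.generations < 1:
            raise ValueError("need at least one generation")
        b = np.asarray(self.bounds, dtype=float)
        # empty bounds are allowed at construction (filled in by the
        # pipeline from the network); de_minimize requires them
        if b.size and (
            b.ndim != 2 or b.shape[1] != 2 or np.any(b[:, 0] > b[:, 1])
            or not np.all(np.isfinite(b))
        ):
            raise ValueError("bounds must be finite (lower, upper) pairs")

    @property
    def np_effective(self) -> int:
        n = self.population_size
        if n is None:
            n = 10 * len(self.bounds)
        if n < 4:
            raise ValueError("population size must be >= 4 for rand/1 mutation")
        return n


@dataclass
class DEResult:
    best_params: np.ndarray
    best_value: float
    history: pd.DataFrame  # per generation: best, median, spread
    n_evaluations: int
    population: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    population_values: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def history_to_csv(self, path) -> None:
        self.history.to_csv(path, index=False)


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Fold out-of-bounds coordinates back into the box (repeatedly)."""
    span = hi - lo
    out = x.copy()
    mask = span == 0
    for _ in range(100):
        below = out < lo
        above = out > hi
        if not (below.any() or above.any()):
            break
        out = np.where(below, 2 * lo - out, out)
        out = np.where(above, 2 * hi - out, out)
    else:  # pathological amplification: clip
        out = np.clip(out, lo, hi)
    return np.where(mask, lo, out)


def de_minimize(objective: Callable[[np.ndarray], float], config: DEConfig) -> DEResult:
    """Minimize *objective* over the box given by ``config.bounds``.

    Deterministic for a given seed.  The best objective value recorded in
    the history is non-increasing by construction (greedy selection).
    """
    bounds = np.asarray(config.bounds, dtype=float)
    if bounds.size == 0:
        raise ValueError("de_minimize needs non-empty bounds")
    lo, hi = bounds[:, 0], bounds[:, 1]
    dim = len(bounds)
    n_pop = config.np_effective
    rng = np.random.default_rng(config.seed)

    pop = lo + rng.random((n_pop, dim)) * (hi - lo)
    values = np.empty(n_pop)
    for i in range(n_pop):
        values[i] = _eval(objective, pop[i])
    n_evals = n_pop

    hist = {"generation": [], "best": [], "median": [], "spread": []}
    for gen in range(config.generations):
        for i in range(n_pop):
            r1, r2, r3 = _distinct_indices(rng, n_pop, i)
            mutant = pop[r1] + config.f * (pop[r2] - pop[r3])
            cross = rng.random(dim) < config.cr
            cross[rng.integers(dim)] = True  # guaranteed crossover coordinate
            trial = np.where(cross, mutant, pop[i])
            trial = _reflect(trial, lo, hi)
            v = _eval(objective, trial)
            n_evals += 1
            if v <= values[i]:
                pop[i] = trial
                values[i] = v
        spread = float(values.max() - values.min())
        hist["generation"].append(gen)
        hist["best"].append(float(values.min()))
        hist["median"].append(float(np.median(values)))
        hist["spread"].append(spread)
        logger.debug("generation %d: best=%.6g median=%.6g spread=%.3g",
                     gen, values.min(), np.median(values), spread)
        if config.spread_tol is not None and spread < config.spread_tol:
            break

    best = int(np.argmin(values))
    return DEResult(
        best_params=pop[best].copy(),
        best_value=float(values[best]),
        history=pd.DataFrame(hist),
        n_evaluations=n_evals,
        population=pop,
        population_values=values,
    )


def _distinct_indices(rng, n_pop: int, exclude: int) -> tuple[int, int, int]:
    idx = []
    while len(idx) < 3:
        r = int(rng.integers(n_pop))
        if r != exclude and r not in idx:
            idx.append(r)
    return tuple(idx)


def _eval(objective, x: np.ndarray) -> float:
    try:
        v = float(objective(x))
    except Exception:
        logger.error("objective raised at parameters %s", x.tolist())
        raise
    if not np.isfinite(v):
        raise ValueError(f"objective returned non-finite value {v!r} at {x.tolist()}")
    return v
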