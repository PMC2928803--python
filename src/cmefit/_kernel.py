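"""Numba inner loop for the direct-method SSA.

Propensities are pre-flattened by :meth:`ReactionNetwork.kernel_tables`
into per-reaction code tables (kind 0 = mass action with up to two
reactant slots, kind 1 = repressive Hill), so the hot loop contains no
Python objects.  Each realization re-seeds numba's per-thread legacy RNG
from an externally supplied sub-stream seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _propensities(x, kinds, coefs, sp, out):
    m = kinds.shape[0]
    a0 = 0.0
    for j in range(m):
        if kinds[j] == 0:
            a = coefs[j, 0]
            s0 = sp[j, 0]
            s1 = sp[j, 1]
            if s0 >= 0:
                if s1 == s0:
                    a *= x[s0] * (x[s0] - 1.0) / 2.0
                else:
                    a *= x[s0]
                    if s1 >= 0:
                        a *= x[s1]
        else:
            # Hill repression: A / (1 + (x/s)^h); scale 0 encodes a fully
            # sequestered regulator (propensity == numerator)
            scale = coefs[j, 1]
            if scale == 0.0:
                a = coefs[j, 0]
            else:
                z = x[sp[j, 0]] / scale
                if z == 0.0 and coefs[j, 2] == 0.0:
                    a = coefs[j, 0] / 2.0  # 0^0 := 1 convention
                else:
                    a = coefs[j, 0] / (1.0 + z ** coefs[j, 2])
        if a < 0.0:
            a = 0.0
        out[j] = a
        a0 += a
    return a0


@njit(cache=True)
def run_ensemble(stoich, kinds, coefs, sp, x0, t0, sample_times, seeds, out):
    """Simulate ``len(seeds)`` independent realizations.

    ``out`` has shape (n_realizations, n_times, n_species) and is filled
    with the state holding over the interval containing each sample time
    (right-continuous step-function convention).
    """
    n_real = seeds.shape[0]
    n_times = sample_times.shape[0]
    n_sp = x0.shape[0]
    m = kinds.shape[0]
    a = np.empty(m)
    for r in range(n_real):
        np.random.seed(seeds[r])
        x = x0.astype(np.float64)
        t = t0
        i_t = 0
        while i_t < n_times:
            a0 = _propensities(x, kinds, coefs, sp, a)
            if a0 <= 0.0:
                # frozen system: every remaining sample sees the same state
                for i in range(i_t, n_times):
                    for s in range(n_sp):
                        out[r, i, s] = np.int64(x[s])
                break
            tau = -np.log(np.random.random()) / a0
            t_next = t + tau
            while i_t < n_times and sample_times[i_t] < t_next:
                for s in range(n_sp):
                    out[r, i_t, s] = np.int64(x[s])
                i_t += 1
            if i_t >= n_times:
                break
            # pick the reaction index proportionally to its propensity
            u = np.random.random() * a0
            acc = 0.0
            j_fire = m - 1
            for j in range(m):
                acc += a[j]
                if u < acc:
                    j_fire = j
                    break
            for s in range(n_sp):
                x[s] += stoich[j_fire, s]
            t = t_next
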