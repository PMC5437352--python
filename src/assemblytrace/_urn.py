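"""Numba kernel for the discrete urn (Moran-with-immigration) dynamics.

One step = one death (uniform over individuals) plus one replacement:
with probability m an immigrant drawn from the (fitness-weighted)
metacommunity, otherwise a local birth proportional to abundance times
fitness.  All randomness enters through a pre-drawn uniform array so the
kernel is deterministic given the caller's generator state.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def urn_run(counts, w, q_cum, m, u):  # pragma: no cover - exercised via wrapper
    S = counts.shape[0]
    N = 0
    for j in range(S):
        N += counts[j]
    n_steps = u.shape[0]
    for t in range(n_steps):
        # death: uniform over the N individuals
        r = u[t, 0] * N
        acc = 0.0
        dj = S - 1
        for j in range(S):
            acc += counts[j]
            if r < acc:
                dj = j
                break
        counts[dj] -= 1
        # replacement
        if u[t, 1] < m:
            # immigrant: inverse-CDF lookup in the metacommunity
            r2 = u[t, 2]
            lo = 0
            hi = S - 1
            while lo < hi:
                mid = (lo + hi) // 2
                if q_cum[mid] < r2:
                    lo = mid + 1
                else:
                    hi = mid
            bj = lo
        else:
            # local birth proportional to count x fitness among the N-1 survivors
            V = 0.0
            for j in range(S):
                V += counts[j] * w[j]
            r2 = u[t, 2] * V
            acc = 0.0
            bj = S - 1
            for j in range(S):
                acc += counts[j] * w[j]
                if r2 < acc:
                    bj = j
                    break
        counts[bj] += 1
    return counts


def run_urn_sample(
    rng: np.random.Generator,
    init_counts: np.ndarray,
    w: np.ndarray,
    q: np.ndarray,
    m: float,
    n_steps: int,
) -> np.ndarray:
    """Run one local community for ``n_steps`` events and return counts."""
    counts = init_counts.astype(np.int64).copy()
    q_cum = np.cumsum(q / q.sum())
    q_cum[-1] = 1.0
    u = rng.random((n_steps, 3))
    return np.asarray(
        urn_run(counts, w.astype(np.float64), q_cum, float(m), u)
    )
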