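"""Independent brute-force oracles shared by the statistics tests.

These re-derive the procedures from their definitions with naive loops and
enumeration, deliberately avoiding the code paths (and libraries) used by
the implementation.
"""

import itertools

import numpy as np


def bh_stepup_bruteforce(p):
    """Step-up definition applied literally: adj_(i) = min_{k >= i} m p_(k)/k."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [m * p[order[k - 1]] / k for k in range(rank_i, m + 1)]
        adj[idx] = min(1.0, min(candidates))
    return adj


def mwu_enumeration_p(x, y):
    """Exact two-sided p by enumerating every assignment of the pooled
    values to the two samples (no ties assumed)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = x.size

    def u_of(sample_a, sample_b):
        return sum(a > b for a in sample_a for b in sample_b)

    u_obs = u_of(x, y)
    us = []
    for subset in itertools.combinations(range(pooled.size), n1):
        mask = np.zeros(pooled.size, bool)
        mask[list(subset)] = True
        us.append(u_of(pooled[mask], pooled[~mask]))
    us = np.array(us)
    u_hi = max(u_obs, n1 * y.size - u_obs)
    return min(1.0, 2.0 * (us >= u_hi).mean())
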