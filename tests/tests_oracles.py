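"""Independent brute-force oracles used to cross-check the statistics."""

from itertools import combinations
from math import comb

import numpy as np


def enumerated_ranksum_p(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating every case/control split
    of the pooled values (tie-free inputs)."""
    pooled = list(x) + list(y)
    m = len(x)

    def u_stat(xs, ys):
        return sum(1.0 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    us = []
    for pick in combinations(range(len(pooled)), m):
        picked = set(pick)
        xs = [pooled[i] for i in pick]
        ys = [pooled[i] for i in range(len(pooled)) if i not in picked]
        us.append(u_stat(xs, ys))
    us = np.array(us)
    p_le = float(np.mean(us <= u_obs))
    p_ge = float(np.mean(us >= u_obs))
    return min(1.0, 2 * min(p_le, p_ge))


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by hypergeometric enumeration at fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    total = comb(r1 + r2, c1)

    def pr(k):
        return comb(r1, k) * comb(r2, c1 - k) / total

    p_obs = pr(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(pr(k) for k in range(lo, hi + 1) if pr(k) <= p_obs * (1 + 1e-9))
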