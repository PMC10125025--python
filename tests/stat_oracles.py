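"""Independent enumeration oracles for the nonparametric tests and the
Poisson tail, used to cross-check the package's statistics routines."""

from __future__ import annotations

from itertools import combinations

import mpmath
import numpy as np
from scipy.stats import rankdata


def mann_whitney_exact(a, b):
    """Exact two-sided Mann-Whitney p by enumerating group assignments."""
    a, b = list(map(float, a)), list(map(float, b))
    n, m = len(a), len(b)
    pool = a + b

    def u_of(group_a, group_b):
        return sum(
            1.0 if x > y else 0.5 if x == y else 0.0 for x in group_a for y in group_b
        )

    u_obs = u_of(a, b)
    us = []
    for idx in combinations(range(n + m), n):
        in_a = set(idx)
        ga = [pool[i] for i in idx]
        gb = [pool[i] for i in range(n + m) if i not in in_a]
        us.append(u_of(ga, gb))
    us = np.asarray(us)
    cdf = np.mean(us <= u_obs)
    sf = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2 * min(cdf, sf))


def wilcoxon_exact(diffs):
    """Exact two-sided signed-rank p by enumerating all sign flips.

    Zero differences are discarded (the "wilcox" convention). Returns
    ``(T+, p)``.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    t_obs = float(np.sum(ranks[d > 0]))
    ts = np.empty(2**n)
    for mask in range(2**n):
        s = 0.0
        for k in range(n):
            if (mask >> k) & 1:
                s += ranks[k]
        ts[mask] = s
    cdf = np.mean(ts <= t_obs)
    sf = np.mean(ts >= t_obs)
    return t_obs, min(1.0, 2 * min(cdf, sf))


def poisson_surprise_oracle(n: int, lam: float, dps: int = 60) -> float:
    """High-precision -ln P(X >= n) by brute-force tail/complement summation."""
    with mpmath.workdps(dps):
        lam_mp = mpmath.mpf(lam)
        if n - 1 >= lam:
            # direct tail: terms decay geometrically past n
            total = mpmath.mpf(0)
            k = n
            while True:
                term = mpmath.e ** (-lam_mp) * lam_mp**k / mpmath.factorial(k)
                total += term
                if k > n and term < total * mpmath.mpf(10) ** (-dps):
                    break
                k += 1
            return float(-mpmath.log(total))
        head = sum(
            mpmath.e ** (-lam_mp) * lam_mp**k / mpmath.factorial(k) for k in range(n)
        )
        return float(-mpmath.log(1 - head))
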