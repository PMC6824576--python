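"""Independent reference implementations used as test oracles.

These deliberately favour clarity over speed (plain loops, enumeration,
symbolic algebra) and share no code with the package implementations they
check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import stats


def lof_bruteforce(points: np.ndarray, k: int, lrd_cap: float = 1e10):
    """Textbook LOF with explicit loops: k-distance, reachability,
    local reachability density, then the density ratio."""
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x.reshape(-1, 1)
    n = len(x)
    d = [[math.dist(x[i], x[j]) for j in range(n)] for i in range(n)]

    kdist = []
    neigh = []
    for i in range(n):
        others = sorted(d[i][j] for j in range(n) if j != i)
        kd = others[k - 1]
        kdist.append(kd)
        neigh.append([j for j in range(n) if j != i and d[i][j] <= kd])

    lrd = []
    for i in range(n):
        reach = [max(kdist[j], d[i][j]) for j in neigh[i]]
        m = sum(reach) / len(reach)
        lrd.append(lrd_cap if m == 0 else 1.0 / m)

    return np.array([
        sum(lrd[j] for j in neigh[i]) / len(neigh[i]) / lrd[i]
        for i in range(n)
    ])


def mann_whitney_exact(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumeration of all rank splits."""
    x = list(map(float, x))
    y = list(map(float, y))
    n1, n2 = len(x), len(y)
    pooled = np.array(x + y)
    ranks = stats.rankdata(pooled)  # midranks

    def u_of(idx):
        r1 = sum(ranks[i] for i in idx)
        return r1 - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    mu = n1 * n2 / 2
    total = 0
    extreme = 0
    for idx in combinations(range(n1 + n2), n1):
        total += 1
        if abs(u_of(idx) - mu) >= abs(u_obs - mu) - 1e-12:
            extreme += 1
    return u_obs, extreme / total


def eigenvalues_charpoly(matrix: np.ndarray) -> np.ndarray:
    """Eigenvalues via the symbolically expanded characteristic polynomial."""
    import sympy

    a = np.asarray(matrix, dtype=float)
    m = sympy.Matrix([[sympy.Rational(x).limit_denominator(10 ** 15)
                       for x in row] for row in a.tolist()])
    lam = sympy.symbols("lam")
    poly = m.charpoly(lam)  # division-free Berkowitz expansion
    roots = [complex(r) for r in sympy.Poly(poly.as_expr(), lam).nroots(n=30)]
    return np.sort(np.array([r.real for r in roots]))[::-1]


def log_likelihood_distance_direct(a, b) -> float:
    """Direct evaluation of the merge cost on raw 1-D member lists."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    g = pooled.var()  # global population variance of everything merged

    def xi(v):
        return -len(v) * 0.5 * math.log(g + v.var())

    return xi(a) + xi(b) - xi(pooled)
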