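"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately naive: exhaustive enumeration and direct dynamic
programming, sharing no code with the package.
"""

from __future__ import annotations

import math
from itertools import combinations


def local_affine_score(
    a: str,
    b: str,
    match: float = 5,
    mismatch: float = -4,
    gap_open: float = 20,
    gap_extend: float = 0.5,
) -> float:
    """Brute-force Gotoh local alignment score.

    A gap of length L costs gap_open + (L-1)*gap_extend.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = max(0.0, diag + s)
            Ix[i][j] = max(M[i - 1][j] - gap_open, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - gap_open, Iy[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return best


def mw_exact_two_sided_p(x, y) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments.

    Tie-free samples only.
    """
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n, m = len(x), len(y)
    order = sorted(range(n + m), key=lambda i: pooled[i])
    rank_of = {idx: r + 1 for r, idx in enumerate(order)}
    u_obs = sum(rank_of[i] for i in range(n)) - n * (n + 1) / 2
    u_hi = max(u_obs, n * m - u_obs)
    u_lo = min(u_obs, n * m - u_obs)
    total = 0
    extreme = 0
    all_ranks = list(range(1, n + m + 1))
    for ranks_x in combinations(all_ranks, n):
        u = sum(ranks_x) - n * (n + 1) / 2
        total += 1
        if u >= u_hi or u <= u_lo:
            extreme += 1
    return extreme / total


def poisson_tail_ge(k: int, lam: float) -> float:
    """P(X >= k) for Poisson(lam) by direct summation."""
    if k <= 0:
        return 1.0
    p = 0.0
    for i in range(0, k):
        p += math.exp(-lam) * lam**i / math.factorial(i)
    return 1.0 - p


def min_count_oracle(lam: float, alpha: float, strictly_greater: bool) -> int:
    """Smallest k with P(X > k) < alpha (or P(X >= k) < alpha)."""
    k = 0
    while True:
        tail = poisson_tail_ge(k + 1, lam) if strictly_greater else poisson_tail_ge(k, lam)
        if tail < alpha:
            return k
        k += 1
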