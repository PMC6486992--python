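"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's algorithms (seed-and-extend,
sliding scoring, closed-form survival functions) and recompute expected
values by direct enumeration at small n.
"""

import math
from typing import List, Set, Tuple

import numpy as np

from cucirc.io_formats import reverse_complement


def brute_force_matches(
    up: str, down: str, min_len: int
) -> Set[Tuple[int, int, int, int]]:
    """All maximal reverse-complement substring matches by dynamic programming.

    Returns (up_start, up_end, down_start, down_end), 1-based inclusive.
    """
    up = up.upper()
    rc = reverse_complement(down.upper())
    n, m = len(up), len(rc)
    a = np.frombuffer(up.encode(), dtype=np.uint8)
    b = np.frombuffer(rc.encode(), dtype=np.uint8)
    eq = (a[:, None] == b[None, :]) & (a[:, None] != ord("N"))
    L = np.zeros((n + 1, m + 1), dtype=np.int32)
    for i in range(1, n + 1):
        L[i, 1 : m + 1] = np.where(eq[i - 1], L[i - 1, 0:m] + 1, 0)
    out: Set[Tuple[int, int, int, int]] = set()
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            length = int(L[i, j])
            if length < min_len:
                continue
            # maximal iff it cannot be extended to the right
            if i < n and j < m and eq[i, j]:
                continue
            i0, j0 = i - length, j - length  # 0-based starts in up / rc
            d0 = m - 1 - (j0 + length - 1)  # 0-based start in down
            out.add((i0 + 1, i0 + length, d0 + 1, d0 + length))
    return out


def hypergeom_sf_enumeration(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for a hypergeometric draw by direct combinatorial sum."""
    total = math.comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        acc += math.comb(K, x) * math.comb(N - K, n - x)
    return acc / total


def ranksum_two_sided_enumeration(x: List[float], y: List[float]) -> float:
    """Exact two-sided rank-sum p-value by enumerating all group assignments."""
    from itertools import combinations

    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "enumeration oracle assumes no ties"
    ranks = {v: r for r, v in enumerate(pooled, start=1)}
    nx = len(x)
    obs = sum(ranks[v] for v in x)
    sums = [sum(pos for pos in combo) for combo in combinations(range(1, len(pooled) + 1), nx)]
    mean = nx * (len(pooled) + 1) / 2.0
    extreme = sum(1 for s in sums if abs(s - mean) >= abs(obs - mean) - 1e-12)
    return extreme / len(sums)


def bh_step_up_by_hand(pvals: List[float]) -> List[float]:
    """Benjamini-Hochberg by the literal step-up definition."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adj = [0.0] * n
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * n / rank_from_top)
        adj[i] = running
    return adj
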