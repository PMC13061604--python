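"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: assignments are
enumerated exhaustively, survival curves counted with a double loop, and
Fisher p values summed from exact rational hypergeometric probabilities.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import permutations
from math import comb

import numpy as np


def bruteforce_link_cost(prev_pts: np.ndarray, cur_pts: np.ndarray,
                         max_dist: float) -> float:
    """Minimal total cost over all feasible partial one-to-one assignments.

    Cost = sum of squared distances of linked pairs + max_dist**2 per
    unlinked spot on either side (the LAP non-linking alternative).
    """
    n, m = len(prev_pts), len(cur_pts)
    alt = max_dist**2
    d2 = ((prev_pts[:, None, :] - cur_pts[None, :, :]) ** 2).sum(axis=2)
    best = np.inf
    # enumerate assignments of prev spots to cur spots or None
    targets = list(range(m)) + [None] * n
    for perm in set(permutations(targets, n)):
        used = [t for t in perm if t is not None]
        if len(used) != len(set(used)):
            continue
        cost = 0.0
        feasible = True
        for i, t in enumerate(perm):
            if t is None:
                cost += alt
            elif d2[i, t] < alt:
                cost += d2[i, t]
            else:
                feasible = False
                break
        if not feasible:
            continue
        cost += alt * (m - len(used))     # unlinked current spots
        best = min(best, cost)
    return best


def achieved_link_cost(prev_pts: np.ndarray, cur_pts: np.ndarray,
                       assign: dict[int, int], max_dist: float) -> float:
    alt = max_dist**2
    cost = 0.0
    for i, j in assign.items():
        cost += float(((prev_pts[i] - cur_pts[j]) ** 2).sum())
    cost += alt * (len(prev_pts) - len(assign))
    cost += alt * (len(cur_pts) - len(assign))
    return cost


def survival_counting(durations: np.ndarray, t_min: float) -> tuple[np.ndarray, np.ndarray]:
    """O(n^2) survival curve: S(t') = #(shifted >= t') / n at unique points."""
    shifted = np.asarray(durations, float) - t_min
    ts = np.unique(shifted)
    s = np.array([np.sum(shifted >= t) / len(shifted) for t in ts], float)
    return ts, s


def fisher_two_sided_exact(table: list[list[int]]) -> float:
    """Two-sided Fisher p by exact rational enumeration of the support."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(k: int) -> Fraction:
        return Fraction(comb(row1, k) * comb(row2, col1 - k), comb(n, col1))

    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    p_obs = prob(a)
    total = sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs)
    return float(total)


def bh_by_hand(p: np.ndarray) -> np.ndarray:
    """Step-up Benjamini-Hochberg from the definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return np.minimum(adj, 1.0)


def msd_double_loop(xy: np.ndarray, max_lag: int) -> np.ndarray:
    """Time-averaged MSD by explicit double loop."""
    n = len(xy)
    out = np.zeros(max_lag)
    for lag in range(1, max_lag + 1):
        acc = 0.0
        cnt = 0
        for i in range(n - lag):
            acc += float(((xy[i + lag] - xy[i]) ** 2).sum())
            cnt += 1
        out[lag - 1] = acc / cnt
    return out
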