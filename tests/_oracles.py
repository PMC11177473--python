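"""Independent brute-force oracles used by the test suite.

Each function here re-derives an expected result by direct enumeration or
elementary arithmetic, independently of the implementation it checks.
"""

from itertools import product

import numpy as np
from scipy import stats

STATES = ("ns", "up", "down")


def pattern_rule_table(s_f1p1: str, s_f1p2: str, s_p1p2: str,
                       m_p1: float, m_f1: float, m_p2: float) -> str:
    """Rule-table classification from contrast states and genotype means.

    States are 'ns' (not significant), 'up'/'down' (significant with that
    direction; F1vsP1 'up' means F1 above parent1, P1vsP2 'up' means
    parent1 above parent2).
    """
    if s_f1p1 == "up" and s_f1p2 == "up":
        return {"up": "P12", "down": "P10", "ns": "P11"}[s_p1p2]
    if s_f1p1 == "down" and s_f1p2 == "down":
        return {"up": "P9", "down": "P7", "ns": "P8"}[s_p1p2]
    if s_p1p2 in ("up", "down"):
        if s_f1p1 == "ns" and s_f1p2 != "ns":
            return "P3" if s_p1p2 == "up" else "P5"
        if s_f1p2 == "ns" and s_f1p1 != "ns":
            return "P6" if s_p1p2 == "up" else "P4"
        if (
            s_f1p1 != "ns"
            and s_f1p2 != "ns"
            and min(m_p1, m_p2) < m_f1 < max(m_p1, m_p2)
        ):
            return "P1" if m_p1 > m_p2 else "P2"
    return "UNCLASSIFIED"


def enumerate_call_combinations():
    """All 3^3 contrast-state combinations x consistent mean orderings.

    Means are drawn from {1, 2, 3}^3 and kept when compatible with every
    significant direction (a significant contrast's means must be ordered
    accordingly; non-significant contrasts impose no constraint).
    """
    combos = []
    for s1, s2, sp in product(STATES, repeat=3):
        for m_p1, m_f1, m_p2 in product((1.0, 2.0, 3.0), repeat=3):
            if s1 == "up" and not m_f1 > m_p1:
                continue
            if s1 == "down" and not m_f1 < m_p1:
                continue
            if s2 == "up" and not m_f1 > m_p2:
                continue
            if s2 == "down" and not m_f1 < m_p2:
                continue
            if sp == "up" and not m_p1 > m_p2:
                continue
            if sp == "down" and not m_p1 < m_p2:
                continue
            combos.append((s1, s2, sp, m_p1, m_f1, m_p2))
    return combos


def hypergeom_tail_bruteforce(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by direct summation of hypergeometric point masses."""
    from math import comb

    denom = comb(N, n)
    return sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(n, K) + 1)) / denom


def bh_stepup(p):
    """Hand step-up BH: p_(i) * m / i, cumulative minimum from the top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def welch_all_pairs_distinct(groups: dict, alpha: float) -> dict:
    """Pairwise Welch t-tests; returns {pair: significantly different}."""
    names = list(groups)
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            p = stats.ttest_ind(groups[a], groups[b], equal_var=False).pvalue
            out[(a, b)] = p < alpha
    return out
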