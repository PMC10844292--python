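"""Independent brute-force oracles used to pin down the statistical kernels.

These deliberately avoid the code paths they check: the Fisher oracle
enumerates the hypergeometric support directly, the rank-sum oracle
enumerates arm assignments, and the BH oracle is the textbook step-up loop.
"""

from itertools import combinations
from math import comb

import numpy as np


def fisher_two_sided(a: int, n1: int, b: int, n2: int) -> float:
    """Two-sided Fisher exact p for [[a, n1-a], [b, n2-b]] by summing the
    probabilities of all tables (same margins) no more likely than the
    observed one."""
    k = a + b  # first-column margin
    lo, hi = max(0, k - n2), min(k, n1)

    def table_prob(x):
        return comb(n1, x) * comb(n2, k - x) / comb(n1 + n2, k)

    p_obs = table_prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        px = table_prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return min(total, 1.0)


def ranksum_two_sided(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating all assignments of the
    pooled (tie-free) values to the first arm."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n1 = len(x)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    mu = n1 * (len(pooled) + 1) / 2
    dev_obs = abs(w_obs - mu)
    count = 0
    total = 0
    for subset in combinations(pooled, n1):
        total += 1
        w = sum(ranks[v] for v in subset)
        if abs(w - mu) >= dev_obs - 1e-12:
            count += 1
    return count / total


def bh_step_up(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, straight from the definition."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(p[i] * m / rank_from_top, prev)
        adj[i] = min(val, 1.0)
        prev = adj[i]
    return np.array(adj)


def shannon_brute(sizes):
    """Entropy and Hutcheson variance evaluated term by term."""
    n = sum(sizes)
    h = 0.0
    s1 = 0.0
    s2 = 0.0
    for c in sizes:
        p = c / n
        h -= p * np.log(p)
        s1 += p * np.log(p)
        s2 += p * np.log(p) ** 2
    var = (s2 - s1**2) / n + (len(sizes) - 1) / (2 * n**2)
    return h, var
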