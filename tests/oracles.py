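"""Independent brute-force oracles used to check the statistical kernels.

These are deliberately naive: exact rational arithmetic and full
enumeration, written from the textbook definitions rather than from the
package's own code paths.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact rational two-sided Fisher p by full table enumeration.

    With margins fixed, each admissible table is determined by its top-left
    cell k; its probability is C(r1, k) C(r2, c1-k) / C(n, c1).  The
    two-sided p sums probabilities of tables no more likely than the
    observed one (exact rational comparison, so no tie tolerance needed).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    probs = {k: Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
             for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum((p for p in probs.values() if p <= p_obs), Fraction(0))


def mann_whitney_exact_oracle(x, y) -> Fraction:
    """Exact two-sided Mann-Whitney p by enumerating group assignments.

    Enumerates every way of labelling the pooled observations, computes
    the rank-sum-based U for each, and counts assignments whose deviation
    of U from its null mean n1*n2/2 is at least the observed deviation.
    Valid only for tie-free data.
    """
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1, n2 = len(x), len(y)
    n = n1 + n2
    rank_of = {v: i + 1 for i, v in enumerate(pooled)}
    mu = Fraction(n1 * n2, 2)

    def u_of(values) -> Fraction:
        r1 = sum(rank_of[v] for v in values)
        return Fraction(r1 - n1 * (n1 + 1) // 2)

    dev_obs = abs(u_of(x) - mu)
    count = total = 0
    for combo in itertools.combinations(pooled, n1):
        total += 1
        if abs(u_of(combo) - mu) >= dev_obs:
            count += 1
    return Fraction(count, total)


def bh_naive_oracle(p_values):
    """Naive O(m^2) Benjamini-Hochberg step-up adjustment."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [None] * m
    for rank_pos, idx in enumerate(order):
        candidates = []
        for later_pos in range(rank_pos, m):
            j = order[later_pos]
            candidates.append(p_values[j] * m / (later_pos + 1))
        q[idx] = min(1.0, min(candidates))
    return q
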