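"""Association statistics: hypomethylation class, Fisher, Mann-Whitney,
Spearman.

These are the tests linking promoter methylation to disease stage and
expression: a sample is *hypomethylated* when its region mean beta is
strictly below the cutoff (default 0.33); hypomethylation frequency
between stages is compared with a two-sided Fisher exact test; expression
shifts with a two-tailed unpaired Mann-Whitney test; and methylation-
expression coupling with Spearman rank correlation.

The tests are implemented here from their definitions (hypergeometric
enumeration for Fisher; exact rank-assignment enumeration or the
tie/continuity-corrected normal approximation for Mann-Whitney; mid-rank
Pearson with a t approximation for Spearman) so that boundary and tie
behavior is fully specified and checked against brute-force oracles in the
test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

HYPO = "hypomethylated"
NOT_HYPO = "not_hypomethylated"
UNCLASSIFIED = "unclassified"


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    odds_ratio: float | None = None

    def __post_init__(self) -> None:
        if not math.isnan(self.p_value) and not (0 <= self.p_value <= 1):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not math.isnan(self.rho) and abs(self.rho) > 1 + 1e-12:
            raise ValidationError(f"|rho| > 1: {self.rho}")


def classify_hypomethylated(region_means, cutoff: float = 0.33) -> pd.Series:
    """Label each sample by its region mean beta: strictly below the
    cutoff is hypomethylated, at or above is not, missing is unclassified.
    """
    if not (0 < cutoff < 1):
        raise ValidationError("cutoff must be in (0, 1)")
    means = pd.Series(region_means, dtype=float)
    labels = pd.Series(
        np.where(means.isna(), UNCLASSIFIED,
                 np.where(means < cutoff, HYPO, NOT_HYPO)),
        index=means.index,
    )
    labels.name = "methylation_class"
    return labels


def contingency_by_group(classes: pd.Series, groups: pd.Series,
                         group1: str, group2: str) -> np.ndarray:
    """Build the 2x2 table [[hypo, not], [hypo, not]] for two sample
    groups, ignoring unclassified samples."""
    shared = classes.index.intersection(groups.index)
    classes, groups = classes.loc[shared], groups.loc[shared]
    usable = classes != UNCLASSIFIED
    table = np.zeros((2, 2), dtype=int)
    for i, g in enumerate((group1, group2)):
        sel = usable & (groups == g)
        table[i, 0] = int((classes[sel] == HYPO).sum())
        table[i, 1] = int((classes[sel] == NOT_HYPO).sum())
    return table


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    With both margins fixed, the two-sided p sums the hypergeometric
    probabilities of every table at least as unlikely as the observed one
    (probability-ordering definition); a relative tolerance of 1e-7
    absorbs floating-point ties.  The odds ratio is ad/bc with an
    infinite sentinel when bc = 0.
    """
    counts = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in counts):
        raise ValidationError(f"counts must be non-negative integers: {counts}")
    a, b, c, d = (int(x) for x in counts)
    n = a + b + c + d
    if n == 0:
        raise ValidationError("empty contingency table")
    r1, c1 = a + b, a + c
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    p = min(p, 1.0)
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = a * d / (b * c)
    return TestResult(statistic=odds, p_value=p, method="fisher_exact_two_sided",
                      n=(r1, c + d), odds_ratio=odds)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    greater = (x[:, None] > y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    return float(greater) + 0.5 * float(ties)


def mann_whitney(x, y, mode: str = "auto",
                 exact_limit: int = 12) -> TestResult:
    """Two-tailed unpaired Mann-Whitney U test.

    U counts the pairs (x_i, y_j) with x_i > y_j, plus half the tied
    pairs.  The exact two-sided p enumerates all C(n1+n2, n1) rank
    assignments and is used when n1 + n2 <= ``exact_limit`` and no values
    tie; otherwise the normal approximation with tie correction and a
    0.5 continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    if mode not in ("auto", "exact", "approx"):
        raise ValidationError("mode must be exact, approx or auto")
    n1, n2 = len(x), len(y)
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    use_exact = mode == "exact" or (
        mode == "auto" and n1 + n2 <= exact_limit and not has_ties)
    if use_exact and has_ties:
        raise ValidationError("exact Mann-Whitney p is undefined with ties")
    mu = n1 * n2 / 2.0
    if use_exact:
        dev = abs(u - mu)
        count = total = 0
        idx = np.arange(n1 + n2)
        for combo in itertools.combinations(idx, n1):
            xs = pooled[list(combo)]
            ys = np.delete(pooled, list(combo))
            total += 1
            if abs(_u_statistic(xs, ys) - mu) >= dev - 1e-9:
                count += 1
        return TestResult(statistic=u, p_value=count / total,
                          method="mann_whitney_exact", n=(n1, n2))
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum())
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return TestResult(statistic=u, p_value=1.0,
                          method="mann_whitney_approx", n=(n1, n2))
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(sps.norm.sf(z)))
    return TestResult(statistic=u, p_value=p,
                      method="mann_whitney_approx", n=(n1, n2))


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    Pairs with a missing member are dropped; with fewer than 3 complete
    pairs the result is flagged missing (NaN rho and p).  The two-sided p
    uses the t approximation with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        return CorrelationResult(rho=math.nan, p_value=math.nan, n=n)
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    sx, sy = rx.std(ddof=0), ry.std(ddof=0)
    if sx == 0 or sy == 0:
        return CorrelationResult(rho=math.nan, p_value=math.nan, n=n)
    if np.array_equal(rx, ry):  # identical rankings: exactly 1
        rho = 1.0
    elif np.array_equal(rx, len(rx) + 1 - ry):  # exactly reversed
        rho = -1.0
    else:
        rho = float(np.clip(
            np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy),
            -1.0, 1.0))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1 - rho ** 2))
        p = min(1.0, 2.0 * float(sps.t.sf(abs(t), n - 2)))
    return CorrelationResult(rho=rho, p_value=p, n=n)
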