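"""Quantile-threshold maximum-lifespan comparison.

Maximum lifespan is compared between two groups by pooling their ages,
finding the age at which only an upper fraction (e.g. the longest-lived 25%
or 10%) of the pooled animals remains alive, scoring every animal
alive/dead at that threshold, and testing the resulting 2×2 table with an
exact Fisher test built by hypergeometric enumeration. Unlike the log-rank
test, which integrates over the whole follow-up, this test is sensitive
specifically to divergence in the survival tail.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import EstimationError, ParameterError

__all__ = [
    "MaxLifeTestResult",
    "FisherExactResult",
    "quantile_threshold",
    "fisher_exact",
    "wang_allison_test",
]


def quantile_threshold(pooled_ages, alive_fraction: float) -> float:
    """Age at which only ``alive_fraction`` of the pooled animals survive.

    Returns the ceil(n·(1 − alive_fraction))-th order statistic of the
    pooled (uncensored) ages: strictly more than alive_fraction·n animals
    outlive any age strictly below it.
    """
    if not (0.0 < alive_fraction < 1.0):
        raise ParameterError("alive_fraction must lie strictly between 0 and 1")
    ages = np.sort(np.asarray(pooled_ages, dtype=float).ravel())
    if ages.size == 0:
        raise EstimationError("no ages supplied")
    k = math.ceil(ages.size * (1.0 - alive_fraction))
    return float(ages[k - 1])


@dataclass(frozen=True)
class FisherExactResult:
    p_value: float
    odds_ratio: float


def fisher_exact(table, tie_slack: float = 1e-7) -> FisherExactResult:
    """Exact two-sided Fisher test of a 2×2 table by direct hypergeometric
    enumeration with integer arithmetic.

    With row and column margins fixed, the two-sided p-value sums the
    (exact) hypergeometric probabilities of every table whose probability
    does not exceed the observed one; ``tie_slack`` is the relative slack
    admitting near-ties (the enumeration itself is exact, so it only matters
    for deliberately loose tie rules). The odds ratio is (a·d)/(b·c), with
    infinity when b·c = 0 < a·d and NaN for a 0/0 indeterminate or a zero
    margin (where p = 1).
    """
    t = np.asarray(table, dtype=object)
    if t.shape != (2, 2):
        raise ParameterError("table must be 2x2")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    if min(a, b, c, d) < 0:
        raise ParameterError("table entries must be non-negative integers")

    ad, bc = a * d, b * c
    if bc == 0:
        odds = math.inf if ad > 0 else math.nan
    else:
        odds = ad / bc

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        # a zero margin: only one table is possible
        return FisherExactResult(p_value=1.0, odds_ratio=math.nan)

    # support of the (1,1) cell given the margins; unnormalised integer
    # weights comb(r1, k) * comb(r2, c1 - k) share the denominator comb(n, c1)
    kmin = max(0, c1 - r2)
    kmax = min(r1, c1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(kmin, kmax + 1)]
    w_obs = weights[a - kmin]
    cutoff = w_obs + int(tie_slack * w_obs)
    numer = sum(w for w in weights if w <= cutoff)
    denom = math.comb(n, c1)
    return FisherExactResult(p_value=min(1.0, numer / denom), odds_ratio=odds)


@dataclass(frozen=True)
class MaxLifeTestResult:
    """Outcome of the quantile-threshold maximum-lifespan test."""

    quantile: float        # fraction of the pooled sample left alive
    threshold_age: float   # days
    table: np.ndarray      # rows = groups, columns = (alive, dead)
    p_value: float
    odds_ratio: float


def wang_allison_test(group_a, group_b, alive_fraction: float = 0.25) -> MaxLifeTestResult:
    """Compare maximum lifespan between two groups at a pooled quantile age.

    Both (uncensored) groups are pooled; the threshold is the pooled age at
    which ``alive_fraction`` of animals remain alive; each animal is scored
    alive (age strictly greater than the threshold — the threshold animal
    itself has died by that age) or dead; the group × status table goes to
    :func:`fisher_exact`.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise EstimationError("both groups must be non-empty")
    threshold = quantile_threshold(np.concatenate([a, b]), alive_fraction)
    alive_a = int(np.sum(a > threshold))
    alive_b = int(np.sum(b > threshold))
    table = np.array(
        [[alive_a, a.size - alive_a], [alive_b, b.size - alive_b]], dtype=int
    )
    if alive_a + alive_b == 0:
        warnings.warn(
            "no animal outlives the threshold age: maximum-lifespan table is "
            "degenerate, p = 1"
        )
        return MaxLifeTestResult(alive_fraction, threshold, table, 1.0, math.nan)
    res = fisher_exact(table)
    return MaxLifeTestResult(
        quantile=alive_fraction,
        threshold_age=threshold,
        table=table,
        p_value=res.p_value,
        odds_ratio=res.odds_ratio,
    )
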