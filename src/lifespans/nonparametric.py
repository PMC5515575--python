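"""Kaplan–Meier estimation, median lifespan and the two-sample log-rank test.

These are implemented from their defining formulas rather than delegated, so
that the tie conventions and the score-test identity with the Cox model are
under the package's control (lifelines is used as an independent cross-check
in the test suite only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import EstimationError, ParameterError

__all__ = [
    "SurvivalCurve",
    "LogRankResult",
    "km_estimate",
    "median_lifespan",
    "percent_change",
    "PercentChange",
    "logrank_test",
]


def _as_ages_events(ages, events=None) -> tuple[np.ndarray, np.ndarray]:
    """Accept an array of ages, an (ages, events) pair, or a Cohort-like
    object exposing .ages/.events."""
    if events is None and hasattr(ages, "ages") and hasattr(ages, "events"):
        return np.asarray(ages.ages, float), np.asarray(ages.events, bool)
    if events is None and isinstance(ages, tuple) and len(ages) == 2:
        ages, events = ages
    a = np.asarray(ages, dtype=float).ravel()
    e = (
        np.ones(a.shape, dtype=bool)
        if events is None
        else np.asarray(events, dtype=bool).ravel()
    )
    if a.size == 0:
        raise EstimationError("no observations")
    if e.shape != a.shape:
        raise EstimationError("ages and events must have equal length")
    if np.any(~np.isfinite(a)) or np.any(a <= 0):
        raise EstimationError("ages must be positive and finite")
    return a, e


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit survival estimate.

    ``times`` are the distinct observed death times (strictly increasing);
    ``survival`` the KM estimate just after each, with ``at_risk`` and
    ``deaths`` the corresponding risk-set sizes and death counts.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray

    def survival_at(self, t):
        """S(t): right-continuous step evaluation (S = 1 before the first
        death time)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        padded = np.concatenate([[1.0], self.survival])
        out = padded[idx]
        return out if out.shape else float(out)


def km_estimate(ages, events=None) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimator.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct death times t_i with
    d_i deaths among n_i at risk. With no censoring this equals the empirical
    survival function. An all-censored input yields an empty step function
    (S identically 1) with a warning.
    """
    a, e = _as_ages_events(ages, events)
    if not e.any():
        warnings.warn("all observations censored: survival curve is constant at 1")
        empty = np.array([], dtype=float)
        return SurvivalCurve(empty, empty, empty.astype(int), empty.astype(int))
    order = np.argsort(a, kind="stable")
    a, e = a[order], e[order]
    death_times = np.unique(a[e])
    # at risk just before t: number with age >= t
    n_at_risk = a.size - np.searchsorted(a, death_times, side="left")
    deaths = np.array([np.sum(e[a == t]) for t in death_times])
    surv = np.cumprod(1.0 - deaths / n_at_risk)
    return SurvivalCurve(death_times, surv, n_at_risk.astype(int), deaths.astype(int))


def median_lifespan(curve: SurvivalCurve | np.ndarray, events=None) -> float:
    """Median survival: smallest death time t with S(t) <= 0.5.

    Accepts a fitted curve or raw ages(+events). Raises when the curve never
    reaches 0.5 (heavy censoring).
    """
    if not isinstance(curve, SurvivalCurve):
        curve = km_estimate(curve, events)
    below = np.nonzero(curve.survival <= 0.5)[0]
    if below.size == 0:
        raise EstimationError("survival never drops to 0.5: median undefined")
    return float(curve.times[below[0]])


@dataclass(frozen=True)
class PercentChange:
    """Lifespan difference reference − comparison in days and percent."""

    days: float
    percent: float

    @property
    def days_rounded(self) -> int:
        return int(round(self.days))

    @property
    def percent_rounded(self) -> int:
        return int(round(self.percent))


def percent_change(reference: float, comparison: float) -> PercentChange:
    """Change from ``reference`` to ``comparison``: positive = shortening.

    percent = 100·(reference − comparison)/reference. The ``*_rounded``
    accessors give the nearest-integer forms used for whole-day /
    whole-percent statements.
    """
    if reference <= 0:
        raise ParameterError("reference lifespan must be positive")
    days = reference - comparison
    return PercentChange(days=days, percent=100.0 * days / reference)


@dataclass(frozen=True)
class LogRankResult:
    """Two-sample log-rank test (1 degree of freedom)."""

    statistic: float
    p_value: float
    observed: np.ndarray  # per-group observed deaths
    expected: np.ndarray  # per-group expected deaths under H0
    variance: float       # accumulated hypergeometric variance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"LogRankResult(statistic={self.statistic:.4g}, "
            f"p_value={self.p_value:.4g})"
        )


def logrank_test(group_a, group_b, events_a=None, events_b=None) -> LogRankResult:
    """Two-sample log-rank test.

    At each distinct death time the observed deaths in group A are compared
    with the conditional hypergeometric expectation E = d·n_a/n and variance
    V = d·(n_a/n)(1 − n_a/n)(n − d)/(n − 1) (defined as 0 when n = 1); the
    statistic (O_A − E_A)² / ΣV is referred to chi-square with 1 df. A zero
    total variance yields p = 1 with a warning.
    """
    a, ea = _as_ages_events(group_a, events_a)
    b, eb = _as_ages_events(group_b, events_b)
    stat, p, o, e, v = _logrank_arrays(a, ea, b, eb)
    return LogRankResult(stat, p, o, e, v)


def _logrank_arrays(a, ea, b, eb):
    a_sorted = np.sort(a)
    b_sorted = np.sort(b)
    death_times = np.unique(np.concatenate([a[ea], b[eb]]))
    na = a.size - np.searchsorted(a_sorted, death_times, side="left")
    nb = b.size - np.searchsorted(b_sorted, death_times, side="left")
    da = _counts_at(a[ea], death_times)
    db = _counts_at(b[eb], death_times)
    n = na + nb
    d = da + db
    frac = na / n
    expected_a = d * frac
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.where(
            n > 1, d * frac * (1.0 - frac) * (n - d) / np.maximum(n - 1, 1), 0.0
        )
    o_a = float(da.sum())
    e_a = float(expected_a.sum())
    v = float(var.sum())
    if v == 0.0:
        warnings.warn("log-rank variance is zero; the groups cannot be compared")
        return 0.0, 1.0, np.array([o_a, float(db.sum())]), np.array(
            [e_a, float((d - expected_a).sum())]
        ), 0.0
    stat = (o_a - e_a) ** 2 / v
    p = float(stats.chi2.sf(stat, df=1))
    observed = np.array([o_a, float(db.sum())])
    expected = np.array([e_a, float((d - expected_a).sum())])
    return float(stat), p, observed, expected, v


def _counts_at(values: np.ndarray, times: np.ndarray) -> np.ndarray:
    values = np.sort(values)
    left = np.searchsorted(values, times, side="left")
    right = np.searchsorted(values, times, side="right")
    return (right - left).astype(float)
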