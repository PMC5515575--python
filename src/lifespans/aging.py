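"""Non-parametric interval mortality rates and aging rates.

Mortality in an age interval is estimated occurrence/exposure style: the
number of deaths in the interval divided by the mouse-days lived in it by
all animals (each animal alive at the interval start contributes
min(death age, interval end) − interval start days). The aging rate between
two adjacent intervals is the difference of their mortality rates divided by
the distance between interval midpoints — a finite-difference estimate of
the hazard slope, reported at the shared boundary age in deaths per 10,000
mice per day.

Intervals are half-open [k·width, (k+1)·width) anchored at day 0. To guard
against sparse tails, the last interval containing deaths
is excluded from rate comparisons when it holds exactly one death.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EstimationError, ParameterError

__all__ = [
    "MortalityIntervalTable",
    "AgingRateSeries",
    "interval_mortality_rates",
    "aging_rates_from_mortality",
]

PER_10K = 1.0e4


@dataclass(frozen=True)
class MortalityIntervalTable:
    """Per-interval deaths, exposure and mortality rate for one group."""

    table: pd.DataFrame  # interval_start, interval_end, deaths, mouse_days,
                         # mortality_rate, rate_per_10k, excluded
    width: float
    n_animals: int

    def __len__(self) -> int:
        return len(self.table)

    @property
    def usable(self) -> pd.DataFrame:
        """Intervals entering aging-rate differences: not excluded and with
        positive exposure."""
        t = self.table
        return t[(~t["excluded"]) & (t["mouse_days"] > 0)]

    @property
    def total_mouse_days(self) -> float:
        return float(self.table["mouse_days"].sum())

    @property
    def total_deaths(self) -> int:
        return int(self.table["deaths"].sum())


def interval_mortality_rates(
    ages, width: float = 200.0, origin: float = 0.0
) -> MortalityIntervalTable:
    """Occurrence/exposure mortality rates in fixed age intervals.

    ``ages`` are uncensored death ages (days). Deaths are counted in the
    half-open interval containing the death age; exposure is exact
    person-time. The last death-containing interval is flagged ``excluded``
    when it contains exactly one death.
    """
    if width <= 0:
        raise ParameterError("interval width must be positive")
    a = np.asarray(ages, dtype=float).ravel()
    if a.size == 0:
        raise EstimationError("no death ages supplied")
    if np.any(~np.isfinite(a)) or np.any(a <= 0):
        raise EstimationError("death ages must be positive and finite")
    if np.any(a < origin):
        raise EstimationError("death age below the interval origin")

    n_bins = int(np.floor((a.max() - origin) / width)) + 1
    starts = origin + width * np.arange(n_bins)
    ends = starts + width
    deaths = np.array(
        [np.sum((a >= s) & (a < e)) for s, e in zip(starts, ends)], dtype=int
    )
    exposure = np.array(
        [np.sum(np.clip(a - s, 0.0, width)) for s in starts], dtype=float
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(exposure > 0, deaths / np.where(exposure > 0, exposure, 1.0), np.nan)

    excluded = np.zeros(n_bins, dtype=bool)
    populated = np.nonzero(deaths > 0)[0]
    last = populated[-1]
    if deaths[last] == 1:
        excluded[last] = True
    excluded |= exposure <= 0  # no person-time: rate undefined

    table = pd.DataFrame(
        {
            "interval_start": starts,
            "interval_end": ends,
            "deaths": deaths,
            "mouse_days": exposure,
            "mortality_rate": rate,
            "rate_per_10k": rate * PER_10K,
            "excluded": excluded,
        }
    )
    return MortalityIntervalTable(table=table, width=float(width), n_animals=a.size)


@dataclass(frozen=True)
class AgingRateSeries:
    """Finite-difference aging rates between adjacent age intervals.

    ``ages`` are the shared boundaries of the differenced interval pairs
    (days); ``rates_per_10k`` is the change in mortality rate per day on the
    deaths-per-10,000-mice-per-day scale. ``signed`` records whether the
    difference kept its sign or was folded to absolute value (the
    default)."""

    ages: np.ndarray
    rates_per_10k: np.ndarray
    signed: bool

    @property
    def rates(self) -> np.ndarray:
        """Rates in deaths per mouse-day per day (unscaled)."""
        return self.rates_per_10k / PER_10K

    def __len__(self) -> int:
        return len(self.ages)


def aging_rates_from_mortality(
    table: MortalityIntervalTable, signed: bool = False
) -> AgingRateSeries:
    """Difference adjacent usable interval mortality rates.

    For consecutive usable intervals i, i+1 (equal width w):
    rate_i = |m_{i+1} − m_i| / Δ, with Δ the distance between interval
    midpoints; the signed variant keeps m_{i+1} − m_i. Only *adjacent*
    usable intervals are differenced; gaps (excluded or empty interior
    intervals) break the series rather than being treated as zero rate.
    """
    usable = table.usable
    if len(usable) < 2:
        raise EstimationError("need at least two usable intervals for aging rates")
    starts = usable["interval_start"].to_numpy()
    mids = (usable["interval_start"].to_numpy() + usable["interval_end"].to_numpy()) / 2.0
    m10k = usable["rate_per_10k"].to_numpy()
    ends = usable["interval_end"].to_numpy()

    adjacent = np.isclose(starts[1:], ends[:-1])
    if not adjacent.any():
        raise EstimationError("no adjacent usable interval pairs")
    delta = mids[1:] - mids[:-1]
    diff = (m10k[1:] - m10k[:-1]) / delta
    if not signed:
        diff = np.abs(diff)
    boundary = ends[:-1]
    return AgingRateSeries(
        ages=boundary[adjacent], rates_per_10k=diff[adjacent], signed=signed
    )
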