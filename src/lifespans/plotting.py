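"""Basic survival-curve and aging-rate plots (matplotlib)."""

from __future__ import annotations

import numpy as np

from .aging import AgingRateSeries
from .nonparametric import SurvivalCurve

__all__ = ["plot_survival", "plot_aging_rates"]


def plot_survival(curves: dict[str, SurvivalCurve], ax=None):
    """Step plot of one or more Kaplan-Meier curves, keyed by label."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, curve in curves.items():
        t = np.concatenate([[0.0], curve.times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=label)
    ax.set_xlabel("age (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax


def plot_aging_rates(series: dict[str, AgingRateSeries], ax=None):
    """Aging rates vs boundary age, in deaths per 10,000 mice per day."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, s in series.items():
        ax.plot(s.ages, s.rates_per_10k, marker="o", label=label)
    ax.set_xlabel("age (days)")
    ax.set_ylabel("aging rate (deaths per 10,000 mice per day)")
    ax.legend()
    return ax
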