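"""Formula-defined assay transforms: qRT-PCR ΔΔCt fold change, respiratory
quotient, and insulin-tolerance-test percent-of-baseline normalisation.

ΔΔCt sign conventions
---------------------
Two conventions are exposed. ``livak`` is the standard relative-expression
formula, fold = 2^(−ΔΔCt), under which an up-regulated gene (lower Ct in the
treated group) gives fold > 1. ``paper`` is fold = 2^(+ΔΔCt), which some
methods sections print; it yields the reciprocal (fold < 1 for
up-regulation). The default here is ``paper``, matching the convention of the study
pipeline this package mirrors — check which convention your numbers assume
before comparing across studies; the two are exact reciprocals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError

__all__ = [
    "CtMeasurement",
    "GasExchangeSample",
    "ddct_fold_change",
    "respiratory_quotient",
    "itt_percent_baseline",
]


@dataclass(frozen=True)
class CtMeasurement:
    """Threshold cycles for a target gene and its reference (e.g. GAPDH)."""

    gene_ct: float
    reference_ct: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.gene_ct) and np.isfinite(self.reference_ct)):
            raise ParameterError("Ct values must be finite")
        for v in (self.gene_ct, self.reference_ct):
            if not (10.0 <= v <= 40.0):
                warnings.warn(f"Ct value {v} outside the typical 10-40 range")

    @property
    def delta_ct(self) -> float:
        """ΔCt = gene Ct − reference Ct."""
        return self.gene_ct - self.reference_ct


def ddct_fold_change(
    treated: CtMeasurement, normal: CtMeasurement, convention: str = "paper"
) -> float:
    """Relative expression fold change from ΔΔCt.

    ΔΔCt = ΔCt_treated − ΔCt_normal; fold = 2^ΔΔCt under ``paper`` and
    2^(−ΔΔCt) under ``livak`` (see the module docstring for the sign
    discussion — the two are reciprocals).
    """
    if convention not in ("paper", "livak"):
        raise ParameterError(f"unknown convention {convention!r}")
    ddct = treated.delta_ct - normal.delta_ct
    exponent = ddct if convention == "paper" else -ddct
    return float(2.0 ** exponent)


@dataclass(frozen=True)
class GasExchangeSample:
    """Simultaneous O2 consumption and CO2 production (same volume units)."""

    vo2: float
    vco2: float

    def __post_init__(self) -> None:
        if not (self.vo2 > 0):
            raise ParameterError("VO2 must be positive")
        if self.vco2 < 0:
            raise ParameterError("VCO2 must be non-negative")


def respiratory_quotient(sample: GasExchangeSample) -> float:
    """RQ = VCO2/VO2; ~1.0 for carbohydrate oxidation, ~0.7 for fat."""
    return sample.vco2 / sample.vo2


def itt_percent_baseline(glucose, baseline_index: int = 0) -> np.ndarray:
    """Insulin-tolerance-test series as percent of its baseline value.

    Returns 100·g_t/g_baseline for each time point; invariant under
    rescaling of the glucose units.
    """
    g = np.asarray(glucose, dtype=float).ravel()
    if g.size == 0:
        raise ParameterError("empty glucose series")
    if not (0 <= baseline_index < g.size):
        raise ParameterError("baseline_index out of range")
    baseline = g[baseline_index]
    if not (baseline > 0):
        raise ParameterError("baseline glucose must be positive")
    return 100.0 * g / baseline
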