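"""Linear models of lifespan on treatment (and sex), via ordinary least
squares. The fit itself is delegated to statsmodels; this module owns the
design-matrix construction, rank diagnostics and the adjusted group means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort
from .exceptions import EstimationError

__all__ = ["LinearLifespanFit", "lifespan_linear_model"]


@dataclass
class LinearLifespanFit:
    """OLS fit of lifespan (days) on treatment with optional sex covariate.

    ``adjusted_means`` are model predictions at each treatment level averaged
    over the cohort's sex distribution ("adjusted mean lifespan"); in a
    saturated one-factor model they equal the sample group means exactly.
    """

    coefficients: pd.Series
    se: pd.Series
    pvalues: pd.Series
    adjusted_means: pd.Series
    results: sm.regression.linear_model.RegressionResultsWrapper

    @property
    def treatment_effect(self) -> float:
        """Coefficient of the non-reference treatment level (days)."""
        name = [c for c in self.coefficients.index if c.startswith("treatment")]
        return float(self.coefficients[name[0]])

    def summary(self):
        return self.results.summary()


def lifespan_linear_model(
    data: Cohort | pd.DataFrame,
    include_sex: bool = True,
    treatment_col: str = "treatment",
    sex_col: str = "sex",
    age_col: str = "age_days",
    reference: str = "saline",
) -> LinearLifespanFit:
    """Fit lifespan ~ treatment (+ sex) by least squares.

    Requires uncensored lifespans and a full-rank design; a rank-deficient
    design raises naming the collinear columns.
    """
    df = data.to_dataframe() if isinstance(data, Cohort) else data.copy()
    if "event" in df.columns and not df["event"].astype(bool).all():
        raise EstimationError("linear lifespan models require uncensored data")

    y = df[age_col].to_numpy(dtype=float)
    X = pd.DataFrame({"const": np.ones(len(df))})
    levels = [l for l in pd.unique(df[treatment_col]) if l != reference]
    base = reference if reference in set(df[treatment_col]) else pd.unique(df[treatment_col])[0]
    for level in levels:
        X[f"{treatment_col}[{level}]"] = (df[treatment_col] == level).astype(float)
    if include_sex:
        sex_levels = list(pd.unique(df[sex_col]))
        for level in sex_levels[1:]:
            X[f"{sex_col}[{level}]"] = (df[sex_col] == level).astype(float)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        bad = _collinear_columns(X)
        raise EstimationError(f"rank-deficient design; collinear columns: {bad}")

    res = sm.OLS(y, X).fit()

    # adjusted means: predict at each treatment level, averaging over the
    # observed sex distribution
    adj = {}
    for level in pd.unique(df[treatment_col]):
        Xl = X.copy()
        for other in levels:
            Xl[f"{treatment_col}[{other}]"] = 1.0 if other == level else 0.0
        adj[level] = float(res.predict(Xl).mean())

    return LinearLifespanFit(
        coefficients=pd.Series(res.params, index=X.columns),
        se=pd.Series(res.bse, index=X.columns),
        pvalues=pd.Series(res.pvalues, index=X.columns),
        adjusted_means=pd.Series(adj),
        results=res,
    )


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Name the columns implicated in the rank deficiency: those whose
    removal restores full rank of the remainder."""
    full_rank = np.linalg.matrix_rank(X.to_numpy())
    bad = []
    for col in X.columns:
        sub = X.drop(columns=[col]).to_numpy()
        if np.linalg.matrix_rank(sub) == min(sub.shape) and full_rank < X.shape[1]:
            bad.append(col)
    return bad or list(X.columns)
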