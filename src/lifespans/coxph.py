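"""Cox proportional-hazards regression by Newton–Raphson on the partial
likelihood, with Efron (default) or Breslow handling of tied death times.

The model/results split follows statsmodels: build a :class:`CoxPH` from
arrays or a DataFrame, call :meth:`CoxPH.fit`, and read estimates,
standard errors and diagnostics off the returned :class:`CoxPHResults`.

Efron's correction replaces the Breslow denominator at a time with d tied
deaths by the product over l = 0..d−1 of (S0 − (l/d)·s0), where S0 sums
risk-set weights exp(xβ) and s0 sums the tied deaths' weights; it is the
less biased choice for day-resolution lifespan data, which are tie-rich.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EstimationError

__all__ = ["CoxPH", "CoxPHResults", "cox_ph_fit"]


class CoxPH:
    """Cox proportional-hazards model for right-censored durations.

    Parameters
    ----------
    durations, events : array-like
        Age at death/censoring (days) and death indicator per subject.
    exog : array-like, shape (n, p)
        Covariates; must present at least two distinct patterns among events.
    ties : {"efron", "breslow"}
        Partial-likelihood correction for tied death times.
    """

    def __init__(self, durations, events, exog, ties: str = "efron", xnames=None):
        t = np.asarray(durations, dtype=float).ravel()
        e = np.asarray(events, dtype=bool).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if t.size == 0 or X.shape[0] != t.size or e.size != t.size:
            raise EstimationError("durations, events and exog must align")
        if np.any(~np.isfinite(X)):
            raise EstimationError("missing or non-finite covariate values")
        if not e.any():
            raise EstimationError("no events: partial likelihood is empty")
        for j in range(X.shape[1]):
            if np.ptp(X[:, j]) == 0:
                name = xnames[j] if xnames else f"x{j}"
                raise EstimationError(
                    f"covariate {name!r} is constant: no contrast to estimate"
                )
        if ties not in ("efron", "breslow"):
            raise EstimationError(f"unknown tie method {ties!r}")
        order = np.argsort(t, kind="stable")
        self.durations = t[order]
        self.events = e[order]
        self.exog = X[order]
        self.ties = ties
        self.xnames = list(xnames) if xnames else [f"x{j}" for j in range(X.shape[1])]
        self.nobs = t.size
        self.k_params = X.shape[1]
        # distinct death times -> slices into the sorted arrays
        self._death_times = np.unique(self.durations[self.events])

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        covariates: list[str],
        duration_col: str = "age_days",
        event_col: str = "event",
        ties: str = "efron",
    ) -> "CoxPH":
        """Build from a lifespan DataFrame, dummy-coding string covariates.

        Categorical columns are coded 0/1 against their first-seen level
        (e.g. treatment saline=0 / GH=1 when saline appears first).
        """
        cols = []
        names = []
        for c in covariates:
            col = df[c]
            if col.dtype == object or str(col.dtype) == "category":
                levels = list(pd.unique(col))
                if len(levels) != 2:
                    raise EstimationError(
                        f"covariate {c!r} must have exactly 2 levels, got {levels}"
                    )
                cols.append((col == levels[1]).to_numpy(dtype=float))
                names.append(f"{c}[{levels[1]}]")
            else:
                cols.append(col.to_numpy(dtype=float))
                names.append(c)
        X = np.column_stack(cols)
        events = (
            df[event_col].to_numpy(dtype=bool)
            if event_col in df.columns
            else np.ones(len(df), dtype=bool)
        )
        return cls(df[duration_col].to_numpy(float), events, X, ties=ties, xnames=names)

    # -- partial likelihood machinery ------------------------------------

    def _suffix_sums(self, beta: np.ndarray):
        """S0/S1/S2 risk-set sums at every sorted index via reverse cumsums."""
        eta = self.exog @ beta
        eta = eta - eta.max()  # guard overflow; cancels in all ratios
        w = np.exp(eta)
        wx = w[:, None] * self.exog
        wxx = wx[:, :, None] * self.exog[:, None, :]
        S0 = np.cumsum(w[::-1])[::-1]
        S1 = np.cumsum(wx[::-1], axis=0)[::-1]
        S2 = np.cumsum(wxx[::-1], axis=0)[::-1]
        return eta, w, wx, wxx, S0, S1, S2

    def loglik_score_info(self, beta):
        """Partial log-likelihood, score vector and observed information.

        The log-likelihood omits no terms; the information returned is the
        negative Hessian.
        """
        beta = np.asarray(beta, dtype=float).ravel()
        t, e, X = self.durations, self.events, self.exog
        eta, w, wx, wxx, S0, S1, S2 = self._suffix_sums(beta)
        ll = 0.0
        score = np.zeros(self.k_params)
        info = np.zeros((self.k_params, self.k_params))
        first = np.searchsorted(t, self._death_times, side="left")
        for k, tk in enumerate(self._death_times):
            i0 = first[k]
            tied = (t == tk) & e
            d = int(tied.sum())
            ll += eta[tied].sum()
            score += X[tied].sum(axis=0)
            s0, s1, s2 = S0[i0], S1[i0], S2[i0]
            if self.ties == "efron" and d > 1:
                t0 = w[tied].sum()
                t1 = wx[tied].sum(axis=0)
                t2 = wxx[tied].sum(axis=0)
                for l in range(d):
                    phi = l / d
                    den = s0 - phi * t0
                    g = (s1 - phi * t1) / den
                    ll -= np.log(den)
                    score -= g
                    info += (s2 - phi * t2) / den - np.outer(g, g)
            else:  # Breslow (also the Efron d == 1 case)
                g = s1 / s0
                ll -= d * np.log(s0)
                score -= d * g
                info += d * (s2 / s0 - np.outer(g, g))
        return float(ll), score, info

    def score_test(self, beta0=None):
        """Rao score test at ``beta0`` (default 0): returns (chi2, p).

        At β = 0 with a binary covariate and no tied deaths this equals the
        two-sample log-rank statistic exactly.
        """
        if beta0 is None:
            beta0 = np.zeros(self.k_params)
        _, score, info = self.loglik_score_info(beta0)
        stat = float(score @ np.linalg.solve(info, score))
        return stat, float(stats.chi2.sf(stat, df=self.k_params))

    def fit(self, max_iter: int = 50, tol: float = 1e-8) -> "CoxPHResults":
        """Maximise the partial likelihood by Newton steps with step-halving.

        Convergence: max-norm of the score below ``tol``. A monotone
        likelihood (perfect separation of the event order) is reported as
        non-convergence with diverging coefficients and a warning, not an
        exception.
        """
        beta = np.zeros(self.k_params)
        ll, score, info = self.loglik_score_info(beta)
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError as exc:
                raise EstimationError("singular information matrix") from exc
            # Newton decrement score'I^{-1}score: estimated log-likelihood
            # gap to the optimum; robust to the absolute scale of the score
            decrement = float(score @ step)
            if np.max(np.abs(score)) < tol or 0.0 <= decrement < (10.0 * tol) ** 2:
                converged = True
                break
            alpha = 1.0
            for _ in range(30):
                cand = beta + alpha * step
                ll_new, score_new, info_new = self.loglik_score_info(cand)
                if ll_new >= ll - 1e-12:
                    break
                alpha /= 2.0
            beta, ll, score, info = cand, ll_new, score_new, info_new
        else:
            n_iter = max_iter
        if converged and np.max(np.abs(beta)) > 15.0:
            # likelihood asymptote: the score vanishes as beta diverges
            converged = False
        if not converged:
            warnings.warn(
                "Cox fit did not converge (possible monotone likelihood / "
                f"perfect separation); |score|_inf = {np.max(np.abs(score)):.2e}, "
                f"beta = {beta}"
            )
        cov = np.linalg.inv(info)
        return CoxPHResults(
            model=self,
            params=beta,
            cov_params=cov,
            llf=ll,
            converged=converged,
            n_iter=n_iter,
            score_norm=float(np.max(np.abs(score))),
        )


@dataclass
class CoxPHResults:
    """Fitted Cox model: log hazard ratios with Wald inference."""

    model: CoxPH
    params: np.ndarray
    cov_params: np.ndarray
    llf: float
    converged: bool
    n_iter: int
    score_norm: float

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return np.column_stack(
            [self.params - z * self.bse, self.params + z * self.bse]
        )

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "HR": self.hazard_ratios,
                "se(coef)": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
                "HR 95% low": np.exp(ci[:, 0]),
                "HR 95% high": np.exp(ci[:, 1]),
            },
            index=self.model.xnames,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        status = "converged" if self.converged else "NOT converged"
        return (
            f"<CoxPHResults {status} in {self.n_iter} iter, "
            f"llf={self.llf:.4f}, ties={self.model.ties}>"
        )


def cox_ph_fit(durations, events, exog, ties: str = "efron", **fit_kwargs) -> CoxPHResults:
    """One-call convenience wrapper: build a :class:`CoxPH` and fit it."""
    return CoxPH(durations, events, exog, ties=ties).fit(**fit_kwargs)
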