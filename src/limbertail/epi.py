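"""Exact binomial inference, logistic risk modelling and descriptive summaries.

Incidence proportions carry Clopper-Pearson (central exact binomial)
intervals throughout, the convention for small case-control studies.
Odds ratios for 2x2 exposure tables come from the conditional exact
machinery in :mod:`limbertail.exact2x2`; this module adds the binomial
side, a thin logistic-regression wrapper (statsmodels under the hood,
with convergence and separation surfaced instead of swallowed) and the
t-interval / Pearson-correlation descriptives used for episode
duration, pain and quality-of-life scores.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exact2x2 import (  # noqa: F401  (re-exported as part of the stats surface)
    ContingencyTable2x2,
    OrEstimate,
    conditional_mle_or,
    exact_or_ci,
    exact_or_estimate,
    fisher_exact_p,
)

__all__ = [
    "BinomialEstimate",
    "IncidenceEstimate",
    "LogisticFit",
    "NumericSummary",
    "clopper_pearson_ci",
    "cumulative_incidence",
    "fit_logistic",
    "summarise_numeric",
    "pearson_correlation",
    "table_from_masks",
    "ContingencyTable2x2",
    "OrEstimate",
    "conditional_mle_or",
    "exact_or_ci",
    "exact_or_estimate",
    "fisher_exact_p",
]


@dataclass(frozen=True)
class BinomialEstimate:
    k: int
    n: int
    point: float
    ci_low: float
    ci_high: float
    level: float

    @property
    def percent(self) -> tuple[float, float, float]:
        """(point, low, high) on the 0-100 scale."""
        return (100 * self.point, 100 * self.ci_low, 100 * self.ci_high)


def clopper_pearson_ci(k: int, n: int, level: float = 0.95) -> BinomialEstimate:
    """Central exact (Clopper-Pearson) binomial interval.

    Uses the beta-quantile characterisation: the lower bound is the
    alpha/2 quantile of Beta(k, n-k+1), the upper the 1-alpha/2 quantile
    of Beta(k+1, n-k); k=0 and k=n pin the corresponding bound to 0 / 1.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, n], got k={k}, n={n}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return BinomialEstimate(k, n, k / n, low, high, level)


@dataclass(frozen=True)
class IncidenceEstimate:
    """Cumulative incidence with an optional non-responder sensitivity bound.

    The sensitivity bound treats every listed non-responder as
    unaffected, i.e. recomputes k / (n + n_nonresponders) — a lower
    bound on the incidence under total non-response bias.
    """

    primary: BinomialEstimate
    sensitivity: BinomialEstimate | None = None


def cumulative_incidence(
    n_cases: int, n_at_risk: int, level: float = 0.95, n_nonresponders: int = 0
) -> IncidenceEstimate:
    if n_cases > n_at_risk:
        raise ValueError("n_cases cannot exceed n_at_risk")
    primary = clopper_pearson_ci(n_cases, n_at_risk, level)
    sens = None
    if n_nonresponders > 0:
        sens = clopper_pearson_ci(n_cases, n_at_risk + n_nonresponders, level)
    return IncidenceEstimate(primary, sens)


@dataclass
class LogisticFit:
    coefficients: dict[str, float]
    wald_ci: dict[str, tuple[float, float]]
    or_scale: dict[str, float]
    or_ci: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    level: float
    converged: bool
    separation: bool
    n: int
    flags: list[str] = field(default_factory=list)


def fit_logistic(outcome, predictors, level: float = 0.95) -> LogisticFit:
    """Binary logistic regression with Wald intervals, on both scales.

    ``outcome`` is a binary vector (case=1 / control=0); ``predictors``
    a DataFrame or 2-D array of numeric/binary covariates.  An
    intercept is always added.  Non-convergence and (quasi-)complete
    separation are detected and flagged — coefficients from a separated
    fit are reported but marked unreliable, never silently returned.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    if isinstance(predictors, pd.DataFrame):
        X = predictors.astype(float)
    else:
        arr = np.atleast_2d(np.asarray(predictors, dtype=float))
        if arr.shape[0] == 1 and len(y) != 1:
            arr = arr.T
        X = pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])
    if any(X[c].nunique() == 1 for c in X.columns):
        raise ValueError("constant predictor duplicates the intercept")
    Xc = sm.add_constant(X, prepend=True)

    separation = False
    flags: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises on perfect separation
            if "separation" in str(exc).lower() or "Singular" in str(exc):
                res = sm.Logit(y, Xc).fit(disp=0, maxiter=200, method="bfgs")
                separation = True
                flags.append("separation_detected")
            else:
                raise
    converged = bool(res.mle_retvals.get("converged", False))
    if not separation and np.abs(res.params).max() > 20:
        separation = True
        flags.append("separation_suspected")
    if not converged:
        flags.append("not_converged")

    alpha = 1.0 - level
    ci = res.conf_int(alpha)
    names = list(Xc.columns)
    coefficients = {n: float(res.params[n]) for n in names}
    wald_ci = {n: (float(ci.loc[n, 0]), float(ci.loc[n, 1])) for n in names}
    return LogisticFit(
        coefficients=coefficients,
        wald_ci=wald_ci,
        or_scale={n: math.exp(v) for n, v in coefficients.items()},
        or_ci={n: (math.exp(lo), math.exp(hi)) for n, (lo, hi) in wald_ci.items()},
        p_values={n: float(res.pvalues[n]) for n in names},
        level=level,
        converged=converged,
        separation=separation,
        n=len(y),
        flags=flags,
    )


@dataclass(frozen=True)
class NumericSummary:
    n: int
    mean: float
    ci_low: float | None
    ci_high: float | None
    sd: float | None
    level: float
    n_missing: int = 0


def summarise_numeric(values: Sequence[float], level: float = 0.95) -> NumericSummary:
    """Arithmetic mean with a symmetric t-based confidence interval.

    Missing values are dropped (and counted); a single observation
    yields the mean with no interval; a constant sample yields a
    zero-width interval.
    """
    arr = np.asarray(values, dtype=float)
    n_missing = int(np.isnan(arr).sum())
    arr = arr[~np.isnan(arr)]
    n = len(arr)
    if n == 0:
        raise ValueError("no non-missing values to summarise")
    mean = float(arr.mean())
    if n < 2:
        return NumericSummary(n, mean, None, None, None, level, n_missing)
    sd = float(arr.std(ddof=1))
    half = stats.t.ppf(1 - (1 - level) / 2, n - 1) * sd / math.sqrt(n)
    return NumericSummary(n, mean, mean - half, mean + half, sd, level, n_missing)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; undefined (raises) for zero variance."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    if len(xa) < 3:
        raise ValueError("need at least 3 paired observations")
    if xa.std() == 0 or ya.std() == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(stats.pearsonr(xa, ya).statistic)


def table_from_masks(case_mask, exposed_mask) -> ContingencyTable2x2:
    """Build the exposure-by-status 2x2 table from aligned boolean vectors."""
    case = np.asarray(case_mask, dtype=bool)
    exp = np.asarray(exposed_mask, dtype=bool)
    if case.shape != exp.shape:
        raise ValueError("masks must be aligned")
    return ContingencyTable2x2(
        int((case & exp).sum()),
        int((case & ~exp).sum()),
        int((~case & exp).sum()),
        int((~case & ~exp).sum()),
    )
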