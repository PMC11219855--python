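"""Group comparisons and bootstrap-CI regressions for cohort analyses.

Psychophysical parameters (internal-noise SD, representation
typicality) are typically non-normal across participants, so group
means are compared with the Mann-Whitney rank-sum test; linear
associations with clinical covariates use ordinary least squares with
case-resampling percentile bootstrap confidence intervals (small-sample
robust-variance corrections inflate false positives, so plain OLS is
used and significance is judged from the bootstrap CI).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = ["GroupComparison", "RegressionResult", "compare_groups", "ols_bootstrap"]


@dataclass(frozen=True)
class GroupComparison:
    mean_difference: float
    u_statistic: float
    p_value: float
    ci_low: float
    ci_high: float
    n_a: int
    n_b: int


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    r_squared: float
    t_statistic: float
    p_value: float
    n: int


def compare_groups(
    x,
    y,
    n_boot: int = 10_000,
    rng: Optional[np.random.Generator] = None,
    ci: float = 0.95,
) -> GroupComparison:
    """Rank-sum comparison of two groups with a bootstrap CI on mean(x) - mean(y).

    The reported U counts (x_i > y_j) pairs (midranks for ties), so
    U = 0 when every value of ``y`` exceeds every value of ``x``.  The
    exact null distribution is used when min(n) <= 8 and the pooled data
    have no ties; otherwise the midrank normal approximation with tie
    correction.  The CI is a percentile bootstrap resampling each group
    independently.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng() if rng is None else rng

    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)

    bx = rng.choice(x, size=(n_boot, x.size), replace=True).mean(axis=1)
    by = rng.choice(y, size=(n_boot, y.size), replace=True).mean(axis=1)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(bx - by, [alpha, 1.0 - alpha])
    return GroupComparison(
        mean_difference=float(x.mean() - y.mean()),
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_a=int(x.size),
        n_b=int(y.size),
    )


def ols_bootstrap(
    x,
    y,
    n_boot: int = 10_000,
    rng: Optional[np.random.Generator] = None,
    ci: float = 0.95,
) -> RegressionResult:
    """Simple OLS of y on x with a case-resampling bootstrap CI on the slope.

    The point estimate, R^2, t and p come from the analytic fit
    (homoskedastic errors assumed); the percentile CI resamples (x, y)
    pairs with replacement.  Degenerate resamples where x has no spread
    are redrawn.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and aligned")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("x has no variation")
    rng = np.random.default_rng() if rng is None else rng

    fit = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = fit.params

    slopes = np.empty(n_boot)
    filled = 0
    while filled < n_boot:
        idx = rng.integers(0, n, size=(n_boot - filled, n))
        xb = x[idx]
        yb = y[idx]
        xc = xb - xb.mean(axis=1, keepdims=True)
        var = np.einsum("ij,ij->i", xc, xc)
        ok = var > 1e-12 * max(float(x.var()) * n, 1.0)
        cov = np.einsum("ij,ij->i", xc, yb - yb.mean(axis=1, keepdims=True))
        good = cov[ok] / var[ok]
        slopes[filled : filled + good.size] = good
        filled += good.size
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(slopes, [alpha, 1.0 - alpha])
    return RegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        ci_low=float(lo),
        ci_high=float(hi),
        r_squared=float(fit.rsquared),
        t_statistic=float(fit.tvalues[1]),
        p_value=float(fit.pvalues[1]),
        n=int(n),
    )


def read_covariates(path, id_column: str = "participant") -> pd.DataFrame:
    """Read a delimited covariate table keyed by participant id."""
    df = pd.read_csv(path)
    if id_column not in df.columns:
        raise ValueError(f"covariate table must contain a '{id_column}' column")
    return df.set_index(id_column)
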