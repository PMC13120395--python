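"""Nonparametric statistics for exposure-group comparison.

The battery mirrors standard practice for small, non-normal veterinary
cohorts: continuous variables are summarised as median [IQR] and compared
with two-sided Mann-Whitney U tests, with Cliff's delta (plus a bootstrap
percentile CI) as the effect size; binary variables use Fisher's exact
test with an odds ratio; monotone associations use Spearman's rank
correlation with an approximate CI from Fisher's z-transformation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .errors import ParameterError, ValidationError

__all__ = [
    "GroupComparison", "FisherResult", "SpearmanResult",
    "median_iqr", "mann_whitney_u", "cliffs_delta", "bootstrap_delta_ci",
    "fisher_exact_2x2", "spearman", "fisher_z_ci", "spearman_with_ci",
    "compare_groups", "correlation_matrix",
]


@dataclass
class GroupComparison:
    variable: str
    n1: int
    n2: int
    median1: float
    iqr1: float
    median2: float
    iqr2: float
    u_statistic: float
    p_value: float
    cliffs_delta: float
    delta_ci: tuple[float, float]


@dataclass
class FisherResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    or_ci: tuple[float, float]
    p_value: float
    ci_method: str = "exact"
    degenerate: bool = False  # a zero cell made the cross-product OR 0 or inf


@dataclass
class SpearmanResult:
    rho: float
    n: int
    p_value: float
    rho_ci: tuple[float, float]
    degenerate_ci: bool = False  # |rho| == 1, CI collapsed to the point


def median_iqr(values: Sequence[float]) -> tuple[float, float, float, float]:
    """Median, IQR, Q1 and Q3 with linear-interpolation quantiles."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("median_iqr of an empty sample")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q3 - q1), float(q1), float(q3)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with midrank ties.

    The p-value is exact when both samples have at most 8 observations
    and no ties occur across the pooled sample; otherwise the normal
    approximation with tie and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("mann_whitney_u requires two non-empty samples")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def cliffs_delta(x: Sequence[float], y: Sequence[float]) -> float:
    """Cliff's delta: P(X > Y) - P(X < Y), computed exactly over all pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("cliffs_delta requires two non-empty samples")
    gt = np.sum(x[:, None] > y[None, :])
    lt = np.sum(x[:, None] < y[None, :])
    return float((gt - lt) / (x.size * y.size))


def bootstrap_delta_ci(x: Sequence[float], y: Sequence[float], *,
                       reps: int = 10_000, rng_seed: int = 0,
                       level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI for Cliff's delta.

    Groups are resampled independently with replacement; the statistic is
    recomputed exactly per replicate.
    """
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(rng_seed)
    xb = x[rng.integers(0, x.size, size=(reps, x.size))]
    yb = y[rng.integers(0, y.size, size=(reps, y.size))]
    # chunk to bound the reps x n1 x n2 broadcast
    deltas = np.empty(reps)
    chunk = max(1, int(2e7 / max(1, x.size * y.size)))
    for i in range(0, reps, chunk):
        xs = xb[i:i + chunk, :, None]
        ys = yb[i:i + chunk, None, :]
        gt = (xs > ys).sum(axis=(1, 2))
        lt = (xs < ys).sum(axis=(1, 2))
        deltas[i:i + chunk] = (gt - lt) / (x.size * y.size)
    alpha = (1 - level) / 2
    lo, hi = np.percentile(deltas, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def fisher_exact_2x2(table, *, ci_method: str = "exact",
                     level: float = 0.95) -> FisherResult:
    """Fisher's exact test on a 2x2 table with an odds-ratio effect size.

    The p-value follows the probability-ordering rule (sum of tables no
    more likely than the observed one).  The OR point estimate is the
    sample cross-product ratio (a*d)/(b*c), not the conditional MLE.
    ``ci_method='exact'`` gives the exact conditional interval from the
    noncentral hypergeometric likelihood; ``'logit'`` gives the Woolf
    normal-approximation interval on the log-odds scale.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ParameterError("table must be 2x2 with non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("fisher_exact_2x2 requires positive margins")
    a, b = t[0]
    c, d = t[1]
    _, p = sps.fisher_exact(t, alternative="two-sided")
    degenerate = (b * c == 0) or (a * d == 0)
    if b * c == 0:
        point = math.inf if a * d > 0 else math.nan
    else:
        point = (a * d) / (b * c)
    if ci_method == "exact":
        res = _odds_ratio(t, kind="conditional")
        ci = res.confidence_interval(confidence_level=level)
        lo, hi = float(ci.low), float(ci.high)
    elif ci_method == "logit":
        if degenerate:
            lo, hi = 0.0, math.inf
        else:
            se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            z = sps.norm.ppf(1 - (1 - level) / 2)
            lo = point * math.exp(-z * se)
            hi = point * math.exp(z * se)
    else:
        raise ParameterError(f"unknown ci_method {ci_method!r}")
    return FisherResult(
        table=((int(a), int(b)), (int(c), int(d))),
        odds_ratio=float(point), or_ci=(lo, hi), p_value=float(p),
        ci_method=ci_method, degenerate=degenerate,
    )


def _exact_spearman_p(xr: np.ndarray, yr: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (small n).

    Enumerates all pairings of the (mid)rank vectors; the correlation is a
    monotone function of sum(x_perm * y), so the comparison is done on rho
    recomputed per permutation to handle ties exactly.
    """
    n = xr.size
    perms = np.array(list(itertools.permutations(range(n))))
    xp = xr[perms]  # (n!, n)
    xc = xp - xp.mean(axis=1, keepdims=True)
    yc = yr - yr.mean()
    denom = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum())
    with np.errstate(invalid="ignore"):
        rhos = (xc @ yc) / denom
    tol = 1e-12
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - tol))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman's rank correlation (Pearson on midranks) with two-sided p.

    Pairs with a missing value in either variable are dropped listwise.
    The p-value is an exact permutation probability for n <= 8 and the
    t approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValidationError("spearman requires at least 3 complete pairs")
    xr = sps.rankdata(x)
    yr = sps.rankdata(y)
    rho = float(np.corrcoef(xr, yr)[0, 1])
    if n <= 8:
        p = _exact_spearman_p(xr, yr, rho)
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return rho, p


def fisher_z_ci(rho: float, n: int, *, level: float = 0.95
                ) -> tuple[float, float]:
    """Approximate CI for a correlation via Fisher's z-transformation.

    z = atanh(rho), half-width z_crit / sqrt(n - 3), back-transformed with
    tanh.  |rho| == 1 returns the degenerate point interval.
    """
    if n < 4:
        raise ValidationError("fisher_z_ci requires n >= 4")
    if not -1 <= rho <= 1:
        raise ParameterError("rho must lie in [-1, 1]")
    if abs(rho) == 1:
        return (rho, rho)
    z = math.atanh(rho)
    hw = sps.norm.ppf(1 - (1 - level) / 2) / math.sqrt(n - 3)
    return (math.tanh(z - hw), math.tanh(z + hw))


def spearman_with_ci(x: Sequence[float], y: Sequence[float], *,
                     level: float = 0.95) -> SpearmanResult:
    """Spearman rho, two-sided p, and Fisher-z CI in one result object."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    n = int(keep.sum())
    rho, p = spearman(x, y)
    if abs(rho) == 1:
        return SpearmanResult(rho=rho, n=n, p_value=p, rho_ci=(rho, rho),
                              degenerate_ci=True)
    if n < 4:
        raise ValidationError("CI requires n >= 4 complete pairs")
    return SpearmanResult(rho=rho, n=n, p_value=p,
                          rho_ci=fisher_z_ci(rho, n, level=level))


def compare_groups(x: Sequence[float], y: Sequence[float], variable: str, *,
                   bootstrap_reps: int = 10_000, rng_seed: int = 0
                   ) -> GroupComparison:
    """Full two-group comparison: median [IQR] per group, Mann-Whitney U,
    Cliff's delta and its bootstrap CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m1, i1, _, _ = median_iqr(x)
    m2, i2, _, _ = median_iqr(y)
    u, p = mann_whitney_u(x, y)
    d = cliffs_delta(x, y)
    ci = bootstrap_delta_ci(x, y, reps=bootstrap_reps, rng_seed=rng_seed)
    return GroupComparison(variable=variable, n1=x.size, n2=y.size,
                           median1=m1, iqr1=i1, median2=m2, iqr2=i2,
                           u_statistic=u, p_value=p, cliffs_delta=d,
                           delta_ci=ci)


def correlation_matrix(df: pd.DataFrame,
                       variables: Optional[Sequence[str]] = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlation matrix on the listwise-complete subset.

    Returns ``(rho, p)`` DataFrames indexed by variable; the diagonal of
    ``rho`` is exactly 1.  Raises when fewer than 4 complete rows remain,
    naming the variables with missing data.
    """
    if variables is None:
        variables = list(df.columns)
    sub = df.loc[:, list(variables)].astype(float)
    complete = sub.dropna()
    if len(complete) < 4:
        missing = [c for c in variables if sub[c].isna().any()]
        raise ValidationError(
            f"only {len(complete)} complete cases (need >= 4); "
            f"variables with missing values: {missing}"
        )
    k = len(variables)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r, p = spearman(complete.iloc[:, i].values, complete.iloc[:, j].values)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    return (pd.DataFrame(rho, index=variables, columns=variables),
            pd.DataFrame(pval, index=variables, columns=variables))
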