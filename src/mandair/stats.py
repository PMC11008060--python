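"""Reliability and inferential statistics for the measurement pipeline.

Implements the study-level statistical layer:

* ``icc_a1`` — intraclass correlation ICC(A,1): single-rating, absolute
  agreement, two-way mixed-effects model, with the McGraw & Wong
  F-distribution 95% confidence interval;
* ``spearman_one_tailed`` — Spearman rank correlation with a directional
  one-tailed p-value: exact permutation enumeration for n <= 9, the
  t-approximation above;
* ``describe`` — median and interquartile range by linear-interpolation
  quantiles;
* thin wrappers over scipy for the conventional screening tests
  (Shapiro-Wilk, Kruskal-Wallis, Mann-Whitney U) used in cohort reports.

ICC mean squares (n subjects, k ratings): with row means r_i, column means
c_j and grand mean g,

    MSR = k * sum_i (r_i - g)^2 / (n - 1)        (between subjects)
    MSC = n * sum_j (c_j - g)^2 / (k - 1)        (between ratings)
    MSE = sum_ij (x_ij - r_i - c_j + g)^2 / ((n-1)(k-1))

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError, UndefinedStatisticError, ValidationError

log = logging.getLogger(__name__)

EXACT_PERMUTATION_MAX_N = 9


# ---------------------------------------------------------------------------
# ICC(A,1)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    n: int
    k: int
    degenerate: bool = False


def _two_way_mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    n, k = data.shape
    grand = data.mean()
    rows = data.mean(axis=1)
    cols = data.mean(axis=0)
    msr = k * np.sum((rows - grand) ** 2) / (n - 1)
    msc = n * np.sum((cols - grand) ** 2) / (k - 1)
    resid = data - rows[:, None] - cols[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_a1(data: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1): single-rating, absolute-agreement, two-way mixed model.

    ``data`` is an (n, k) matrix of n subjects by k ratings (k = 2 in the
    repeated-measurement design) with no missing cells.  The confidence
    interval is the McGraw & Wong F-based interval with Satterthwaite
    degrees of freedom.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ValidationError("repeated-measures data must be a 2D matrix")
    n, k = data.shape
    if n < 3:
        raise InsufficientDataError(f"need at least 3 subjects, got {n}")
    if k < 2:
        raise ValidationError(f"need at least 2 ratings per subject, got {k}")
    if not np.isfinite(data).all():
        raise ValidationError("missing or non-finite cells in ratings matrix")

    msr, msc, mse = _two_way_mean_squares(data)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    degenerate = denom <= 0 or msr <= 1e-12 * max(mse, msc, 1.0)
    est = (msr - mse) / denom if denom != 0 else float("nan")
    if degenerate:
        log.warning(
            "ICC degenerate: between-subject variance ~ 0 (MSR=%.3g, MSE=%.3g)",
            msr,
            mse,
        )

    # McGraw & Wong CI for ICC(A,1)
    if mse <= 0:
        # perfect agreement: interval collapses
        lo = hi = est
    else:
        r = min(max(est, -0.999999999), 0.999999999)
        a = (k * r) / (n * (1 - r))
        b = 1 + (k * r * (n - 1)) / (n * (1 - r))
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num / den if den > 0 else 1.0
        f_u = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_l = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo = (n * (msr - f_u * mse)) / (
            f_u * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = (n * (f_l * msr - mse)) / (
            k * msc + (k * n - k - n) * mse + n * f_l * msr
        )
    lo, hi = float(min(lo, est)), float(max(hi, est))
    return ICCResult(
        estimate=float(est), ci_low=lo, ci_high=hi, n=n, k=k, degenerate=degenerate
    )


# ---------------------------------------------------------------------------
# one-tailed Spearman
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_one_tailed: float
    direction: Literal["positive", "negative"]
    n: int
    method: Literal["exact", "t-approximation"]

    @property
    def significant(self) -> bool:
        return self.p_one_tailed < 0.05


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum() * (ry**2).sum()))
    if denom == 0:
        raise UndefinedStatisticError("constant vector: Spearman rho undefined")
    return float((rx * ry).sum() / denom)


def spearman_one_tailed(
    x, y, direction: Literal["positive", "negative"] = "positive"
) -> CorrelationResult:
    """Spearman rank correlation with a directional one-tailed p-value.

    Ties receive average ranks.  For n <= 9 the p-value is the exact
    permutation probability P(rho_perm >= rho_obs) (or <=, for the negative
    direction) over all n! orderings; for larger n the usual t-approximation
    t = rho sqrt((n-2)/(1-rho^2)) with n-2 degrees of freedom is used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1D vectors")
    n = len(x)
    if n < 4:
        raise InsufficientDataError(f"need n >= 4 for a correlation test, got {n}")
    if direction not in ("positive", "negative"):
        raise ValidationError(f"unknown direction {direction!r}")
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    rho = _spearman_rho(rx, ry)

    if n <= EXACT_PERMUTATION_MAX_N:
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
        # rho is an increasing affine function of sum(rx * ry_perm): compare sums
        s_obs = float(np.dot(rx, ry))
        s_perm = ry[perms] @ rx
        eps = 1e-9 * max(abs(s_obs), 1.0)
        if direction == "positive":
            p = float(np.mean(s_perm >= s_obs - eps))
        else:
            p = float(np.mean(s_perm <= s_obs + eps))
        method = "exact"
    else:
        if abs(rho) >= 1.0:
            t = math.inf if rho > 0 else -math.inf
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho**2))
        if direction == "positive":
            p = float(sps.t.sf(t, n - 2))
        else:
            p = float(sps.t.cdf(t, n - 2))
        method = "t-approximation"
    return CorrelationResult(
        rho=rho, p_one_tailed=p, direction=direction, n=n, method=method
    )


# ---------------------------------------------------------------------------
# descriptive summaries and screens
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DescriptiveSummary:
    median: float
    q1: float
    q3: float
    n: int

    def __str__(self) -> str:
        return f"{self.median:.1f} ({self.q1:.1f};{self.q3:.1f})"


def describe(values) -> DescriptiveSummary:
    """Median and IQR (25th;75th percentile, linear interpolation)."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise InsufficientDataError("cannot summarise an empty vector")
    q1, med, q3 = np.percentile(v, [25.0, 50.0, 75.0], method="linear")
    return DescriptiveSummary(median=float(med), q1=float(q1), q3=float(q3), n=v.size)


def normality_screen(values) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p-value (reporting convenience)."""
    stat, p = sps.shapiro(np.asarray(values, float))
    return float(stat), float(p)


def group_screen(values, groups) -> tuple[str, float, float]:
    """Mann-Whitney U (2 groups) or Kruskal-Wallis (>2) screen.

    Returns (test name, statistic, two-tailed p).
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    levels = [values[groups == g] for g in np.unique(groups)]
    if len(levels) < 2:
        raise ValidationError("group screen needs at least 2 groups")
    if len(levels) == 2:
        stat, p = sps.mannwhitneyu(levels[0], levels[1], alternative="two-sided")
        return "mann-whitney-u", float(stat), float(p)
    stat, p = sps.kruskal(*levels)
    return "kruskal-wallis", float(stat), float(p)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional; the default reports are uncorrected)."""
    p = np.asarray(p_values, float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj
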