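"""Reaction-time distribution statistics and LATER-style reciprobit analysis.

Implements the statistics used to summarize and compare antisaccade RT
distributions:

* per-category medians and interquartile coefficients of variation,
  CV = (Q75 - Q25) / median — a robust, scale-invariant dispersion measure;
* error rate (% of valid trials with an error-prosaccade crossing) and the
  percentage of errors subsequently corrected;
* cumulative percentile distributions on a 5%-step grid;
* the Wilcoxon signed-rank test for paired percentile distributions;
* reciprobit regression: probit of the cumulative probability against -1/RT.
  Under the LATER model (a linear rise to threshold whose rate varies
  normally across trials) RTs are recinormal, so these points fall on a
  straight line whose slope and intercept encode the rate distribution;
* a homogeneity-of-slopes/intercepts comparison of two reciprobit lines via
  pooled regression with a group-by-predictor interaction.

All quantiles (medians, quartiles, percentile grids) use the same rule:
linear interpolation between order statistics (numpy's default, "type 7").
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy import stats as sstats
from scipy.special import ndtr, ndtri

from .exceptions import DegenerateDataError, InvalidInputError
from .trial import (
    OUTCOME_ANTI,
    OUTCOME_CORRECTED,
    OUTCOME_ERROR,
    OUTCOME_NONE,
)

PERCENTILE_GRID = np.arange(5, 101, 5)


@dataclasses.dataclass(frozen=True)
class CategoryStats:
    n: int
    median_ms: float
    cv: float


@dataclasses.dataclass(frozen=True)
class RTSummary:
    """Per-category medians/CVs plus the two error-performance rates.

    Categories with zero trials are ``None`` (absent), never zero.
    """

    error_prosaccade: Optional[CategoryStats]
    antisaccade: Optional[CategoryStats]
    corrected_antisaccade: Optional[CategoryStats]
    error_rate_percent: Optional[float]
    percent_errors_corrected: Optional[float]
    n_valid_trials: int
    n_trials: int


@dataclasses.dataclass(frozen=True)
class CumulativeDistribution:
    percentiles: np.ndarray  # 5, 10, ..., 100 (%)
    rt_at_percentile: np.ndarray  # ms, non-decreasing


@dataclasses.dataclass(frozen=True)
class ReciprobitFit:
    slope: float
    intercept: float
    r: float
    n_points: int


@dataclasses.dataclass(frozen=True)
class WilcoxonResult:
    z: float
    p: float
    statistic: float  # W+ (sum of ranks of positive differences)
    n: int  # nonzero differences used


@dataclasses.dataclass(frozen=True)
class LineComparison:
    t_slope: float
    p_slope: float
    df_slope: int
    t_intercept: float
    p_intercept: float
    df_intercept: int


# ---------------------------------------------------------------------------
# category extraction and summary statistics


def category_rts(trials, category: str) -> np.ndarray:
    """RTs (ms) of one behavioral category from an iterable of TrialResults."""
    field = {
        OUTCOME_ERROR: "rt_error_ms",
        "error_prosaccade": "rt_error_ms",
        OUTCOME_ANTI: "rt_anti_ms",
        OUTCOME_CORRECTED: "rt_corrected_ms",
    }.get(category)
    if field is None:
        raise InvalidInputError(f"unknown category {category!r}")
    vals = [getattr(t, field) for t in trials]
    return np.array([v for v in vals if v is not None], dtype=float)


def coefficient_of_variation(rts) -> float:
    """Interquartile CV: (Q75 - Q25) / median, linear-interpolation quantiles."""
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise InvalidInputError("empty RT list")
    q25, med, q75 = np.quantile(rts, [0.25, 0.5, 0.75])
    if med <= 0:
        raise InvalidInputError(f"median must be > 0 for the CV, got {med}")
    return float((q75 - q25) / med)


def _category_stats(rts: np.ndarray) -> Optional[CategoryStats]:
    if rts.size == 0:
        return None
    med = float(np.median(rts))
    # a non-positive median can only arise far off calibration (inter-crossing
    # intervals with the wrong sign); the CV is undefined there
    cv = coefficient_of_variation(rts) if med > 0 else float("nan")
    return CategoryStats(n=int(rts.size), median_ms=med, cv=cv)


def summarize(ensemble) -> RTSummary:
    """Table-1/Table-2 style summary of one ensemble.

    Error rate = 100 * (trials with an error crossing) / (valid trials),
    where valid trials are those with at least one threshold crossing;
    no-response trials enter neither rates nor RT statistics.
    """
    trials = getattr(ensemble, "trials", ensemble)
    if len(trials) == 0:
        raise InvalidInputError("ensemble has no trials")
    n_error = sum(1 for t in trials if t.rt_error_ms is not None)
    n_corrected = sum(1 for t in trials if t.outcome == OUTCOME_CORRECTED)
    n_valid = sum(1 for t in trials if t.outcome != OUTCOME_NONE)
    error_rate = 100.0 * n_error / n_valid if n_valid else None
    pct_corrected = 100.0 * n_corrected / n_error if n_error else None
    return RTSummary(
        error_prosaccade=_category_stats(category_rts(trials, OUTCOME_ERROR)),
        antisaccade=_category_stats(category_rts(trials, OUTCOME_ANTI)),
        corrected_antisaccade=_category_stats(category_rts(trials, OUTCOME_CORRECTED)),
        error_rate_percent=error_rate,
        percent_errors_corrected=pct_corrected,
        n_valid_trials=n_valid,
        n_trials=len(trials),
    )


def cumulative_distribution(rts) -> CumulativeDistribution:
    """RT at each percentile of the 5%-step grid (ascending-order construction)."""
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise InvalidInputError("empty RT list")
    q = np.quantile(rts, PERCENTILE_GRID / 100.0)
    return CumulativeDistribution(percentiles=PERCENTILE_GRID.copy(), rt_at_percentile=q)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test

_EXACT_N_MAX = 12


def wilcoxon_signed_rank(paired_a, paired_b) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are discarded; ties get midranks.  For n <= 12 nonzero
    differences the two-sided p is computed by exact enumeration over all 2^n
    sign assignments (valid with midranks); above that, a normal
    approximation with tie and continuity corrections is used.  The z
    statistic is always reported from the normal approximation, signed so
    that a > b gives z > 0.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError("paired samples must be equal-length 1-D arrays")
    if a.size < 5:
        raise InvalidInputError(f"need at least 5 pairs, got {a.size}")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = sstats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = n * (n + 1) / 2.0
    mu = total / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        raise DegenerateDataError("zero variance in signed ranks")
    delta = w_plus - mu
    z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var)
    if n <= _EXACT_N_MAX:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        p = float(2.0 * (1.0 - ndtr(abs(z))))
    return WilcoxonResult(z=float(z), p=min(1.0, float(p)), statistic=w_plus, n=n)


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p over all sign assignments of the given (mid)ranks."""
    # doubled ranks are integers even with .5 midranks
    r2 = np.rint(2 * ranks).astype(int)
    dist: dict[int, float] = {0: 1.0}
    for r in r2:
        new: dict[int, float] = {}
        for s, c in dist.items():
            for v in (s, s + r):
                new[v] = new.get(v, 0.0) + c
        dist = new
    total2 = int(r2.sum())
    w2 = int(round(2 * w_plus))
    w_small = min(w2, total2 - w2)
    w_large = total2 - w_small
    n_all = 2.0 ** len(r2)
    p = (
        sum(c for s, c in dist.items() if s <= w_small)
        + sum(c for s, c in dist.items() if s >= w_large)
    ) / n_all
    return p


# ---------------------------------------------------------------------------
# reciprobit regression


def reciprobit_points(dist: CumulativeDistribution):
    """Usable (x, y) points: x = -1/RT, y = probit(percentile/100).

    Grid points whose probit is infinite (0% or 100%) are excluded.
    """
    p = np.asarray(dist.percentiles, dtype=float)
    rt = np.asarray(dist.rt_at_percentile, dtype=float)
    mask = (p > 0) & (p < 100)
    x = -1.0 / rt[mask]
    y = ndtri(p[mask] / 100.0)
    return x, y


def reciprobit_fit(dist: CumulativeDistribution) -> ReciprobitFit:
    """OLS of probit cumulative probability on -1/RT.

    For recinormal RTs (1/RT ~ Normal(m, s)) the points are exactly linear
    with slope 1/s and intercept -m/s; the fitted median is slope/intercept
    evaluated at probit 0, i.e. RT_50 = slope/intercept.
    """
    x, y = reciprobit_points(dist)
    if x.size < 3:
        raise InvalidInputError(
            f"need at least 3 usable percentile points, got {x.size}"
        )
    res = sstats.linregress(x, y)
    return ReciprobitFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        n_points=int(x.size),
    )


def fitted_median_ms(fit: ReciprobitFit) -> float:
    """RT at the 50th percentile implied by a reciprobit line.

    probit = 0 at x = -intercept/slope and x = -1/RT, hence RT = slope/intercept.
    """
    if fit.intercept == 0:
        raise InvalidInputError("degenerate fit: zero intercept")
    return fit.slope / fit.intercept


def _t_with_guard(coef: float, se: float, df: int, tiny: float = 1e-12):
    """t = coef/se with 0/0 -> 0 and x/0 -> +/-inf (zero-residual fits)."""
    if se < tiny:
        if abs(coef) < tiny:
            return 0.0, 1.0
        return float(np.sign(coef) * np.inf), 0.0
    t = coef / se
    p = float(2 * sstats.t.sf(abs(t), df)) if df > 0 else float("nan")
    return float(t), p


def compare_lines(points_a, points_b) -> LineComparison:
    """Homogeneity-of-slopes/intercepts test for two fitted lines.

    ``points_a``/``points_b`` are (x, y) pairs of arrays.  A pooled OLS with
    a group-by-predictor interaction gives the slope-equality t (df = n - 4);
    assuming equal slopes, the group main effect in the reduced model gives
    the intercept-equality t (df = n - 3).
    """
    import statsmodels.api as sm

    xa, ya = (np.asarray(v, dtype=float) for v in points_a)
    xb, yb = (np.asarray(v, dtype=float) for v in points_b)
    if xa.size < 3 or xb.size < 3:
        raise InvalidInputError("each point set needs at least 3 points")
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise InvalidInputError("zero-variance predictor")
    x = np.concatenate([xa, xb])
    y = np.concatenate([ya, yb])
    g = np.concatenate([np.zeros(xa.size), np.ones(xb.size)])
    n = x.size
    X_full = np.column_stack([np.ones(n), x, g, g * x])
    fit_full = sm.OLS(y, X_full).fit()
    t_slope, p_slope = _t_with_guard(fit_full.params[3], fit_full.bse[3], n - 4)
    X_red = np.column_stack([np.ones(n), x, g])
    fit_red = sm.OLS(y, X_red).fit()
    t_int, p_int = _t_with_guard(fit_red.params[2], fit_red.bse[2], n - 3)
    return LineComparison(
        t_slope=t_slope,
        p_slope=p_slope,
        df_slope=n - 4,
        t_intercept=t_int,
        p_intercept=p_int,
        df_intercept=n - 3,
    )
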