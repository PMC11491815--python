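"""Group comparisons, correlation and a diel trend smoother.

Mirrors the comparison layer of a small biologging study: Welch
two-sample t-tests on (optionally arcsine-square-root transformed)
metrics between sexes, paired t-tests within breeding pairs, one-way
ANOVA across brood sizes, a Pearson correlation / least-squares line of
flight effort against weight-normalized wing area, and a tricube local
linear (loess-style) smooth of flight proportion over time of day with
a pointwise confidence band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .metrics import BirdSummary


@dataclass(frozen=True)
class ComparisonResult:
    """One statistical test: statistic, df, p and per-group summaries."""

    test_name: str
    statistic: float
    degrees_of_freedom: float
    p_value: float
    group_summaries: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


def arcsine_sqrt(p) -> np.ndarray | float:
    """Variance-stabilising transform for proportions: asin(sqrt(p))."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) else out


def _resolve_transform(transform):
    if transform is None:
        return lambda x: np.asarray(x, dtype=float)
    if transform == "arcsine":
        return lambda x: np.asarray(arcsine_sqrt(np.asarray(x, dtype=float)))
    if callable(transform):
        return transform
    raise ValueError(f"unknown transform {transform!r}")


def _metric_values(summaries: list[BirdSummary], metric: str) -> np.ndarray:
    values = []
    for s in summaries:
        v = getattr(s, metric)
        if v is None:
            raise ValueError(f"{s.bird_id} has no value for {metric}")
        values.append(float(v))
    return np.array(values)


def _summary(x: np.ndarray) -> dict:
    return {"n": len(x), "mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0}


def welch_ttest(x, y, pooled: bool = False) -> ComparisonResult:
    """Two-sample t-test; Welch (unequal variances, fractional df) by
    default, classical pooled-variance form as an option."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need at least 2 observations")
    name = "pooled t-test" if pooled else "Welch t-test"
    if np.var(x) == 0 and np.var(y) == 0 and np.mean(x) == np.mean(y):
        # identical degenerate groups: no evidence of a difference
        return ComparisonResult(name, 0.0, float(len(x) + len(y) - 2), 1.0,
                                {"a": _summary(x), "b": _summary(y)})
    res = sps.ttest_ind(x, y, equal_var=pooled)
    return ComparisonResult(
        test_name=name,
        statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
        group_summaries={"a": _summary(x), "b": _summary(y)},
    )


def compare_sexes(
    summaries: list[BirdSummary], metric: str, transform=None, pooled: bool = False
) -> ComparisonResult:
    """Welch t-test of a per-bird metric between females and males."""
    f = [s for s in summaries if s.sex == "female"]
    m = [s for s in summaries if s.sex == "male"]
    if len(f) < 2 or len(m) < 2:
        raise ValueError("need at least 2 birds of each sex")
    tf = _resolve_transform(transform)
    res = welch_ttest(tf(_metric_values(f, metric)), tf(_metric_values(m, metric)), pooled=pooled)
    return ComparisonResult(
        test_name=res.test_name,
        statistic=res.statistic,
        degrees_of_freedom=res.degrees_of_freedom,
        p_value=res.p_value,
        group_summaries={
            "female": _summary(_metric_values(f, metric)),
            "male": _summary(_metric_values(m, metric)),
        },
        extra={"metric": metric, "transform": transform},
    )


def compare_pairs(
    pairs: list[tuple[BirdSummary, BirdSummary]], metric: str, transform=None
) -> ComparisonResult:
    """Paired t-test on within-pair (female - male) differences; df = n - 1."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 complete pairs")
    tf = _resolve_transform(transform)
    females, males = zip(*pairs)
    for f, m in pairs:
        if f.sex == m.sex:
            raise ValueError(f"pair ({f.bird_id}, {m.bird_id}) is not a female/male pair")
    fx = tf(_metric_values(list(females), metric))
    mx = tf(_metric_values(list(males), metric))
    diffs = fx - mx
    extra = {"metric": metric, "transform": transform}
    if np.std(diffs, ddof=1) == 0:
        extra["degenerate"] = True
        stat = math.inf * np.sign(diffs.mean()) if diffs.mean() != 0 else 0.0
        p = 1.0 if diffs.mean() == 0 else 0.0
    else:
        res = sps.ttest_rel(fx, mx)
        stat, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        test_name="paired t-test",
        statistic=float(stat),
        degrees_of_freedom=float(len(pairs) - 1),
        p_value=float(p),
        group_summaries={"female": _summary(fx), "male": _summary(mx)},
        extra=extra,
    )


def brood_size_anova(summaries: list[BirdSummary], metric: str, transform=None) -> ComparisonResult:
    """One-way ANOVA with brood size as a categorical factor."""
    tf = _resolve_transform(transform)
    groups: dict[int, list[float]] = {}
    for s in summaries:
        if s.brood_size is None:
            raise ValueError(f"{s.bird_id} has no brood size")
        groups.setdefault(int(s.brood_size), []).append(float(getattr(s, metric)))
    usable = {k: tf(np.asarray(v)) for k, v in groups.items() if len(v) >= 2}
    if len(usable) < 2:
        raise ValueError("need at least 2 brood-size levels with >= 2 birds each")
    arrays = [usable[k] for k in sorted(usable)]
    res = sps.f_oneway(*arrays)
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    return ComparisonResult(
        test_name="one-way ANOVA",
        statistic=float(res.statistic),
        degrees_of_freedom=float(k - 1),
        p_value=float(res.pvalue),
        group_summaries={str(lvl): _summary(usable[lvl]) for lvl in sorted(usable)},
        extra={"metric": metric, "df_between": k - 1, "df_within": n - k},
    )


def morphology_effort_correlation(sstar, vedba_mean_bird) -> ComparisonResult:
    """Pearson correlation and least-squares line of effort on S*."""
    x = np.asarray(sstar, dtype=float)
    y = np.asarray(vedba_mean_bird, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    lr = sps.linregress(x, y)
    return ComparisonResult(
        test_name="Pearson correlation",
        statistic=float(lr.rvalue),
        degrees_of_freedom=float(len(x) - 2),
        p_value=float(lr.pvalue),
        group_summaries={"x": _summary(x), "y": _summary(y)},
        extra={
            "slope": float(lr.slope),
            "intercept": float(lr.intercept),
            "r_squared": float(lr.rvalue**2),
            "slope_stderr": float(lr.stderr),
        },
    )


# ---------------------------------------------------------------------------
# Tricube local linear smoother (loess-style) with a pointwise band
# ---------------------------------------------------------------------------


def loess(
    x,
    y,
    span: float = 0.75,
    grid=None,
    n_grid: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Locally weighted linear regression with tricube weights.

    At each grid point the ``span`` fraction of nearest observations gets
    tricube weights and a weighted straight line is fitted; returns
    ``(grid, fit, se)`` where ``se`` is the pointwise standard error of
    the fitted value (wider where data are sparse).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("all x values identical")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), n_grid)
    grid = np.asarray(grid, dtype=float)

    n = len(x)
    k = max(2, int(math.ceil(span * n)))
    fit = np.empty_like(grid)
    hat_sq = np.empty_like(grid)  # sum of squared hat weights per grid point
    resid_var = _loess_residual_variance(x, y, k)
    for j, g in enumerate(grid):
        d = np.abs(x - g)
        h = np.sort(d)[k - 1]
        h = h if h > 0 else 1e-12
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        fit[j], hat = _weighted_line_at(x, y, w, g)
        hat_sq[j] = float((hat**2).sum())
    se = np.sqrt(resid_var * hat_sq)
    return grid, fit, se


def _weighted_line_at(x, y, w, x0) -> tuple[float, np.ndarray]:
    """WLS line through (x, y, w) evaluated at x0; returns the fitted
    value and the hat (equivalent-kernel) weights."""
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    if sxx <= 1e-14:
        hat = w / sw
        return ym, hat
    slope_w = w * (x - xm) / sxx
    hat = w / sw + (x0 - xm) * slope_w
    return float((hat * y).sum()), hat


def _loess_residual_variance(x, y, k) -> float:
    """Residual variance from local fits evaluated at the data points."""
    n = len(x)
    resid = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        h = np.sort(d)[k - 1]
        h = h if h > 0 else 1e-12
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        fit_i, _ = _weighted_line_at(x, y, w, x[i])
        resid[i] = y[i] - fit_i
    dof = max(n - 4, 1)
    return float((resid**2).sum() / dof)


def time_of_day_trend(
    summaries: list[BirdSummary],
    metric: str = "r_flight",
    span: float = 0.75,
    grid=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smooth diel trend of a per-bird metric over tagging time.

    Returns ``(hour_grid, fit, se)``; needs >= 8 birds with tag hours.
    """
    pts = [(s.tag_hour, getattr(s, metric)) for s in summaries
           if s.tag_hour is not None and getattr(s, metric) is not None]
    if len(pts) < 8:
        raise ValueError("need at least 8 birds with tagging times")
    hours = np.array([p[0] for p in pts])
    values = np.array([p[1] for p in pts])
    return loess(hours, values, span=span, grid=grid)
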