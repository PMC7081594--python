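"""Cross-condition statistics for plate-assay studies.

Covers the analyses used to evaluate substrate and interlab comparability:
OLS regression of paired group means with a 95% mean-response confidence
band (substrate-correlation plots), one-way ANOVA and Tukey–Kramer HSD for
group comparisons, and a Shapiro–Wilk normality report.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import DegenerateDataError, InsufficientDataError, ValidationError

__all__ = [
    "RegressionFit",
    "paired_mean_regression",
    "one_way_anova",
    "AnovaResult",
    "pairwise_q",
    "tukey_hsd",
    "shapiro_wilk_report",
]


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of paired group means with a 95% confidence band.

    The band is the mean-response confidence interval from standard OLS
    theory with n - 2 degrees of freedom, evaluated on ``band_x``; the x/y
    SDs are carried for plotting error bars only and do not enter the fit.
    """

    slope: float
    intercept: float
    r_squared: float
    n: int
    x: np.ndarray
    y: np.ndarray
    x_sd: np.ndarray | None
    y_sd: np.ndarray | None
    band_x: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray
    slope_stderr: float

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def paired_mean_regression(
    x_means,
    y_means,
    x_sd=None,
    y_sd=None,
    band_points: int = 100,
    alpha: float = 0.05,
) -> RegressionFit:
    """Regress y-group means on x-group means (one point per group).

    Group-level means — e.g. mean rate on a reference substrate (x) versus
    a widely-available one (y), one point per organism or per (lab,
    organism) — are fitted by OLS with intercept. ``r_squared`` is the
    squared Pearson correlation of the means.
    """
    x = np.asarray(x_means, dtype=float)
    y = np.asarray(y_means, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x_means and y_means must be 1-D and equal length")
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 paired means, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("zero variance in x means: slope undefined")

    model = sm.OLS(y, sm.add_constant(x)).fit()
    grid = np.linspace(x.min(), x.max(), band_points)
    pred = model.get_prediction(sm.add_constant(grid))
    band = pred.conf_int(alpha=alpha)  # mean-response CI, t with n-2 df
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        n=int(x.size),
        x=x,
        y=y,
        x_sd=None if x_sd is None else np.asarray(x_sd, dtype=float),
        y_sd=None if y_sd is None else np.asarray(y_sd, dtype=float),
        band_x=grid,
        band_lower=band[:, 0],
        band_upper=band[:, 1],
        slope_stderr=float(model.bse[1]),
    )


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    degenerate: bool = False  # within-SS was zero; F/p are the documented sentinel


def _check_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise InsufficientDataError(f"need >= 2 groups, got {len(gs)}")
    for i, g in enumerate(gs):
        if g.size < 2:
            raise InsufficientDataError(f"group {i} has n={g.size} < 2")
    return gs


def one_way_anova(groups) -> AnovaResult:
    """Standard one-way between/within decomposition.

    When the within-group sum of squares is exactly zero (constant groups)
    the result is the documented sentinel F = +inf, p = 0.0 with
    ``degenerate=True`` rather than an exception.
    """
    gs = _check_groups(groups)
    all_v = np.concatenate(gs)
    grand = all_v.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_between = len(gs) - 1
    df_within = all_v.size - len(gs)
    if ss_within == 0:
        return AnovaResult(np.inf, 0.0, df_between, df_within, degenerate=True)
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return AnovaResult(float(f), p, df_between, df_within)


def pairwise_q(groups) -> tuple[np.ndarray, np.ndarray, int]:
    """Tukey–Kramer studentized-range statistics for all group pairs.

    Returns ``(q, mean_diff, df_within)`` with one entry per unordered pair
    in ``itertools.combinations`` order. The rejection decision
    ``q > studentized_range.ppf(1 - alpha, k, df)`` is identical to
    ``p_adj < alpha`` (the survival function is strictly decreasing), which
    is what large null simulations should use: one ppf call instead of one
    sf call per pair.
    """
    gs = _check_groups(groups)
    k = len(gs)
    df_within = sum(g.size for g in gs) - k
    msw = sum(((g - g.mean()) ** 2).sum() for g in gs) / df_within
    if msw == 0:
        raise DegenerateDataError("zero within-group variance: q undefined")
    qs, diffs = [], []
    for i, j in itertools.combinations(range(k), 2):
        diff = gs[j].mean() - gs[i].mean()
        se = np.sqrt((msw / 2.0) * (1.0 / gs[i].size + 1.0 / gs[j].size))
        qs.append(abs(diff) / se)
        diffs.append(diff)
    return np.array(qs), np.array(diffs), df_within


def tukey_hsd(groups, alpha: float = 0.05, labels=None) -> pd.DataFrame:
    """Tukey–Kramer honestly-significant-difference pairwise comparisons.

    For groups i, j with means m and sizes n, the studentized-range
    statistic is ``q = |m_i - m_j| / sqrt((MSW / 2) (1/n_i + 1/n_j))`` with
    MSW the pooled within-group mean square; the adjusted p-value comes
    from the studentized range distribution with (k, N - k) parameters,
    which controls the familywise error rate over all k(k-1)/2 pairs.

    Returns a DataFrame with one row per unordered pair: ``group_a,
    group_b, mean_diff, q, p_adj, reject``.
    """
    gs = _check_groups(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(len(gs))]
    if len(labels) != len(gs):
        raise ValidationError("labels length must match number of groups")
    k = len(gs)
    qs, diffs, df_within = pairwise_q(gs)
    rows = []
    for (i, j), q, diff in zip(itertools.combinations(range(k), 2), qs, diffs):
        p = float(np.clip(sps.studentized_range.sf(q, k, df_within), 0.0, 1.0))
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_diff": float(diff),
                "q": float(q),
                "p_adj": p,
                "reject": p < alpha,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["alpha"] = alpha
    table.attrs["df_within"] = df_within
    return table


def shapiro_wilk_report(values) -> tuple[float, float]:
    """Shapiro–Wilk W and p for 3 <= n <= 5000.

    Reported for transparency only; no downstream analysis is gated on it.
    """
    v = np.asarray(values, dtype=float)
    if not (3 <= v.size <= 5000):
        raise InsufficientDataError(
            f"Shapiro-Wilk defined for 3 <= n <= 5000, got n={v.size}"
        )
    if np.ptp(v) == 0:
        raise DegenerateDataError("constant sample: W undefined (zero variance)")
    w, p = sps.shapiro(v)
    return float(w), float(p)
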