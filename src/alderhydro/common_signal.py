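"""Shared high-frequency growth variation and its monthly climate correlates.

A PCA across the detrended tree-ring series (series as variables, years as
observations) separates regional from site-specific growth signals: the
component scores trace common growth variation, the loadings tie
individual trees to it.  Scores are then correlated with monthly
temperature, precipitation or SPEI over the 17-month window from May of
the previous year through September of the current year — the standard
dendroclimatological correlation function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.decomposition import PCA

from .chronology import IndexSeries, SiteChronology, _index_matrix

__all__ = [
    "PCAResult",
    "CorrelationFunction",
    "pca_trees",
    "monthly_correlations",
    "cross_site_correlation",
    "CORRELATION_WINDOW",
]

# (year offset, calendar month): previous May ... current September
CORRELATION_WINDOW: tuple[tuple[int, int], ...] = tuple(
    [(-1, m) for m in range(5, 13)] + [(0, m) for m in range(1, 10)]
)


@dataclass
class PCAResult:
    """Scores (years x components), loadings (series x components) and
    explained-variance fractions of a tree-ring PCA."""

    period: tuple[int, int]
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance: np.ndarray

    def score(self, component: int = 1) -> pd.Series:
        return self.scores[f"PC{component}"]


@dataclass
class CorrelationFunction:
    """Monthly correlation function of annual scores with a climate variable."""

    variable: str
    months: list[str]
    r: np.ndarray
    p: np.ndarray
    significant: np.ndarray  # p < alpha flags
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"month": self.months, "r": self.r, "p": self.p, "significant": self.significant}
        )


def pca_trees(
    index_series_list: Sequence[IndexSeries] | pd.DataFrame,
    period: tuple[int, int],
    scale: bool = True,
    n_components: int | None = None,
) -> PCAResult:
    """PCA of the series-by-year matrix over a complete common period.

    Series are centered and (by default) scaled to unit variance —
    correlation PCA, the dendro convention.  Every series must be complete
    over ``period``; offenders are listed in the error.
    """
    mat = index_series_list if isinstance(index_series_list, pd.DataFrame) else _index_matrix(
        index_series_list
    )
    lo, hi = period
    mat = mat.loc[(mat.index >= lo) & (mat.index <= hi)]
    if len(mat) < hi - lo + 1:
        raise ValueError(f"period {period} not fully covered by the year grid")
    incomplete = mat.columns[mat.isna().any()].tolist()
    if incomplete:
        raise ValueError(f"series incomplete over {period}: {incomplete}")
    if mat.shape[1] < 3:
        raise ValueError("need at least three series for a PCA")
    x = mat.to_numpy(float)
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance series cannot be scaled")
        x = x / sd
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        period=period,
        scores=pd.DataFrame(scores, index=mat.index, columns=cols),
        loadings=pd.DataFrame(pca.components_.T, index=mat.columns, columns=cols),
        explained_variance=pca.explained_variance_ratio_,
    )


_MONTH_ABBR = ["Jan", "Feb", "Mar", "Apr", "May", "Jun", "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]


def monthly_correlations(
    scores: pd.Series,
    monthly: pd.Series,
    variable: str,
    window: Sequence[tuple[int, int]] = CORRELATION_WINDOW,
    alpha: float = 0.05,
) -> CorrelationFunction:
    """Pearson correlations of annual scores with single calendar months.

    For each (offset, month) in ``window`` the score of year t is paired
    with the monthly value of year t+offset; significance is a per-month
    two-sided test at ``alpha`` with no multiple-testing correction.
    """
    if not isinstance(monthly.index, pd.PeriodIndex):
        raise TypeError("monthly series must carry a monthly PeriodIndex")
    years = scores.index.to_numpy(int)
    labels, rs, ps = [], [], []
    for offset, month in window:
        idx = pd.PeriodIndex.from_fields(year=years + offset, month=np.full_like(years, month), freq="M")
        vals = monthly.reindex(idx).to_numpy(float)
        mask = np.isfinite(vals) & np.isfinite(scores.to_numpy(float))
        if mask.sum() < 10:
            raise ValueError(
                f"fewer than 10 overlapping years for month {month} offset {offset}"
            )
        r, p = pearsonr(scores.to_numpy(float)[mask], vals[mask])
        labels.append(f"{'prev' if offset else 'cur'} {_MONTH_ABBR[month - 1]}")
        rs.append(r)
        ps.append(p)
    rs_arr, ps_arr = np.asarray(rs), np.asarray(ps)
    return CorrelationFunction(
        variable=variable, months=labels, r=rs_arr, p=ps_arr,
        significant=ps_arr < alpha, alpha=alpha,
    )


def cross_site_correlation(
    chronologies: Mapping[str, SiteChronology | pd.Series],
    period: tuple[int, int],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations (and p-values) between site chronologies."""
    series = {
        k: (v.to_series() if isinstance(v, SiteChronology) else v) for k, v in chronologies.items()
    }
    lo, hi = period
    names = list(series)
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    p = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            joined = pd.concat([series[a].loc[lo:hi], series[b].loc[lo:hi]], axis=1).dropna()
            if len(joined) < 10:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            rr, pp = pearsonr(joined.iloc[:, 0], joined.iloc[:, 1])
            r.loc[a, b] = r.loc[b, a] = rr
            p.loc[a, b] = p.loc[b, a] = pp
    return r, p
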