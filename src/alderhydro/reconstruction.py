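"""Lagged linear lake/groundwater-level reconstruction from tree rings and SPEI.

Water level in water year t is regressed on ring-width indices of years t
and t+1 (the lag admits delayed growth responses) or on the water-year
mean of a single SPEI accumulation scale (12-72 months).  Candidate
models within each predictor pool are ranked by calibration R²;
reconstructions are issued only for the contiguous year range where the
chronology rests on at least 10 trees and a running 30-year EPS of at
least 0.85.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .chronology import SiteChronology
from .climate_spei import SPEISeries, WaterYearSeries, water_year_mean

logger = logging.getLogger(__name__)

__all__ = [
    "LinearReconModel",
    "ReconstructionWindow",
    "RWI_POOL",
    "build_predictor_table",
    "fit_ols",
    "select_best",
    "reconstruction_window",
    "predict",
    "verify",
    "write_model",
]

RWI_POOL = (("rwi_t",), ("rwi_t1",), ("rwi_t", "rwi_t1"))


@dataclass
class LinearReconModel:
    """OLS reconstruction model: target_t = intercept + sum coef_i * x_{i,t}."""

    target: str
    predictors: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    calibration_period: tuple[int, int]
    r2: float
    p_value: float
    nobs: int

    @property
    def max_order(self) -> float:
        """Largest lag/scale among predictors (tie-break key: rwi_t=0,
        rwi_t1=1, spei_k=k/12 years)."""
        orders = []
        for p in self.predictors:
            if p == "rwi_t":
                orders.append(0.0)
            elif p == "rwi_t1":
                orders.append(1.0)
            elif p.startswith("spei_"):
                orders.append(int(p.split("_")[1]) / 12.0)
            else:
                orders.append(0.0)
        return max(orders)


@dataclass
class ReconstructionWindow:
    """Contiguous year range where the chronology passes both reliability gates."""

    first_year: int
    last_year: int
    min_trees: int = 10
    eps_threshold: float = 0.85
    eps_window: int = 30

    def __len__(self) -> int:
        return self.last_year - self.first_year + 1

    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)


def build_predictor_table(
    chronology: SiteChronology,
    spei_set: Mapping[int, SPEISeries | WaterYearSeries],
    target: WaterYearSeries,
    min_rows: int = 15,
) -> pd.DataFrame:
    """Annual table of target, rwi_t, rwi_t1 and water-year SPEI means.

    One row per water year t; rows with any missing value are dropped (and
    counted in the log).  The chronology enters at calendar-year
    resolution: rwi_t1 for year t is the chronology value of year t+1.
    """
    chron = chronology.to_series()
    cols: dict[str, pd.Series] = {
        "target": target.values(complete_only=True),
        "rwi_t": chron,
        "rwi_t1": pd.Series(chron.to_numpy(), index=chron.index - 1),
    }
    for k in sorted(spei_set):
        s = spei_set[k]
        wy = water_year_mean(s) if isinstance(s, SPEISeries) else s
        cols[f"spei_{k}"] = wy.values(complete_only=True)
    table = pd.DataFrame(cols)
    n_all = len(table)
    table = table.dropna()
    logger.info("predictor table: %d rows kept, %d dropped", len(table), n_all - len(table))
    if len(table) < min_rows:
        raise ValueError(
            f"only {len(table)} complete water years; need {min_rows} for a stable fit"
        )
    table.index.name = "water_year"
    return table


def fit_ols(
    table: pd.DataFrame,
    predictor_subset: Sequence[str],
    target: str = "target",
) -> LinearReconModel:
    """Ordinary least squares with intercept; plain R² and F-test p-value."""
    predictors = tuple(predictor_subset)
    missing = [p for p in predictors if p not in table.columns]
    if missing:
        raise ValueError(f"predictors not in table: {missing}")
    x = sm.add_constant(table[list(predictors)].to_numpy(float))
    if np.linalg.cond(x) > 1e8:
        raise ValueError(f"collinear predictors {predictors} (condition number > 1e8)")
    y = table[target].to_numpy(float)
    res = sm.OLS(y, x).fit()
    years = table.index.to_numpy(int)
    return LinearReconModel(
        target=target,
        predictors=predictors,
        intercept=float(res.params[0]),
        coefficients={p: float(b) for p, b in zip(predictors, res.params[1:])},
        calibration_period=(int(years.min()), int(years.max())),
        r2=float(res.rsquared),
        p_value=float(res.f_pvalue),
        nobs=int(res.nobs),
    )


def select_best(models: Sequence[LinearReconModel], tol: float = 1e-9) -> LinearReconModel:
    """Highest calibration R²; ties go to fewer predictors, then to the
    smaller maximum lag/scale."""
    if not models:
        raise ValueError("empty candidate pool")
    best_r2 = max(m.r2 for m in models)
    contenders = [m for m in models if m.r2 >= best_r2 - tol]
    return min(contenders, key=lambda m: (len(m.predictors), m.max_order))


def reconstruction_window(
    chronology: SiteChronology,
    min_trees: int = 10,
    eps_threshold: float = 0.85,
) -> ReconstructionWindow | None:
    """Maximal contiguous run of years with depth >= min_trees and running
    EPS >= eps_threshold; None when no year qualifies."""
    ok = (chronology.sample_depth >= min_trees) & (
        np.nan_to_num(chronology.running_eps, nan=-np.inf) >= eps_threshold
    )
    years = chronology.years
    best: tuple[int, int] | None = None
    start = None
    for i, flag in enumerate(np.append(ok, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if best is None or i - start > best[1] - best[0] + 1:
                best = (int(years[start]), int(years[i - 1]))
            start = None
    if best is None:
        return None
    return ReconstructionWindow(best[0], best[1], min_trees, eps_threshold)


def predict(
    model: LinearReconModel,
    predictors: pd.DataFrame | Mapping[str, pd.Series],
    window: ReconstructionWindow | None = None,
) -> pd.Series:
    """Apply the model: y_t = intercept + sum coef_i * x_{i,t}.

    Restricted to ``window`` when given; years with a missing predictor
    yield NaN gaps (logged).
    """
    frame = predictors if isinstance(predictors, pd.DataFrame) else pd.DataFrame(dict(predictors))
    if window is not None:
        frame = frame.loc[(frame.index >= window.first_year) & (frame.index <= window.last_year)]
    y = pd.Series(model.intercept, index=frame.index, dtype=float)
    for p, b in model.coefficients.items():
        if p not in frame.columns:
            raise ValueError(f"predictor {p!r} absent from input")
        y = y + b * frame[p].astype(float)
    n_gaps = int(y.isna().sum())
    if n_gaps:
        logger.warning("prediction has %d gap years (missing predictors)", n_gaps)
    return y.rename(f"reconstructed_{model.target}")


def verify(
    model: LinearReconModel,
    table: pd.DataFrame,
    holdout_fraction: float = 0.25,
    target: str = "target",
) -> dict[str, float] | None:
    """Split-sample verification: refit on the early part, score the late part.

    Returns calibration R², holdout R² (1 - SSE/SST about the holdout
    mean, may be negative) and the reduction of error (RE, about the
    calibration mean).  None with a warning when the holdout is < 5 rows.
    """
    if len(table) < 20:
        raise ValueError("need at least 20 rows for split-sample verification")
    n_hold = int(round(holdout_fraction * len(table)))
    if n_hold < 5:
        logger.warning("holdout of %d rows too small; verification skipped", n_hold)
        return None
    calib, hold = table.iloc[:-n_hold], table.iloc[-n_hold:]
    refit = fit_ols(calib, model.predictors, target=target)
    pred = predict(refit, hold)
    obs = hold[target].astype(float)
    sse = float(((obs - pred) ** 2).sum())
    sst_hold = float(((obs - obs.mean()) ** 2).sum())
    sst_calib = float(((obs - calib[target].mean()) ** 2).sum())
    return {
        "calibration_r2": refit.r2,
        "holdout_r2": 1.0 - sse / sst_hold,
        "reduction_of_error": 1.0 - sse / sst_calib,
        "n_holdout": float(n_hold),
    }


def write_model(model: LinearReconModel, path: str | Path) -> None:
    """Serialize a model to a small key-value text file."""
    lines = [
        f"target = {model.target}",
        f"predictors = {','.join(model.predictors)}",
        f"intercept = {model.intercept!r}",
    ]
    for p, b in model.coefficients.items():
        lines.append(f"coef_{p} = {b!r}")
    lines += [
        f"calibration_period = {model.calibration_period[0]}-{model.calibration_period[1]}",
        f"r2 = {model.r2:.4f}",
        f"p_value = {model.p_value:.3e}",
        f"nobs = {model.nobs}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
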