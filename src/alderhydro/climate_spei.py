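"""Thornthwaite PET, climatic water balance, and multi-scale SPEI.

The Standardized Precipitation-Evapotranspiration Index (SPEI) transforms
the k-month cumulative water balance D = P - PET into a standard-normal
deviate.  Following the reference formulation, a three-parameter
log-logistic distribution is fitted by unbiased probability-weighted
moments (PWM) separately for each calendar month, which removes
seasonality from the index; SPEI = Phi^-1(F(x)) with F the fitted CDF.

Potential evapotranspiration uses the classic Thornthwaite (1948) monthly
method: temperature plus a day-length correction derived from latitude and
mid-month solar declination.  Water years run October (previous calendar
year) through September (current year).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn
from scipy.stats import fisk, norm

from .ringwidth_io import HydroSeries, MonthlyClimate

__all__ = [
    "SPEISeries",
    "WaterYearSeries",
    "LogLogisticParams",
    "thornthwaite_pet",
    "water_balance",
    "accumulate",
    "fit_loglogistic_pwm",
    "spei",
    "water_year_mean",
    "water_year_of",
]

SPEI_SCALES = (6, 12, 24, 36, 48, 60, 72)

# civil month lengths; February as the Julian-mean 28.25 days
_MONTH_DAYS = np.array([31.0, 28.25, 31.0, 30.0, 31.0, 30.0, 31.0, 31.0, 30.0, 31.0, 30.0, 31.0])
_MID_MONTH_DOY = np.concatenate(([0.0], np.cumsum(_MONTH_DAYS)))[:-1] + _MONTH_DAYS / 2.0


@dataclass
class SPEISeries:
    """SPEI at accumulation scale ``scale_k`` months, as (year, month, value)."""

    site_id: str
    scale_k: int
    data: pd.DataFrame  # columns: year, month, value
    calibration_period: tuple[int, int]

    def values(self) -> pd.Series:
        idx = pd.PeriodIndex.from_fields(year=self.data["year"], month=self.data["month"], freq="M")
        return pd.Series(self.data["value"].to_numpy(float), index=idx)


@dataclass
class WaterYearSeries:
    """Water-year means of a monthly series.

    Water year t spans October of calendar year t-1 through September of t.
    ``data`` has columns water_year, value, n_months, complete; incomplete
    years (fewer than ``min_months`` months) are flagged, not dropped.
    """

    site_id: str
    variable: str
    data: pd.DataFrame

    def values(self, complete_only: bool = True) -> pd.Series:
        df = self.data
        if complete_only:
            df = df[df["complete"]]
        return pd.Series(df["value"].to_numpy(float), index=df["water_year"].to_numpy(int))


def _day_length_hours(latitude_deg: float, month: np.ndarray) -> np.ndarray:
    """Mean day length (h) at mid-month via the standard solar-declination approximation."""
    doy = _MID_MONTH_DOY[month - 1]
    decl = 0.4093 * np.sin(2.0 * np.pi * doy / 365.0 - 1.405)
    phi = np.deg2rad(latitude_deg)
    cos_omega = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    return 24.0 / np.pi * np.arccos(cos_omega)


def thornthwaite_pet(climate: MonthlyClimate, latitude_deg: float) -> pd.Series:
    """Monthly potential evapotranspiration (mm), classic Thornthwaite method.

    The annual heat index I is computed from the record's 12 mean monthly
    temperatures (months with T <= 0 contribute nothing); PET is zero for
    months with T <= 0.  Requires at least 12 consecutive months.
    """
    if not -66.5 < latitude_deg < 66.5:
        raise ValueError("latitude outside (-66.5, 66.5): polar day length unsupported")
    t = climate.tmean()
    if len(t) < 12:
        raise ValueError("need at least 12 consecutive months for the heat index")
    normals = t.groupby(t.index.month).mean()
    heat_index = float((np.maximum(normals, 0.0) / 5.0).pow(1.514).sum())
    if heat_index == 0.0:
        return pd.Series(np.zeros(len(t)), index=t.index)
    a = (
        6.75e-7 * heat_index**3
        - 7.71e-5 * heat_index**2
        + 1.792e-2 * heat_index
        + 0.49239
    )
    months = t.index.month.to_numpy()
    correction = _day_length_hours(latitude_deg, months) / 12.0 * _MONTH_DAYS[months - 1] / 30.0
    temp = t.to_numpy(float)
    pet = np.where(
        temp > 0.0,
        16.0 * np.power(np.maximum(10.0 * temp / heat_index, 0.0), a) * correction,
        0.0,
    )
    return pd.Series(pet, index=t.index)


def water_balance(climate: MonthlyClimate, pet: pd.Series) -> pd.Series:
    """Monthly climatic water balance D = P - PET (mm)."""
    precip = climate.precip()
    if not precip.index.equals(pet.index):
        raise ValueError("climate and PET calendars are misaligned")
    return precip - pet


def accumulate(d: pd.Series, k: int) -> pd.Series:
    """k-month backward-looking sums; undefined for the first k-1 months and
    wherever the window contains a gap."""
    if k < 1:
        raise ValueError("accumulation scale k must be >= 1")
    if not isinstance(d.index, pd.PeriodIndex):
        raise TypeError("expected a monthly PeriodIndex series")
    full = pd.period_range(d.index.min(), d.index.max(), freq="M")
    return d.reindex(full).rolling(k).sum()


@dataclass
class LogLogisticParams:
    """Three-parameter log-logistic: F(x) = 1 / (1 + (scale/(x-origin))^shape).

    ``reflected`` marks a mirror fit: the parameters then describe -X and
    F(x) = 1 - F_loglogistic(-x), which extends the family to left-skewed
    samples while keeping the CDF strictly increasing.
    """

    shape: float
    scale: float
    origin: float
    reflected: bool = False

    def cdf(self, x: np.ndarray) -> np.ndarray:
        if self.reflected:
            return 1.0 - fisk.cdf(-np.asarray(x), self.shape, loc=self.origin, scale=self.scale)
        return fisk.cdf(x, self.shape, loc=self.origin, scale=self.scale)


def _pwm_solution(x: np.ndarray) -> tuple[float, float, float]:
    """Shape/scale/origin from descending unbiased PWMs of an ascending sample;
    shape <= 1 (L-skewness outside the family) is signalled as NaN shape."""
    n = len(x)
    i = np.arange(1, n + 1, dtype=float)
    b0 = x.mean()
    b1 = np.sum((n - i) / (n - 1.0) * x) / n
    b2 = np.sum((n - i) * (n - i - 1.0) / ((n - 1.0) * (n - 2.0)) * x) / n
    shape = (2.0 * b1 - b0) / (6.0 * b1 - b0 - 6.0 * b2)
    if not np.isfinite(shape) or shape <= 1.0:
        return float("nan"), float("nan"), float("nan")
    g = gamma_fn(1.0 + 1.0 / shape) * gamma_fn(1.0 - 1.0 / shape)
    scale = (b0 - 2.0 * b1) * shape / g
    origin = b0 - scale * g
    return float(shape), float(scale), float(origin)


def fit_loglogistic_pwm(samples: np.ndarray) -> LogLogisticParams:
    """Fit the three-parameter log-logistic by unbiased probability-weighted moments.

    Uses the standard PWM solution on the descending-weight moments
    w_s = E[X (1-F)^s]: shape = (2*w1 - w0) / (6*w1 - w0 - 6*w2),
    scale = (w0 - 2*w1) * shape / (G(1+1/shape) * G(1-1/shape)), and
    origin = w0 - scale * G(1+1/shape) * G(1-1/shape).

    Samples whose L-skewness falls outside the family's (right-skewed)
    range are fitted mirrored (see :class:`LogLogisticParams.reflected`).
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 20:
        raise ValueError(f"need at least 20 samples to fit the log-logistic (got {n})")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate sample (zero variance)")
    reflected = False
    shape, scale, origin = _pwm_solution(x)
    if np.isnan(shape):
        reflected = True
        x = np.sort(-x)
        shape, scale, origin = _pwm_solution(x)
        if np.isnan(shape):
            raise ValueError("PWM log-logistic fit failed in both orientations")
    if origin >= x[0]:
        # the fitted support must contain the sample
        warnings.warn(
            "PWM origin exceeds sample minimum; re-anchoring to min - tiny",
            stacklevel=2,
        )
        origin = x[0] - 1e-9 * max(1.0, abs(x[0]))
    return LogLogisticParams(shape=shape, scale=scale, origin=origin, reflected=reflected)


_CDF_EPS = 1e-6  # keeps the normal quantile finite for out-of-support values


def spei(
    d: pd.Series,
    k: int,
    calibration_period: tuple[int, int] | None = None,
    site_id: str = "",
) -> SPEISeries:
    """SPEI at scale ``k`` months from the monthly water balance ``d``.

    A log-logistic distribution is fitted per calendar month on the k-month
    accumulations falling inside ``calibration_period`` (default: the full
    record); every accumulation, inside or outside calibration, is then
    standardized through that month's fit.
    """
    acc = accumulate(d, k)
    years = acc.index.year
    if calibration_period is None:
        calibration_period = (int(years.min()), int(years.max()))
    lo, hi = calibration_period
    out = pd.Series(np.nan, index=acc.index)
    for month in range(1, 13):
        sel = acc.index.month == month
        vals = acc[sel]
        calib = vals[(vals.index.year >= lo) & (vals.index.year <= hi)].dropna()
        if len(calib) < 20:
            raise ValueError(
                f"insufficient calibration data for month {month} at scale {k} "
                f"({len(calib)} values, need 20)"
            )
        params = fit_loglogistic_pwm(calib.to_numpy())
        prob = np.clip(params.cdf(vals.to_numpy(float)), _CDF_EPS, 1.0 - _CDF_EPS)
        out[sel] = np.where(vals.notna().to_numpy(), norm.ppf(prob), np.nan)
    df = pd.DataFrame(
        {"year": out.index.year, "month": out.index.month, "value": out.to_numpy()}
    )
    return SPEISeries(site_id=site_id, scale_k=k, data=df, calibration_period=calibration_period)


def water_year_of(year: np.ndarray, month: np.ndarray) -> np.ndarray:
    """Water-year label: October-December belong to the following water year."""
    return np.where(month >= 10, year + 1, year)


def water_year_mean(
    s: pd.Series | HydroSeries | SPEISeries,
    min_months: int = 12,
    variable: str = "",
    site_id: str = "",
) -> WaterYearSeries:
    """Water-year (Oct t-1 ... Sep t) means of a monthly series.

    Water years with fewer than ``min_months`` non-missing months are
    flagged incomplete; downstream fits exclude them by default.
    """
    if isinstance(s, HydroSeries):
        site_id = site_id or s.site_id
        variable = variable or s.kind
        s = s.level()
    elif isinstance(s, SPEISeries):
        site_id = site_id or s.site_id
        variable = variable or f"spei_{s.scale_k}"
        s = s.values()
    if not isinstance(s.index, pd.PeriodIndex):
        raise TypeError("expected a monthly PeriodIndex series")
    wy = water_year_of(s.index.year.to_numpy(), s.index.month.to_numpy())
    df = pd.DataFrame({"water_year": wy, "value": s.to_numpy(float)})
    grouped = df.groupby("water_year")["value"].agg(["mean", "count"]).reset_index()
    out = pd.DataFrame(
        {
            "water_year": grouped["water_year"].astype(int),
            "value": grouped["mean"],
            "n_months": grouped["count"].astype(int),
        }
    )
    out["complete"] = out["n_months"] >= min_months
    return WaterYearSeries(site_id=site_id, variable=variable, data=out)
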