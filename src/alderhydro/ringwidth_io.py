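"""Domain containers and file I/O for ring-width, climate and gauge series.

Ring widths travel in the Tucson/RWL decadal format that dendro labs
exchange; climate and water-level series travel as long CSV
(``year,month,value`` or ``year,month,tmean,precip``).  Two RWL unit
dialects are accepted on read (0.01 mm with stop marker 999, 0.001 mm with
stop marker -9999); files are always written in the 0.01 mm dialect.

Gaps in gauge records are preserved as missing months and never imputed
here — imputation policy belongs to the consumer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RingWidthSeries",
    "MonthlyClimate",
    "HydroSeries",
    "read_rwl",
    "write_rwl",
    "read_monthly_csv",
    "write_monthly_csv",
]


@dataclass
class RingWidthSeries:
    """One tree's (or core's) annual ring widths in mm.

    Years are contiguous from ``first_year``; widths are strictly positive.
    """

    series_id: str
    site_id: str
    first_year: int
    widths: np.ndarray

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.ndim != 1 or self.widths.size == 0:
            raise ValueError(f"{self.series_id}: widths must be a non-empty 1-d array")
        if not np.all(np.isfinite(self.widths)) or np.any(self.widths <= 0):
            raise ValueError(f"{self.series_id}: widths must be finite and strictly positive")

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.widths) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def to_series(self) -> pd.Series:
        return pd.Series(self.widths, index=self.years, name=self.series_id)


def _check_monthly_frame(df: pd.DataFrame, what: str) -> pd.DataFrame:
    df = df.copy()
    df["year"] = df["year"].astype(int)
    df["month"] = df["month"].astype(int)
    bad = df[(df["month"] < 1) | (df["month"] > 12)]
    if len(bad):
        raise ValueError(f"{what}: month outside 1-12 (first offender: row {bad.index[0]})")
    if df.duplicated(["year", "month"]).any():
        dup = df[df.duplicated(["year", "month"])].iloc[0]
        raise ValueError(f"{what}: duplicate (year, month) = ({dup['year']}, {dup['month']})")
    return df.sort_values(["year", "month"]).reset_index(drop=True)


def _period_series(df: pd.DataFrame, col: str) -> pd.Series:
    """Monthly values on a gap-free PeriodIndex; absent months become NaN."""
    idx = pd.PeriodIndex.from_fields(year=df["year"], month=df["month"], freq="M")
    s = pd.Series(df[col].to_numpy(dtype=float), index=idx)
    full = pd.period_range(idx.min(), idx.max(), freq="M")
    return s.reindex(full)


@dataclass
class MonthlyClimate:
    """Monthly mean air temperature (°C) and precipitation sum (mm) for a site."""

    site_id: str
    data: pd.DataFrame  # columns: year, month, tmean, precip

    def __post_init__(self) -> None:
        self.data = _check_monthly_frame(self.data, f"climate[{self.site_id}]")
        if (self.data["precip"] < 0).any():
            raise ValueError(f"climate[{self.site_id}]: negative precipitation")

    def tmean(self) -> pd.Series:
        return _period_series(self.data, "tmean")

    def precip(self) -> pd.Series:
        return _period_series(self.data, "precip")


@dataclass
class HydroSeries:
    """Monthly lake-level or groundwater gauge readings (abstract gauge units).

    Gaps (missing months) are permitted and preserved.
    """

    site_id: str
    kind: Literal["lake_level", "groundwater"]
    data: pd.DataFrame  # columns: year, month, level

    def __post_init__(self) -> None:
        if self.kind not in ("lake_level", "groundwater"):
            raise ValueError(f"unknown hydro kind {self.kind!r}")
        self.data = _check_monthly_frame(self.data, f"{self.kind}[{self.site_id}]")

    def level(self) -> pd.Series:
        return _period_series(self.data, "level")


# ---------------------------------------------------------------------------
# Tucson / RWL decadal format
# ---------------------------------------------------------------------------

_STOP_MARKERS = {999: 100.0, -9999: 1000.0}  # marker -> divisor to mm


def read_rwl(path: str | Path, site_id: str | None = None) -> list[RingWidthSeries]:
    """Parse a Tucson decadal ring-width file.

    Units are auto-detected per series from the stop marker: 999 means the
    values are hundredths of mm, -9999 thousandths.  Missing-ring zeros are
    not supported (widths must be strictly positive).
    """
    path = Path(path)
    if site_id is None:
        site_id = path.stem
    text = path.read_text()
    lines = text.splitlines()
    out: list[RingWidthSeries] = []
    cur_id: str | None = None
    cur_first: int | None = None
    cur_vals: list[int] = []
    expected_year: int | None = None

    def finish(divisor: float, lineno: int) -> None:
        nonlocal cur_id, cur_first, cur_vals, expected_year
        assert cur_id is not None and cur_first is not None
        if any(v <= 0 for v in cur_vals):
            raise ValueError(
                f"{path}:{lineno}: non-positive width in series {cur_id} "
                "(missing-ring zeros are not supported)"
            )
        out.append(
            RingWidthSeries(cur_id, site_id, cur_first, np.array(cur_vals) / divisor)
        )
        cur_id, cur_first, cur_vals, expected_year = None, None, [], None

    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        # fixed columns: series id in 1-8, decade year in 9-12, then values
        sid = line[:8].strip()
        rest = line[8:].split()
        if not sid or not rest:
            raise ValueError(f"{path}:{lineno}: malformed decade line (need id and year)")
        try:
            year = int(rest[0])
            vals = [int(t) for t in rest[1:]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed decade line: {exc}") from None

        if cur_id is None:
            cur_id, cur_first = sid, year
        elif sid != cur_id:
            raise ValueError(
                f"{path}:{lineno}: series {cur_id} has no stop marker before {sid} begins"
            )
        elif expected_year is not None and year != expected_year:
            raise ValueError(
                f"{path}:{lineno}: non-monotone years in {sid}: expected {expected_year}, got {year}"
            )

        stopped = False
        for v in vals:
            if v in _STOP_MARKERS:
                finish(_STOP_MARKERS[v], lineno)
                stopped = True
                break
            cur_vals.append(v)
        if not stopped:
            # next line must start at the following decade boundary
            expected_year = (year // 10 + 1) * 10
            if len(cur_vals) != expected_year - cur_first:  # type: ignore[operator]
                raise ValueError(
                    f"{path}:{lineno}: decade row for {sid} has wrong number of values"
                )

    if cur_id is not None:
        raise ValueError(f"{path}: series {cur_id} missing stop marker at end of file")
    if not out:
        logger.warning("%s: no ring-width series found (empty file)", path)
    return out


def write_rwl(
    series_list: Iterable[RingWidthSeries],
    path: str | Path,
    precision: float = 0.01,
) -> None:
    """Write series in Tucson decadal format.

    ``precision`` is the unit of the integer fields in mm; 0.01 (marker 999)
    and 0.001 (marker -9999) are supported.  Ids longer than 8 characters
    are truncated with a warning.
    """
    if precision == 0.01:
        marker = 999
    elif precision == 0.001:
        marker = -9999
    else:
        raise ValueError("precision must be 0.01 or 0.001 mm")
    path = Path(path)
    rows: list[str] = []
    for s in series_list:
        sid = s.series_id
        if len(sid) > 8:
            logger.warning("series id %r truncated to 8 characters", sid)
            sid = sid[:8]
        ints = np.rint(s.widths / precision).astype(int)
        if np.any(ints <= 0):
            raise ValueError(f"{s.series_id}: width not representable at precision {precision}")
        chunks: list[tuple[int, list[int]]] = []
        year = s.first_year
        i = 0
        while i < len(ints):
            decade_end = (year // 10) * 10 + 9
            n = min(decade_end - year + 1, len(ints) - i)
            chunks.append((year, list(ints[i : i + n])))
            i += n
            year += n
        last_year, last_vals = chunks[-1]
        if last_year + len(last_vals) - 1 < (last_year // 10) * 10 + 9:
            last_vals.append(marker)  # marker fits in the final decade row
        else:
            chunks.append((year, [marker]))
        for row_year, row_vals in chunks:
            rows.append(_format_rwl_row(sid, row_year, row_vals))
    path.write_text("\n".join(rows) + ("\n" if rows else ""))


def _format_rwl_row(sid: str, year: int, values: list[int]) -> str:
    return f"{sid:<8}{year:>4}" + "".join(f"{v:>6d}" for v in values)


# ---------------------------------------------------------------------------
# Long CSV  (year,month,value | year,month,tmean,precip)
# ---------------------------------------------------------------------------


def read_monthly_csv(
    path: str | Path,
    kind: Literal["climate", "lake_level", "groundwater"],
    site_id: str | None = None,
) -> MonthlyClimate | HydroSeries:
    """Read a monthly series from long CSV.

    ``kind='climate'`` expects columns ``year,month,tmean,precip``; the hydro
    kinds expect ``year,month,value`` (or ``level``).  Missing months remain
    gaps.
    """
    path = Path(path)
    if site_id is None:
        site_id = path.stem
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if kind == "climate":
        missing = {"year", "month", "tmean", "precip"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: climate CSV missing columns {sorted(missing)}")
        return MonthlyClimate(site_id, df[["year", "month", "tmean", "precip"]])
    if "value" in df.columns:
        df = df.rename(columns={"value": "level"})
    if "level" not in df.columns:
        raise ValueError(f"{path}: hydro CSV needs a 'value' or 'level' column")
    return HydroSeries(site_id, kind, df[["year", "month", "level"]])


def write_monthly_csv(obj: MonthlyClimate | HydroSeries, path: str | Path) -> None:
    if isinstance(obj, MonthlyClimate):
        obj.data.to_csv(path, index=False)
    else:
        obj.data.rename(columns={"level": "value"}).to_csv(path, index=False)
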