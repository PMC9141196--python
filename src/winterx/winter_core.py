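"""Winter (DJF) season extraction, seasonal means, ensemble reduction and
the spatial coefficient of variation.

Winters are labelled by the year containing January and February: the
season December 1990 – February 1991 is ``winter_year`` 1991.  A winter
with more than 10% of its days missing is flagged incomplete and excluded
from seasonal means and any downstream classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .station_io import EnsembleMember, StationDailySeries, ValidationError

KELVIN_OFFSET = 273.15

#: Fraction of missing days above which a winter is excluded.
MAX_MISSING_FRACTION = 0.10


@dataclass
class WinterSeries:
    """The DJF window of one station for one winter year."""

    station_id: str
    winter_year: int
    data: pd.DataFrame          # daily tmax/tmin/tmean over the window
    complete: bool              # missing fraction within tolerance

    @property
    def tx_bar(self) -> float:
        return float(self.data["tmax"].mean()) if self.complete else float("nan")

    @property
    def tn_bar(self) -> float:
        return float(self.data["tmin"].mean()) if self.complete else float("nan")

    @property
    def tm_bar(self) -> float:
        return float(self.data["tmean"].mean()) if self.complete else float("nan")


def winter_window(winter_year: int) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Return the (start, end) dates of the DJF window of ``winter_year``."""
    start = pd.Timestamp(year=winter_year - 1, month=12, day=1)
    end = pd.Timestamp(year=winter_year, month=3, day=1) - pd.Timedelta(days=1)
    return start, end


def extract_winter(series: StationDailySeries, winter_year: int,
                   max_missing_frac: float = MAX_MISSING_FRACTION) -> WinterSeries:
    """Extract the Dec 1 – Feb 28/29 window of one winter.

    Raises if the series does not cover the window at all; a partially
    missing window is returned with ``complete`` reflecting the missing
    fraction against the full 90/91-day window length.
    """
    start, end = winter_window(winter_year)
    if series.dates[-1] < start or series.dates[0] > end:
        raise ValidationError(
            f"series {series.station_id} does not cover winter {winter_year}")
    full = pd.date_range(start, end, freq="D")
    window = series.data.reindex(full)
    n_missing = int(window["tmean"].isna().sum())
    complete = n_missing <= max_missing_frac * len(full)
    return WinterSeries(station_id=series.station_id, winter_year=winter_year,
                        data=window, complete=complete)


def available_winters(series: StationDailySeries) -> list[int]:
    """Winter years whose full DJF window lies inside the series span."""
    first, last = series.dates[0], series.dates[-1]
    years = []
    for wy in range(first.year, last.year + 1):
        start, end = winter_window(wy)
        if start >= first and end <= last:
            years.append(wy)
    return years


def winter_mean_table(member_or_series: EnsembleMember | Mapping[str, StationDailySeries],
                      winters: Sequence[int] | None = None) -> pd.DataFrame:
    """Seasonal DJF means per station per winter.

    Returns a tidy frame (station_id, winter_year, tx_bar, tn_bar, tm_bar);
    incomplete winters appear with NaN means.
    """
    series = (member_or_series.series if isinstance(member_or_series, EnsembleMember)
              else member_or_series)
    rows = []
    for sid in sorted(series):
        s = series[sid]
        for wy in (winters if winters is not None else available_winters(s)):
            w = extract_winter(s, wy)
            rows.append({"station_id": sid, "winter_year": wy,
                         "tx_bar": w.tx_bar, "tn_bar": w.tn_bar, "tm_bar": w.tm_bar})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ensemble reduction
# ---------------------------------------------------------------------------

def ensemble_median(tables: Mapping[str, pd.DataFrame], value_col: str) -> pd.DataFrame:
    """Cross-model median (and min/max spread) of a per-station statistic.

    ``tables`` maps model name -> tidy frame with (station_id, winter_year,
    value_col).  All members must cover the same (station, winter) cells.
    The median of an even model count is the mean of the two central values.
    """
    if not tables:
        raise ValidationError("no ensemble members")
    keys = None
    stacked = []
    for model in sorted(tables):
        t = tables[model].set_index(["station_id", "winter_year"])[value_col].sort_index()
        if keys is None:
            keys = t.index
        elif not t.index.equals(keys):
            raise ValidationError(f"member {model} misaligned with the ensemble")
        stacked.append(t.to_numpy())
    arr = np.vstack(stacked)  # models x cells
    out = pd.DataFrame({
        "median": np.median(arr, axis=0),
        "min": arr.min(axis=0),
        "max": arr.max(axis=0),
    }, index=keys).reset_index()
    return out


def ensemble_mean(tables: Mapping[str, pd.DataFrame], value_col: str) -> pd.DataFrame:
    """Cross-model mean companion to :func:`ensemble_median`."""
    out = ensemble_median(tables, value_col)
    arr = np.vstack([tables[m].set_index(["station_id", "winter_year"])[value_col]
                     .sort_index().to_numpy() for m in sorted(tables)])
    out["median"] = arr.mean(axis=0)
    return out.rename(columns={"median": "mean"})


def ensemble_median_daily(members: Iterable[EnsembleMember]) -> dict[str, StationDailySeries]:
    """Per-day cross-model median series per station (the MME-median record)."""
    members = list(members)
    if not members:
        raise ValidationError("no ensemble members")
    ids = members[0].station_ids
    for m in members[1:]:
        if m.station_ids != ids:
            raise ValidationError("members cover different station sets")
    out = {}
    for sid in ids:
        frames = [m.series[sid].data for m in members]
        index = frames[0].index
        for f in frames[1:]:
            if not f.index.equals(index):
                raise ValidationError("members cover different date spans")
        med = pd.DataFrame(
            {col: np.median(np.vstack([f[col].to_numpy() for f in frames]), axis=0)
             for col in ("tmax", "tmin", "tmean")}, index=index)
        out[sid] = StationDailySeries(station_id=sid, data=med)
    return out


# ---------------------------------------------------------------------------
# Spatial coefficient of variation
# ---------------------------------------------------------------------------

def spatial_cv(values_c: Sequence[float]) -> float:
    """Cross-station coefficient of variation on the Kelvin scale.

    ``values_c`` are per-station values in degC for one year; they are
    converted to Kelvin and CV = sample SD (n-1) / mean is returned.
    Requires at least two non-missing stations.
    """
    v = np.asarray(values_c, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValidationError("spatial CV needs at least two stations")
    k = v + KELVIN_OFFSET
    return float(np.std(k, ddof=1) / np.mean(k))


def spatial_cv_series(winter_means: pd.DataFrame, value_col: str) -> pd.Series:
    """Yearly spatial CV across stations from a tidy winter-means frame."""
    return (winter_means.groupby("winter_year")[value_col]
            .apply(lambda v: spatial_cv(v.to_numpy())))
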