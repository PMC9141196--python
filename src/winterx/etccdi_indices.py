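"""ETCCDI extreme-temperature indices on daily station series.

Ten indices are supported:

===== ============================================================== =====
FD0   frost days, Tn < 0 degC                                         days
ID0   ice days, Tx < 0 degC                                           days
TN10p cold nights, Tn below the calendar-day 10th percentile          days
TX90p warm days, Tx above the calendar-day 90th percentile            days
TNn   minimum of daily minimum temperature                            degC
TXx   maximum of daily maximum temperature                            degC
CSDI  cold-spell days: runs of >=6 consecutive days with Tn < p10     days
WSDI  warm-spell days: runs of >=6 consecutive days with Tx > p90     days
DTR   mean daily temperature range Tx - Tn                            degC
GSL   growing-season length (calendar year, 5 degC / 6-day rule)      days
===== ============================================================== =====

Percentile thresholds follow the ETCCDI convention of a 5-day window
centred on each calendar day, pooled over a 30-year base period, with the
linear-interpolation order-statistic estimator.  The base period is
*dynamic* by default: the trailing 30 years ending at the decade before
the decade containing the target year, refreshed each decade (winters
2031–2040 use 2001–2030).  A fixed base period is available by option.
No in-base bootstrap correction is applied.

Spells never bridge across seasons; a run touching the season edge counts
only its in-season days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .station_io import StationDailySeries, ValidationError
from .winter_core import WinterSeries, extract_winter, winter_window

WINTER_INDEX_NAMES = ("FD0", "ID0", "TN10p", "TX90p", "TNn", "TXx", "CSDI", "WSDI", "DTR")
ALL_INDEX_NAMES = WINTER_INDEX_NAMES + ("GSL",)

DEFAULT_DAY_WINDOW = 5
DEFAULT_BASE_SPAN = 30
SPELL_MIN_RUN = 6
GSL_THRESHOLD_C = 5.0
GSL_MIN_RUN = 6


def decade_start(year: int) -> int:
    """First year of the decade containing ``year`` (2035 -> 2031)."""
    return (year - 1) // 10 * 10 + 1


@dataclass
class ThresholdSet:
    """Per-calendar-day percentile thresholds for one station."""

    station_id: str
    p_low_tn: dict[tuple[int, int], float]   # (month, day) -> p10 of Tn, degC
    p_high_tx: dict[tuple[int, int], float]  # (month, day) -> p90 of Tx, degC
    base_years: tuple[int, int]              # winter-year labels of the base window
    day_window: int

    def low_for(self, dates: pd.DatetimeIndex) -> np.ndarray:
        return np.array([self.p_low_tn[(d.month, d.day)] for d in dates])

    def high_for(self, dates: pd.DatetimeIndex) -> np.ndarray:
        return np.array([self.p_high_tx[(d.month, d.day)] for d in dates])


def _season_year(dates: pd.DatetimeIndex) -> np.ndarray:
    """Winter-year label used for base-period membership (Jul–Dec -> year+1)."""
    return dates.year.to_numpy() + (dates.month.to_numpy() >= 7)


def _window_keys(month: int, day: int, half: int) -> list[tuple[int, int]]:
    """Calendar (month, day) keys of the window centred on a calendar day."""
    ref = pd.Timestamp(2000, month, day)  # leap reference so Feb 29 resolves
    return [((ref + pd.Timedelta(days=o)).month, (ref + pd.Timedelta(days=o)).day)
            for o in range(-half, half + 1)]


def winter_calendar_days() -> list[tuple[int, int]]:
    """All (month, day) pairs of the DJF window, Feb 29 included."""
    days = [(12, d) for d in range(1, 32)]
    days += [(1, d) for d in range(1, 32)]
    days += [(2, d) for d in range(1, 30)]
    return days


def compute_thresholds(series: StationDailySeries,
                       target_year: int,
                       low_percentile: float = 10.0,
                       high_percentile: float = 90.0,
                       day_window: int = DEFAULT_DAY_WINDOW,
                       base_span: int = DEFAULT_BASE_SPAN,
                       mode: str = "dynamic",
                       fixed_base: tuple[int, int] | None = None,
                       days: Sequence[tuple[int, int]] | None = None) -> ThresholdSet:
    """Empirical calendar-day percentile thresholds for one station.

    ``mode='dynamic'`` uses the trailing ``base_span`` winters ending at
    the decade boundary before the decade of ``target_year``;
    ``mode='fixed'`` uses the ``fixed_base`` (start, end) winter years.
    Percentiles are linear-interpolation order statistics over the pooled
    ``day_window`` x ``base_span`` sample.
    """
    if mode == "dynamic":
        d0 = decade_start(target_year)
        base = (d0 - base_span, d0 - 1)
    elif mode == "fixed":
        if fixed_base is None:
            raise ValidationError("fixed mode requires fixed_base=(start, end)")
        base = fixed_base
    else:
        raise ValidationError(f"unknown threshold mode {mode!r}")

    start_needed, _ = winter_window(base[0])
    if series.dates[0] > start_needed:
        raise ValidationError(
            f"station {series.station_id}: insufficient history for base window {base} "
            f"(series starts {series.dates[0].date()})")

    season_year = _season_year(series.dates)
    in_base = (season_year >= base[0]) & (season_year <= base[1])
    sub = series.data.loc[in_base]
    by_day_tn: dict[tuple[int, int], np.ndarray] = {}
    by_day_tx: dict[tuple[int, int], np.ndarray] = {}
    for (m, d), grp in sub.groupby([sub.index.month, sub.index.day]):
        by_day_tn[(m, d)] = grp["tmin"].dropna().to_numpy()
        by_day_tx[(m, d)] = grp["tmax"].dropna().to_numpy()

    half = day_window // 2
    p_low: dict[tuple[int, int], float] = {}
    p_high: dict[tuple[int, int], float] = {}
    for (m, d) in (days if days is not None else winter_calendar_days()):
        keys = _window_keys(m, d, half)
        tn = np.concatenate([by_day_tn.get(k, np.empty(0)) for k in keys])
        tx = np.concatenate([by_day_tx.get(k, np.empty(0)) for k in keys])
        if tn.size == 0 or tx.size == 0:
            raise ValidationError(
                f"station {series.station_id}: no base data for calendar day {m:02d}-{d:02d}")
        p_low[(m, d)] = float(np.percentile(tn, low_percentile))
        p_high[(m, d)] = float(np.percentile(tx, high_percentile))
    return ThresholdSet(station_id=series.station_id, p_low_tn=p_low, p_high_tx=p_high,
                        base_years=base, day_window=day_window)


# ---------------------------------------------------------------------------
# Run-length machinery
# ---------------------------------------------------------------------------

def run_lengths(mask: np.ndarray) -> list[int]:
    """Lengths of all maximal runs of True in a boolean array."""
    m = np.asarray(mask, dtype=bool).astype(int)
    if m.size == 0:
        return []
    edges = np.diff(np.concatenate(([0], m, [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return (ends - starts).tolist()


def spell_days(mask: np.ndarray, min_run: int = SPELL_MIN_RUN) -> int:
    """Total days in maximal runs of length >= ``min_run``."""
    return int(sum(l for l in run_lengths(mask) if l >= min_run))


# ---------------------------------------------------------------------------
# Winter indices
# ---------------------------------------------------------------------------

def count_days(winter: WinterSeries, index: str,
               thresholds: ThresholdSet | None = None) -> int:
    """Day-count indices FD0, ID0, TN10p, TX90p over non-missing days."""
    d = winter.data
    if index == "FD0":
        mask = d["tmin"] < 0.0
    elif index == "ID0":
        mask = d["tmax"] < 0.0
    elif index == "TN10p":
        if thresholds is None:
            raise ValidationError("TN10p requires a ThresholdSet")
        mask = d["tmin"] < thresholds.low_for(d.index)
    elif index == "TX90p":
        if thresholds is None:
            raise ValidationError("TX90p requires a ThresholdSet")
        mask = d["tmax"] > thresholds.high_for(d.index)
    else:
        raise ValidationError(f"unknown day-count index {index!r}")
    return int(mask.fillna(False).sum())


def spell_duration(winter: WinterSeries, thresholds: ThresholdSet,
                   side: str, min_run: int = SPELL_MIN_RUN) -> int:
    """WSDI (side='warm': Tx > p90) or CSDI (side='cold': Tn < p10).

    Missing days break runs; runs are truncated at the season boundary.
    """
    d = winter.data
    if side == "warm":
        mask = (d["tmax"] > thresholds.high_for(d.index)).fillna(False).to_numpy()
    elif side == "cold":
        mask = (d["tmin"] < thresholds.low_for(d.index)).fillna(False).to_numpy()
    else:
        raise ValidationError(f"side must be 'warm' or 'cold', got {side!r}")
    return spell_days(mask, min_run)


def extreme_value(winter: WinterSeries, which: str) -> float:
    """TXx (max of Tx) or TNn (min of Tn) over non-missing days."""
    if which == "TXx":
        col = winter.data["tmax"]
        if col.dropna().empty:
            raise ValidationError("empty window")
        return float(col.max())
    if which == "TNn":
        col = winter.data["tmin"]
        if col.dropna().empty:
            raise ValidationError("empty window")
        return float(col.min())
    raise ValidationError(f"which must be 'TXx' or 'TNn', got {which!r}")


def dtr(winter: WinterSeries) -> float:
    """Mean daily temperature range over days with both Tx and Tn present."""
    d = winter.data[["tmax", "tmin"]].dropna()
    if d.empty:
        raise ValidationError("empty window")
    return float((d["tmax"] - d["tmin"]).mean())


def gsl(series: StationDailySeries, year: int,
        threshold_c: float = GSL_THRESHOLD_C, min_run: int = GSL_MIN_RUN) -> int:
    """Growing-season length of one calendar year.

    Days from the start of the first run of >= ``min_run`` days with
    Tm > ``threshold_c`` to the start of the first such run with
    Tm < ``threshold_c`` beginning after 1 July; 0 if there is no onset,
    and through 31 December if there is no termination.
    """
    days = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    tm = series.data["tmean"].reindex(days).to_numpy()
    n = len(days)
    warm = np.nan_to_num(tm, nan=-np.inf) > threshold_c
    cold = np.nan_to_num(tm, nan=np.inf) < threshold_c

    onset = _first_run_start(warm, min_run, from_index=0)
    if onset is None:
        return 0
    july1 = int(np.flatnonzero(days.month == 7)[0])
    term = _first_run_start(cold, min_run, from_index=july1 + 1)
    if term is None or term <= onset:
        return n - onset
    return term - onset


def _first_run_start(mask: np.ndarray, min_run: int, from_index: int) -> int | None:
    m = mask.astype(int)
    edges = np.diff(np.concatenate(([0], m, [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    for s, e in zip(starts, ends):
        if e - s >= min_run and s >= from_index:
            return int(s)
    return None


def winter_indices(series: StationDailySeries, winter_year: int,
                   thresholds: ThresholdSet | None = None) -> dict[str, float]:
    """All nine winter indices of one station-winter as a name -> value dict.

    Relative indices (TN10p, TX90p, CSDI, WSDI) are NaN when no threshold
    set is supplied; every index is NaN for an incomplete winter.
    """
    w = extract_winter(series, winter_year)
    out: dict[str, float] = dict.fromkeys(WINTER_INDEX_NAMES, float("nan"))
    if not w.complete:
        return out
    out["FD0"] = count_days(w, "FD0")
    out["ID0"] = count_days(w, "ID0")
    out["TNn"] = extreme_value(w, "TNn")
    out["TXx"] = extreme_value(w, "TXx")
    out["DTR"] = dtr(w)
    if thresholds is not None:
        out["TN10p"] = count_days(w, "TN10p", thresholds)
        out["TX90p"] = count_days(w, "TX90p", thresholds)
        out["CSDI"] = spell_duration(w, thresholds, "cold")
        out["WSDI"] = spell_duration(w, thresholds, "warm")
    return out


def index_table(series_map: dict[str, StationDailySeries],
                winters: Sequence[int],
                day_window: int = DEFAULT_DAY_WINDOW,
                base_span: int = DEFAULT_BASE_SPAN,
                mode: str = "dynamic",
                fixed_base: tuple[int, int] | None = None,
                include_gsl: bool = True) -> pd.DataFrame:
    """Tidy per-station index table over many winters.

    Thresholds are recomputed once per station per decade (the dynamic
    baseline refresh) and reused for every winter of that decade.
    """
    rows = []
    for sid in sorted(series_map):
        s = series_map[sid]
        cache: dict[tuple[int, int], ThresholdSet] = {}
        for wy in winters:
            key = (decade_start(wy),) if mode == "dynamic" else (0,)
            if key not in cache:
                cache[key] = compute_thresholds(
                    s, wy, day_window=day_window, base_span=base_span,
                    mode=mode, fixed_base=fixed_base)
            vals = winter_indices(s, wy, cache[key])
            if include_gsl:
                vals["GSL"] = gsl(s, wy)
            rows += [{"station_id": sid, "winter_year": wy, "index": k, "value": v}
                     for k, v in vals.items()]
    return pd.DataFrame(rows)
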