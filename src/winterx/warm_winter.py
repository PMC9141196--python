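"""Dynamic-baseline warm-winter grading and decadal event frequency.

The China Meteorological Administration trisection standard treats the
winter-mean temperature as Gaussian and grades each winter against a
moving 30-winter climatological normal:

* normal ``Ta`` = mean of the baseline winters,
* ``sigma`` = their sample standard deviation (denominator n-1),
* anomaly ``dT = T - Ta``,
* *warm winter* when ``dT > 0.43 sigma`` and *strong warm winter* when
  ``dT > 1.29 sigma`` (0.43 is the standard-normal upper-tercile point,
  1.29 the upper-decile point of the trisection refinement).

The baseline is *dynamic*: it covers the three most recent completed
calendar decades before the decade containing the winter, refreshed each
decade (winters 2031–2040 are judged against 2001–2030).  A static
(fixed-window) baseline is available for comparison.

A region is in a warm winter when strictly more than 50% of its effective
stations (those with a valid grade that winter) are graded warm or
strong; a regional *strong* warm winter needs strictly more than 50% of
stations graded strong.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .etccdi_indices import decade_start
from .station_io import ValidationError

#: Trisection thresholds in units of sigma.
WARM_Z = 0.43
STRONG_Z = 1.29

BASELINE_WINTERS = 30

GRADES = ("none", "warm", "strong")


def normal_tercile_point() -> float:
    """Upper-tercile point of the standard normal, P(Z > z) = 1/3."""
    return float(norm.isf(1.0 / 3.0))


@dataclass(frozen=True)
class Baseline:
    """Moving climatological normal for one unit (station or region)."""

    unit_id: str
    decade: int                 # first year of the decade the baseline serves
    ta: float                   # 30-winter mean, degC
    sigma: float                # 30-winter sample SD, degC
    window: tuple[int, int]     # (first, last) baseline winter year
    n: int


@dataclass(frozen=True)
class WarmWinterRecord:
    """Grade of one unit for one winter."""

    level: str                  # 'station' | 'region' | 'national'
    unit_id: str
    winter_year: int
    anomaly: float              # dT = T - Ta, degC (NaN at region level)
    grade: str                  # 'none' | 'warm' | 'strong'


def baseline_window(winter_year: int, n_winters: int = BASELINE_WINTERS) -> tuple[int, int]:
    """Baseline winters serving the decade that contains ``winter_year``.

    The window is the ``n_winters`` winters ending at the last completed
    decade: winter 2035 lies in 2031–2040, so its baseline is 2001–2030.
    """
    d0 = decade_start(winter_year)
    return d0 - n_winters, d0 - 1


def dynamic_baseline(winter_means: pd.Series, winter_year: int,
                     n_winters: int = BASELINE_WINTERS,
                     unit_id: str = "") -> Baseline:
    """Climatological normal and sigma from the moving 30-winter window.

    ``winter_means`` is indexed by winter year.  All ``n_winters`` baseline
    winters must be present and non-missing.
    """
    first, last = baseline_window(winter_year, n_winters)
    window = winter_means.reindex(range(first, last + 1))
    if window.isna().any():
        missing = [int(y) for y in window.index[window.isna()]]
        raise ValidationError(
            f"baseline {first}-{last} for winter {winter_year} incomplete "
            f"(missing winters {missing[:5]}{'...' if len(missing) > 5 else ''})")
    vals = window.to_numpy(dtype=float)
    return Baseline(unit_id=unit_id, decade=decade_start(winter_year),
                    ta=float(vals.mean()), sigma=float(np.std(vals, ddof=1)),
                    window=(first, last), n=len(vals))


def static_baseline(winter_means: pd.Series, window: tuple[int, int],
                    unit_id: str = "") -> Baseline:
    """Fixed-window climatological normal (the non-updating alternative)."""
    vals = winter_means.reindex(range(window[0], window[1] + 1))
    if vals.isna().any():
        raise ValidationError(f"static baseline window {window} incomplete")
    arr = vals.to_numpy(dtype=float)
    return Baseline(unit_id=unit_id, decade=0, ta=float(arr.mean()),
                    sigma=float(np.std(arr, ddof=1)), window=window, n=len(arr))


def classify_station(t: float, baseline: Baseline, winter_year: int,
                     warm_z: float = WARM_Z, strong_z: float = STRONG_Z) -> WarmWinterRecord:
    """Grade one station winter mean against its baseline.

    Strictly greater-than at both thresholds; a zero-variance baseline is
    degenerate and rejected.
    """
    if baseline.sigma <= 0.0:
        raise ValidationError(f"degenerate baseline (sigma=0) for {baseline.unit_id}")
    dt = t - baseline.ta
    if dt > strong_z * baseline.sigma:
        grade = "strong"
    elif dt > warm_z * baseline.sigma:
        grade = "warm"
    else:
        grade = "none"
    return WarmWinterRecord(level="station", unit_id=baseline.unit_id,
                            winter_year=winter_year, anomaly=float(dt), grade=grade)


def classify_region(records: Sequence[WarmWinterRecord], region: str,
                    level: str = "region") -> WarmWinterRecord:
    """Aggregate station grades of one winter into a regional grade.

    Warm when strictly more than half of the effective stations are warm
    or strong; strong when strictly more than half are strong.
    """
    if not records:
        raise ValidationError(f"no effective stations for region {region}")
    years = {r.winter_year for r in records}
    if len(years) != 1:
        raise ValidationError("regional classification mixes winters")
    n = len(records)
    n_warm = sum(r.grade in ("warm", "strong") for r in records)
    n_strong = sum(r.grade == "strong" for r in records)
    if n_strong * 2 > n:
        grade = "strong"
    elif n_warm * 2 > n:
        grade = "warm"
    else:
        grade = "none"
    return WarmWinterRecord(level=level, unit_id=region, winter_year=years.pop(),
                            anomaly=float("nan"), grade=grade)


def decadal_frequency(records: Iterable[WarmWinterRecord], unit_id: str,
                      decade: int) -> tuple[int, int]:
    """(warm-or-strong, strong) event counts among a decade's winters.

    ``decade`` is the first winter year of the decade (2021 covers winters
    2021–2030); the counts are bounded by 10.
    """
    wy0, wy1 = decade, decade + 9
    n_warm = n_strong = 0
    for r in records:
        if r.unit_id == unit_id and wy0 <= r.winter_year <= wy1:
            if r.grade in ("warm", "strong"):
                n_warm += 1
            if r.grade == "strong":
                n_strong += 1
    return n_warm, n_strong


# ---------------------------------------------------------------------------
# Network-level convenience
# ---------------------------------------------------------------------------

def classify_network(winter_means: pd.DataFrame, stations: pd.DataFrame,
                     winters: Sequence[int] | None = None,
                     value_col: str = "tm_bar",
                     mode: str = "dynamic",
                     static_window: tuple[int, int] | None = None
                     ) -> list[WarmWinterRecord]:
    """Station, regional and national grades for every classifiable winter.

    ``winter_means`` is tidy (station_id, winter_year, value_col); regional
    grades use the >50% station rule and the national grade applies the
    same rule to all effective stations.
    """
    by_station = {sid: grp.set_index("winter_year")[value_col]
                  for sid, grp in winter_means.groupby("station_id")}
    all_years = sorted(winter_means["winter_year"].unique())
    if winters is None:
        if mode == "dynamic":
            winters = [wy for wy in all_years
                       if baseline_window(wy)[0] >= all_years[0]
                       and baseline_window(wy)[1] < wy]
        else:
            winters = [wy for wy in all_years if wy > static_window[1]]

    records: list[WarmWinterRecord] = []
    station_cache: dict[tuple[str, int], Baseline] = {}
    for wy in winters:
        per_region: dict[str, list[WarmWinterRecord]] = {}
        national: list[WarmWinterRecord] = []
        for sid, means in by_station.items():
            if wy not in means.index or np.isnan(means.loc[wy]):
                continue
            key = (sid, decade_start(wy) if mode == "dynamic" else 0)
            if key not in station_cache:
                try:
                    if mode == "dynamic":
                        station_cache[key] = dynamic_baseline(means, wy, unit_id=sid)
                    else:
                        station_cache[key] = static_baseline(means, static_window, unit_id=sid)
                except ValidationError:
                    station_cache[key] = None  # station ineffective this decade
            if station_cache[key] is None:
                continue
            rec = classify_station(float(means.loc[wy]), station_cache[key], wy)
            records.append(rec)
            region = str(stations.loc[sid, "region"])
            per_region.setdefault(region, []).append(rec)
            national.append(rec)
        for region in sorted(per_region):
            records.append(classify_region(per_region[region], region))
        if national:
            records.append(classify_region(national, "ECM", level="national"))
    return records


def records_to_frame(records: Iterable[WarmWinterRecord]) -> pd.DataFrame:
    """Tidy frame (level, unit_id, winter_year, anomaly_c, grade)."""
    return pd.DataFrame(
        [{"level": r.level, "unit_id": r.unit_id, "winter_year": r.winter_year,
          "anomaly_c": r.anomaly, "grade": r.grade} for r in records])
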