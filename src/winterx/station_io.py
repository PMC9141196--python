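"""Delimited-text I/O for station networks, daily temperature series,
population tables and pipeline outputs.

All on-disk formats are plain CSV with ISO-8601 dates and one row per
record.  Missing temperatures are encoded as empty fields and represented
in memory as NaN; no sentinel values such as -99.9 are used.  Temperatures
are stored in degrees Celsius at centi-degree (0.01 degC) precision, the
resolution of typical national station archives, which makes write/read
round trips exact.

Formats
-------
stations.csv    station_id,name,longitude,latitude,elevation_m,region
daily CSV       station_id,date,tmax_c,tmin_c,tmean_c
                (one file per ensemble member, named <model>__<scenario>.csv)
population.csv  scenario,region,year,population
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: The seven subregion codes of the station network, plus the national unit.
REGIONS = ("NE", "NC", "SC", "IM", "QT", "NW", "SW")
NATIONAL = "ECM"

#: Climate scenarios a member may carry.
CLIMATE_SCENARIOS = ("historical", "SSP245", "SSP585")
#: Socioeconomic scenarios a population table may carry.
POPULATION_SCENARIOS = ("SSP2", "SSP5")

DAILY_COLUMNS = ("tmax", "tmin", "tmean")

#: Number formatting for temperature fields (centi-degree dialect).
TEMP_FORMAT = "%.2f"


class ValidationError(ValueError):
    """Raised when an input file violates a format invariant.

    Carries ``errors``, a list of human-readable messages each naming the
    offending line number, so callers can report every problem at once.
    """

    def __init__(self, message: str, errors: list[str] | None = None):
        super().__init__(message if not errors else f"{message}: " + "; ".join(errors))
        self.errors = errors or []


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StationMeta:
    """Metadata for one observation station."""

    station_id: str
    longitude: float
    latitude: float
    elevation_m: float
    region: str
    name: str = ""

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"latitude {self.latitude} out of range for {self.station_id}")
        if self.region not in REGIONS:
            raise ValidationError(f"unknown region {self.region!r} for {self.station_id}")


@dataclass
class StationDailySeries:
    """One station's dated daily Tx/Tn/Tm record in degC.

    ``data`` is indexed by a gap-free daily ``DatetimeIndex`` with float
    columns ``tmax``, ``tmin``, ``tmean``; missing days are NaN in all
    three columns.
    """

    station_id: str
    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in DAILY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"daily series missing columns {missing}")
        if not isinstance(self.data.index, pd.DatetimeIndex):
            self.data = self.data.copy()
            self.data.index = pd.DatetimeIndex(self.data.index)
        if not self.data.index.is_monotonic_increasing or self.data.index.has_duplicates:
            raise ValidationError(f"dates not strictly increasing for {self.station_id}")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def tmax(self) -> pd.Series:
        return self.data["tmax"]

    @property
    def tmin(self) -> pd.Series:
        return self.data["tmin"]

    @property
    def tmean(self) -> pd.Series:
        return self.data["tmean"]

    def validate_ordering(self) -> None:
        """Check tmin <= tmean <= tmax on every non-missing day."""
        d = self.data.dropna()
        bad = d[(d["tmin"] > d["tmean"]) | (d["tmean"] > d["tmax"])]
        if len(bad):
            days = ", ".join(str(t.date()) for t in bad.index[:5])
            raise ValidationError(
                f"temperature ordering violated for {self.station_id} on {len(bad)} day(s) ({days} ...)"
            )


@dataclass
class EnsembleMember:
    """One (model, scenario) collection of station daily series."""

    model_name: str
    scenario: str
    series: dict[str, StationDailySeries] = field(default_factory=dict)

    def __post_init__(self):
        spans = {(s.dates[0], s.dates[-1]) for s in self.series.values() if len(s.dates)}
        if len(spans) > 1:
            raise ValidationError(
                f"member {self.model_name}/{self.scenario}: series cover different date spans"
            )

    @property
    def station_ids(self) -> list[str]:
        return sorted(self.series)

    def filename(self) -> str:
        return f"{self.model_name}__{self.scenario}.csv"


# ---------------------------------------------------------------------------
# Station metadata
# ---------------------------------------------------------------------------

def read_stations(path: str | Path) -> pd.DataFrame:
    """Read stations.csv into a DataFrame indexed by station_id."""
    df = pd.read_csv(path, dtype={"station_id": str, "name": str})
    required = {"station_id", "longitude", "latitude", "elevation_m", "region"}
    if not required.issubset(df.columns):
        raise ValidationError(f"stations file missing columns {sorted(required - set(df.columns))}")
    errors = []
    if df["station_id"].duplicated().any():
        dups = df.loc[df["station_id"].duplicated(), "station_id"].tolist()
        errors.append(f"duplicate station_id(s): {dups}")
    bad_lat = df.index[(df["latitude"] < -90) | (df["latitude"] > 90)]
    errors += [f"line {i + 2}: latitude out of range" for i in bad_lat]
    bad_reg = df.index[~df["region"].isin(REGIONS)]
    errors += [f"line {i + 2}: unknown region {df.loc[i, 'region']!r}" for i in bad_reg]
    if errors:
        raise ValidationError("invalid stations file", errors)
    if "name" not in df.columns:
        df["name"] = ""
    return df.set_index("station_id")


def write_stations(stations: pd.DataFrame, path: str | Path) -> None:
    cols = ["name", "longitude", "latitude", "elevation_m", "region"]
    out = stations.reset_index()[["station_id"] + cols]
    out.to_csv(path, index=False, float_format="%.4f")


def station_meta(stations: pd.DataFrame, station_id: str) -> StationMeta:
    row = stations.loc[station_id]
    return StationMeta(
        station_id=station_id,
        longitude=float(row["longitude"]),
        latitude=float(row["latitude"]),
        elevation_m=float(row["elevation_m"]),
        region=str(row["region"]),
        name=str(row.get("name", "")),
    )


# ---------------------------------------------------------------------------
# Daily series
# ---------------------------------------------------------------------------

def read_station_daily(path: str | Path, meta: pd.DataFrame | None = None
                       ) -> dict[str, StationDailySeries]:
    """Read one member's daily CSV into per-station series.

    Every row is either parsed or reported: malformed dates, unknown
    station ids (when ``meta`` is given) and rows with tmin > tmax raise a
    :class:`ValidationError` listing the 1-based file line numbers.
    """
    df = pd.read_csv(path, dtype={"station_id": str, "date": str})
    required = {"station_id", "date", "tmax_c", "tmin_c", "tmean_c"}
    if not required.issubset(df.columns):
        raise ValidationError(f"daily file missing columns {sorted(required - set(df.columns))}")

    errors: list[str] = []
    dates = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    for i in df.index[dates.isna() & df["date"].notna()]:
        errors.append(f"line {i + 2}: malformed date {df.loc[i, 'date']!r}")
    if meta is not None:
        unknown = ~df["station_id"].isin(meta.index)
        for i in df.index[unknown]:
            errors.append(f"line {i + 2}: unknown station_id {df.loc[i, 'station_id']!r}")
    bad_order = (df["tmin_c"] > df["tmax_c"]) & df["tmin_c"].notna() & df["tmax_c"].notna()
    for i in df.index[bad_order]:
        errors.append(f"line {i + 2}: tmin > tmax")
    if errors:
        raise ValidationError("invalid daily file", errors)

    df = df.assign(date=dates)
    out: dict[str, StationDailySeries] = {}
    for sid, grp in df.groupby("station_id", sort=True):
        data = (
            grp.set_index("date")[["tmax_c", "tmin_c", "tmean_c"]]
            .rename(columns={"tmax_c": "tmax", "tmin_c": "tmin", "tmean_c": "tmean"})
            .sort_index()
            .astype(float)
        )
        # re-index onto a gap-free daily grid so gaps become explicit NaN
        full = pd.date_range(data.index[0], data.index[-1], freq="D")
        data = data.reindex(full)
        out[str(sid)] = StationDailySeries(station_id=str(sid), data=data)
    return out


def write_station_daily(series: Mapping[str, StationDailySeries], path: str | Path) -> None:
    """Write per-station daily series as one tidy CSV (sorted by id, date)."""
    frames = []
    for sid in sorted(series):
        s = series[sid]
        f = s.data.rename(
            columns={"tmax": "tmax_c", "tmin": "tmin_c", "tmean": "tmean_c"}
        ).rename_axis("date").reset_index()
        f.insert(0, "station_id", sid)
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format=TEMP_FORMAT)


def read_member(path: str | Path, meta: pd.DataFrame | None = None) -> EnsembleMember:
    """Read a ``<model>__<scenario>.csv`` file into an :class:`EnsembleMember`."""
    stem = Path(path).stem
    try:
        model_name, scenario = stem.split("__")
    except ValueError as exc:
        raise ValidationError(f"member filename {stem!r} is not <model>__<scenario>") from exc
    return EnsembleMember(model_name=model_name, scenario=scenario,
                          series=read_station_daily(path, meta))


def write_member(member: EnsembleMember, out_dir: str | Path) -> Path:
    out = Path(out_dir) / member.filename()
    write_station_daily(member.series, out)
    return out


# ---------------------------------------------------------------------------
# Population tables
# ---------------------------------------------------------------------------

def read_population(path: str | Path) -> pd.DataFrame:
    """Read population.csv -> DataFrame (scenario, region, year, population)."""
    df = pd.read_csv(path, dtype={"scenario": str, "region": str})
    required = {"scenario", "region", "year", "population"}
    if not required.issubset(df.columns):
        raise ValidationError(f"population file missing columns {sorted(required - set(df.columns))}")
    errors = []
    for i in df.index[df["population"] < 0]:
        errors.append(f"line {i + 2}: negative population")
    dup = df.duplicated(subset=["scenario", "region", "year"])
    for i in df.index[dup]:
        errors.append(
            f"line {i + 2}: duplicate (scenario, region, year) "
            f"({df.loc[i, 'scenario']}, {df.loc[i, 'region']}, {df.loc[i, 'year']})"
        )
    if errors:
        raise ValidationError("invalid population file", errors)
    return df.astype({"year": int, "population": float})


def write_population(pop: pd.DataFrame, path: str | Path) -> None:
    out = pop[["scenario", "region", "year", "population"]].copy()
    out["population"] = out["population"].map(lambda v: f"{v:.0f}")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pipeline outputs
# ---------------------------------------------------------------------------

def write_outputs(tables: Mapping[str, pd.DataFrame], out_dir: str | Path,
                  summary: dict | None = None,
                  extra_files: Iterable[str] = ()) -> list[str]:
    """Write output tables (and optional summary.json); return the manifest.

    Column order is taken from each DataFrame; floats are written with
    Python's shortest round-tripping repr so ``read(write(x)) == x``.
    Output is deterministic for identical inputs.  ``extra_files`` are
    already-written files to record in the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = list(extra_files)
    for name in sorted(tables):
        fname = name if name.endswith(".csv") else f"{name}.csv"
        tables[name].to_csv(out_dir / fname, index=False)
        manifest.append(fname)
    if summary is not None:
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest.append("summary.json")
    with open(out_dir / "manifest.txt", "w") as fh:
        fh.write("\n".join(manifest) + "\n")
    return manifest
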