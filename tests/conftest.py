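"""Shared fixtures: tiny synthetic networks and handmade daily series."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import winterx as wx


def make_series(station_id: str, start: str, values=None, n: int | None = None,
                tmax=None, tmin=None, tmean=None) -> wx.StationDailySeries:
    """Build a daily series from explicit arrays or a constant value."""
    if values is not None:
        n = len(np.atleast_1d(values)) if n is None else n
        v = np.broadcast_to(np.atleast_1d(values), (n,)).astype(float)
        tmax, tmin, tmean = v + 4.0, v - 4.0, v
    dates = pd.date_range(start, periods=len(np.atleast_1d(tmax)), freq="D")
    data = pd.DataFrame({"tmax": np.asarray(tmax, dtype=float),
                         "tmin": np.asarray(tmin, dtype=float),
                         "tmean": np.asarray(tmean, dtype=float)}, index=dates)
    return wx.StationDailySeries(station_id=station_id, data=data)


def constant_winter(station_id: str, winter_year: int, tmean: float,
                    spread: float = 4.0) -> wx.WinterSeries:
    """A fully populated DJF window at a constant temperature."""
    start, end = wx.winter_window(winter_year)
    dates = pd.date_range(start, end, freq="D")
    data = pd.DataFrame({"tmax": tmean + spread, "tmin": tmean - spread,
                         "tmean": float(tmean)}, index=dates)
    return wx.WinterSeries(station_id=station_id, winter_year=winter_year,
                           data=data, complete=True)


@pytest.fixture(scope="session")
def network7() -> pd.DataFrame:
    return wx.generate_network(7, seed=11)


@pytest.fixture(scope="session")
def member7(network7) -> wx.EnsembleMember:
    spec = wx.ClimateScenarioSpec(name="SSP245", trend_tx=0.31, trend_tn=0.30)
    return wx.simulate_member(network7, 0, spec, (1990, 1999), seed=11)
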