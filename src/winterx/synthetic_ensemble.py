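"""Synthetic multi-model, multi-scenario station temperature ensembles.

Generates daily Tx/Tn/Tm series for a network of stations under a
minimal statistical model with every feature the downstream analysis
consumes:

* a station climatology (base temperature, latitudinal gradient, lapse
  rate with elevation) shared by all models,
* one additive bias per model, drawn once from a between-model spread,
* a seasonal sinusoid,
* AR(1) day-to-day noise with a stationary standard deviation,
* a linear warming trend applied after a scenario split year, with
  separate decadal rates for daily maxima and minima (moderate-emission
  pathways near 0.3 degC/decade, high-emission near 0.5 degC/decade),
* Tm as the Tx/Tn midpoint and a diurnal range that is a station
  constant plus small noise, so tmin <= tmean <= tmax holds by
  construction.

Regional population trajectories decline (or grow) linearly by decade
with optional noise, clipped at zero.

Seed policy: one master seed; per-(model, station) substreams are derived
with ``numpy.random.SeedSequence`` spawn keys, so any member is
reproducible in isolation and two scenarios sharing (model, seed) are
*identical* before the split year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .station_io import (
    REGIONS,
    EnsembleMember,
    StationDailySeries,
    ValidationError,
)

# Plausible coordinate boxes and elevation ranges (m) per subregion,
# used only to place synthetic stations.
_REGION_BOXES = {
    "NE": ((120.0, 132.0), (40.0, 52.0), (50.0, 600.0)),
    "NC": ((110.0, 120.0), (32.0, 42.0), (5.0, 1500.0)),
    "SC": ((105.0, 122.0), (18.0, 32.0), (5.0, 500.0)),
    "IM": ((97.0, 126.0), (37.0, 53.0), (900.0, 1500.0)),
    "QT": ((78.0, 103.0), (27.0, 39.0), (2500.0, 5000.0)),
    "NW": ((73.0, 110.0), (35.0, 50.0), (500.0, 2000.0)),
    "SW": ((97.0, 110.0), (21.0, 34.0), (300.0, 3000.0)),
}

_REF_LATITUDE = 35.0        # degN at which base_tmean applies
_LAPSE_RATE = 6.5e-3        # degC lost per metre of elevation
_COLDEST_DOY = 15           # mid-January trough of the seasonal cycle


@dataclass(frozen=True)
class ClimateScenarioSpec:
    """Statistical description of one emission scenario.

    Trends are in degC per decade and act only after ``split_year``
    (the historical period is trend-free).  A moderate-emission pathway
    stabilizes its forcing late in the century: after
    ``stabilization_year`` (if set) the warming trend stops and the
    climate plateaus, which is what lets a trailing climatological
    baseline catch up with it.  ``daily_autocorrelation`` is the AR(1)
    coefficient of the daily residual.
    """

    name: str
    trend_tx: float
    trend_tn: float
    split_year: int = 2015
    stabilization_year: int | None = None
    seasonal_amplitude: float = 12.0
    daily_noise_sd: float = 3.5
    daily_autocorrelation: float = 0.7
    model_bias_sd: float = 1.0
    latitudinal_gradient: float = -0.7
    base_tmean: float = 8.0
    diurnal_range: float = 8.0

    def __post_init__(self):
        if self.daily_noise_sd < 0:
            raise ValidationError("daily_noise_sd must be >= 0")
        if not 0.0 <= self.daily_autocorrelation < 1.0:
            raise ValidationError("daily_autocorrelation must be in [0, 1)")
        if self.seasonal_amplitude < 0 or self.model_bias_sd < 0:
            raise ValidationError("amplitudes and spreads must be >= 0")


#: Study-condition defaults: a moderate pathway warming ~0.31/0.30 degC per
#: decade (Tx/Tn) that stabilizes around 2070, and a high pathway warming
#: ~0.51/0.49 that keeps rising; the scenarios diverge in 2015.
DEFAULT_SCENARIOS = {
    "SSP245": ClimateScenarioSpec(name="SSP245", trend_tx=0.31, trend_tn=0.30,
                                  stabilization_year=2080),
    "SSP585": ClimateScenarioSpec(name="SSP585", trend_tx=0.51, trend_tn=0.49),
}


@dataclass(frozen=True)
class PopulationScenarioSpec:
    """Linear-trend population pathway for the seven regions.

    ``baseline`` holds persons per region at the first decade anchor;
    ``trend`` persons per decade (negative = decline); ``noise_sd`` the
    anchor-level Gaussian jitter in persons.
    """

    name: str
    baseline: Mapping[str, float]
    trend: Mapping[str, float]
    noise_sd: float = 0.0

    def __post_init__(self):
        for reg in self.baseline:
            if reg not in REGIONS:
                raise ValidationError(f"unknown region {reg!r} in population spec")
        if set(self.baseline) != set(self.trend):
            raise ValidationError("baseline and trend must cover the same regions")


# 2010-ish regional populations (persons) and the decadal change rates of
# the two socioeconomic pathways (units: persons per decade; the moderate
# pathway totals about -26.3 M/decade nationally, the high about -61.4 M).
_POP_BASELINE = {
    "NE": 110e6, "NC": 367e6, "SC": 596e6, "IM": 25e6,
    "QT": 8.7e6, "NW": 31e6, "SW": 190e6,
}
DEFAULT_POPULATION_SCENARIOS = {
    "SSP2": PopulationScenarioSpec(
        name="SSP2", baseline=_POP_BASELINE,
        trend={"NE": -10.215e6, "NC": -10.498e6, "SC": -2.253e6, "IM": -1.265e6,
               "QT": -0.040e6, "NW": 1.245e6, "SW": -2.823e6},
    ),
    "SSP5": PopulationScenarioSpec(
        name="SSP5", baseline=_POP_BASELINE,
        trend={"NE": -10.546e6, "NC": -20.407e6, "SC": -13.546e6, "IM": -1.586e6,
               "QT": -0.287e6, "NW": -1.242e6, "SW": -13.498e6},
    ),
}


# ---------------------------------------------------------------------------
# Station network
# ---------------------------------------------------------------------------

def generate_network(n_stations: int,
                     region_layout: Mapping[str, float] | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Generate synthetic station metadata spread over the seven regions.

    ``region_layout`` maps region code -> relative weight (default equal).
    Station counts are a deterministic largest-remainder allocation of the
    weights, so the same (n, layout) always yields the same counts; the
    coordinates depend only on ``seed``.
    """
    if n_stations < 1:
        raise ValidationError("n_stations must be >= 1")
    layout = dict.fromkeys(REGIONS, 1.0) if region_layout is None else dict(region_layout)
    for reg in layout:
        if reg not in REGIONS:
            raise ValidationError(f"unknown region {reg!r} in layout")
    if n_stations < len(layout):
        raise ValidationError(
            f"n_stations={n_stations} cannot give each of {len(layout)} regions a station")

    total = sum(layout.values())
    quotas = {r: n_stations * w / total for r, w in layout.items()}
    counts = {r: max(1, int(np.floor(q))) for r, q in quotas.items()}
    # largest-remainder top-up, alphabetical tie-break for determinism
    while sum(counts.values()) < n_stations:
        rem = {r: quotas[r] - counts[r] for r in counts}
        counts[max(sorted(rem), key=lambda r: rem[r])] += 1
    while sum(counts.values()) > n_stations:
        rem = {r: quotas[r] - counts[r] for r in counts if counts[r] > 1}
        counts[min(sorted(rem), key=lambda r: rem[r])] -= 1

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    rows = []
    for region in sorted(counts):
        (lon0, lon1), (lat0, lat1), (el0, el1) = _REGION_BOXES[region]
        for i in range(counts[region]):
            rows.append({
                "station_id": f"{region}{i + 1:03d}",
                "name": f"synthetic-{region}-{i + 1}",
                "longitude": round(float(rng.uniform(lon0, lon1)), 4),
                "latitude": round(float(rng.uniform(lat0, lat1)), 4),
                "elevation_m": round(float(rng.uniform(el0, el1)), 1),
                "region": region,
            })
    return pd.DataFrame(rows).set_index("station_id")


# ---------------------------------------------------------------------------
# Daily series
# ---------------------------------------------------------------------------

def _station_climatology(lat: float, elev: float, spec: ClimateScenarioSpec) -> float:
    return spec.base_tmean + spec.latitudinal_gradient * (lat - _REF_LATITUDE) - _LAPSE_RATE * elev


def _ar1(n: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise of marginal standard deviation ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    z = rng.standard_normal(n)
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    # seed the recursion with a draw from the stationary distribution
    x, _ = lfilter([innov_sd], [1.0, -phi], z[1:], zi=[phi * sd * z[0]])
    return np.concatenate(([sd * z[0]], x))


def simulate_member(network: pd.DataFrame,
                    model_index: int,
                    scenario_spec: ClimateScenarioSpec,
                    year_range: tuple[int, int],
                    seed: int = 0,
                    model_name: str | None = None) -> EnsembleMember:
    """Simulate one (model, scenario) member over calendar years.

    The model bias is drawn once per (seed, model_index) — independent of
    the scenario — and the per-station noise streams are keyed on
    (seed, model_index, station), so two scenario specs that agree before
    their split year produce *identical* members up to the split.
    """
    if len(network) == 0:
        raise ValidationError("empty station network")
    y0, y1 = year_range
    if y1 < y0:
        raise ValidationError("year_range end before start")
    name = model_name if model_name is not None else f"GCM{model_index + 1:02d}"

    offset_rng = np.random.default_rng(np.random.SeedSequence([seed, 1, model_index]))
    model_offset = float(offset_rng.standard_normal()) * scenario_spec.model_bias_sd

    # include the December before the first year so its winter window is complete
    dates = pd.date_range(f"{y0 - 1}-12-01", f"{y1}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    # fractional years of accumulated warming: none before the split, and
    # frozen after the stabilization year when the pathway plateaus
    frac_year = dates.year.to_numpy() + (doy - 1) / 365.25
    if scenario_spec.stabilization_year is not None:
        frac_year = np.minimum(frac_year, float(scenario_spec.stabilization_year))
    yrs_since_split = np.maximum(0.0, frac_year - scenario_spec.split_year)
    seasonal = -scenario_spec.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - _COLDEST_DOY) / 365.25)

    series: dict[str, StationDailySeries] = {}
    for st_index, sid in enumerate(network.index):
        row = network.loc[sid]
        base = _station_climatology(float(row["latitude"]), float(row["elevation_m"]),
                                    scenario_spec)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2, model_index, st_index]))
        noise = _ar1(len(dates), scenario_spec.daily_autocorrelation,
                     scenario_spec.daily_noise_sd, rng)
        drange = scenario_spec.diurnal_range + 0.1 * scenario_spec.daily_noise_sd * \
            rng.standard_normal(len(dates))
        drange = np.clip(drange, 0.0, None)

        centre = base + model_offset + seasonal + noise
        tx = centre + drange / 2.0 + scenario_spec.trend_tx * yrs_since_split / 10.0
        tn = centre - drange / 2.0 + scenario_spec.trend_tn * yrs_since_split / 10.0
        tm = (tx + tn) / 2.0
        data = pd.DataFrame(
            {"tmax": np.round(tx, 2), "tmin": np.round(tn, 2), "tmean": np.round(tm, 2)},
            index=dates)
        series[sid] = StationDailySeries(station_id=sid, data=data)
    return EnsembleMember(model_name=name, scenario=scenario_spec.name, series=series)


def simulate_ensemble(network: pd.DataFrame,
                      scenario_specs: Mapping[str, ClimateScenarioSpec],
                      n_models: int,
                      year_range: tuple[int, int],
                      seed: int = 0) -> list[EnsembleMember]:
    """Simulate all (model, scenario) members for one network."""
    members = []
    for scen in sorted(scenario_specs):
        for m in range(n_models):
            members.append(simulate_member(network, m, scenario_specs[scen],
                                           year_range, seed=seed))
    return members


def simulate_observations(network: pd.DataFrame,
                          scenario_spec: ClimateScenarioSpec,
                          year_range: tuple[int, int],
                          seed: int = 0) -> EnsembleMember:
    """Simulate a pseudo-observation record (its own noise stream, no bias)."""
    spec = ClimateScenarioSpec(
        name="historical", trend_tx=scenario_spec.trend_tx, trend_tn=scenario_spec.trend_tn,
        split_year=scenario_spec.split_year,
        seasonal_amplitude=scenario_spec.seasonal_amplitude,
        daily_noise_sd=scenario_spec.daily_noise_sd,
        daily_autocorrelation=scenario_spec.daily_autocorrelation,
        model_bias_sd=0.0,
        latitudinal_gradient=scenario_spec.latitudinal_gradient,
        base_tmean=scenario_spec.base_tmean, diurnal_range=scenario_spec.diurnal_range)
    return simulate_member(network, model_index=999_000, scenario_spec=spec,
                           year_range=year_range, seed=seed, model_name="OBS")


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------

def simulate_population(pop_spec: PopulationScenarioSpec,
                        decades: Sequence[int],
                        seed: int = 0) -> pd.DataFrame:
    """Generate decadal population anchors per region.

    ``decades`` lists anchor years (e.g. 2020, 2030, ...); trajectories are
    baseline + trend * (decades since first anchor) + noise, clipped at 0.
    """
    if len(decades) == 0:
        raise ValidationError("decades must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    d0 = decades[0]
    rows = []
    for region in sorted(pop_spec.baseline):
        for year in decades:
            k = (year - d0) / 10.0
            value = pop_spec.baseline[region] + pop_spec.trend[region] * k
            if pop_spec.noise_sd > 0:
                value += pop_spec.noise_sd * rng.standard_normal()
            rows.append({"scenario": pop_spec.name, "region": region,
                         "year": int(year), "population": float(max(0.0, round(value)))})
    return pd.DataFrame(rows)
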