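"""Person-time exposure to warm-winter events and derived statistics.

Exposure for a unit (region or the national aggregate) over a decade is
the person-time sum

    E = sum over the decade's winters of  1[warm winter] * population(year)

with annual population linearly interpolated between decadal anchors.
The national row is computed from the national warm-winter classification
with national population — not as the sum of the regional rows, because
regional and national event indicators differ.

Derived statistics (all in percent, reported at 2-decimal precision with
half-away-from-zero rounding):

* ``trend_ratio(a, b)``      — relative increase of trend b over trend a,
* ``relative_change(e0, e1)``— remaining share and decline between decades,
* ``share_of_total``         — a region's share of the national exposure,
* ``avoided_risk``           — exposure avoided under the lower-emission
  pathway relative to the higher one.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .station_io import REGIONS, ValidationError
from .warm_winter import WarmWinterRecord


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed report tables)."""
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(value)))
    return float(d.copy_abs().quantize(q, rounding=ROUND_HALF_UP) * (1 if d >= 0 else -1))


# ---------------------------------------------------------------------------
# Population interpolation
# ---------------------------------------------------------------------------

def annual_population(pop: pd.DataFrame, scenario: str, region: str,
                      years: Sequence[int]) -> np.ndarray:
    """Annual population by linear interpolation between decadal anchors.

    Years outside the anchor span take the nearest anchor value.
    """
    sub = pop[(pop["scenario"] == scenario) & (pop["region"] == region)]
    if sub.empty:
        raise ValidationError(f"no population anchors for ({scenario}, {region})")
    sub = sub.sort_values("year")
    return np.interp(np.asarray(years, dtype=float),
                     sub["year"].to_numpy(dtype=float),
                     sub["population"].to_numpy(dtype=float))


def national_population(pop: pd.DataFrame, scenario: str,
                        years: Sequence[int]) -> np.ndarray:
    """National annual population: the sum of the regional interpolations."""
    return np.sum([annual_population(pop, scenario, r, years)
                   for r in sorted(pop.loc[pop["scenario"] == scenario, "region"].unique())],
                  axis=0)


# ---------------------------------------------------------------------------
# Exposure accounting
# ---------------------------------------------------------------------------

def decadal_exposure(records: Iterable[WarmWinterRecord], unit_id: str,
                     decade: int, population_by_year: Mapping[int, float]) -> float:
    """Person-times of one unit over winters ``decade`` .. ``decade+9``.

    ``population_by_year`` must cover every winter year of the decade.
    """
    total = 0.0
    for r in records:
        if r.unit_id != unit_id or not decade <= r.winter_year <= decade + 9:
            continue
        if r.grade in ("warm", "strong"):
            if r.winter_year not in population_by_year:
                raise ValidationError(f"no population for year {r.winter_year}")
            total += float(population_by_year[r.winter_year])
    return total


def exposure_table(records: Sequence[WarmWinterRecord], pop: pd.DataFrame,
                   pop_scenario: str, decades: Sequence[int],
                   climate_scenario: str = "") -> pd.DataFrame:
    """Region x decade person-times, with a separately computed national row.

    ``decades`` lists decade-start winter years (2021 covers 2021–2030).
    Regional rows use regional grades and regional population; the ECM row
    uses the national grade with the national population.
    """
    years = [y for d in decades for y in range(d, d + 10)]
    rows = []
    regions = sorted(pop.loc[pop["scenario"] == pop_scenario, "region"].unique())
    for region in regions:
        pop_years = dict(zip(years, annual_population(pop, pop_scenario, region, years)))
        for d in decades:
            rows.append({
                "scenario": climate_scenario or pop_scenario, "region": region,
                "decade": d,
                "person_times": decadal_exposure(records, region, d, pop_years)})
    nat_years = dict(zip(years, national_population(pop, pop_scenario, years)))
    for d in decades:
        rows.append({
            "scenario": climate_scenario or pop_scenario, "region": "ECM", "decade": d,
            "person_times": decadal_exposure(records, "ECM", d, nat_years)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Derived statistics
# ---------------------------------------------------------------------------

def trend_ratio(trend_a: float, trend_b: float) -> float:
    """Percent increase of trend b relative to trend a, sign preserved."""
    if trend_a == 0.0:
        raise ValidationError("reference trend is zero")
    return round_half_away(100.0 * (trend_b - trend_a) / trend_a)


def relative_change(e_start: float, e_end: float) -> tuple[float, float]:
    """(remaining %, decline %) of an exposure between two decades."""
    if e_start <= 0.0:
        raise ValidationError("starting exposure must be positive")
    remaining = 100.0 * e_end / e_start
    return round_half_away(remaining), round_half_away(100.0 - remaining)


def share_of_total(part: float, total: float) -> float:
    """Percent share of a part in its containing total."""
    if total <= 0.0:
        raise ValidationError("total must be positive")
    return round_half_away(100.0 * part / total)


def avoided_risk(e_low_scenario: float, e_high_scenario: float) -> float:
    """Percent exposure avoided under the lower-emission pathway."""
    if e_high_scenario <= 0.0:
        raise ValidationError("high-scenario exposure must be positive")
    return round_half_away(100.0 * (e_high_scenario - e_low_scenario) / e_high_scenario)
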