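"""Agreement metrics between modelled and observed temperature series.

Four metrics are computed per (model, variable) over paired samples:

* ``r``    — Pearson product-moment correlation,
* ``RMSE`` — root mean square error, sqrt[(1/N) sum (Obs - M)^2],
* ``VE``   — volume error, (sum Obs - sum M) / sum Obs,
* ``RSR``  — RMSE divided by the observations' standard deviation, both
  with the 1/N (population) convention, so RSR = RMSE / sd_pop(Obs).

Pairs with a missing value on either side are dropped.  ``VE`` is
undefined when the observed sum is zero, and ``r``/``RSR`` when the
observations have zero variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .station_io import EnsembleMember, ValidationError


@dataclass(frozen=True)
class MetricReport:
    """Agreement of one model series with observations."""

    model_name: str
    variable: str
    r: float
    rmse: float
    ve: float
    rsr: float
    n: int


def evaluate(obs: Sequence[float], model: Sequence[float],
             model_name: str = "", variable: str = "") -> MetricReport:
    """Compute r, RMSE, VE and RSR for one paired series."""
    o = np.asarray(obs, dtype=float)
    m = np.asarray(model, dtype=float)
    if o.shape != m.shape:
        raise ValidationError("observed and modelled series differ in length")
    keep = ~(np.isnan(o) | np.isnan(m))
    o, m = o[keep], m[keep]
    n = len(o)
    if n < 2:
        raise ValidationError("evaluation needs >= 2 paired values")

    obs_sd = float(np.std(o))  # population (1/N) convention
    if obs_sd == 0.0:
        raise ValidationError("observations have zero variance: r and RSR undefined")
    obs_sum = float(o.sum())
    if obs_sum == 0.0:
        raise ValidationError("observed sum is zero: VE undefined")

    rmse = float(np.sqrt(np.mean((o - m) ** 2)))
    r = float(np.corrcoef(o, m)[0, 1])
    ve = float((obs_sum - m.sum()) / obs_sum)
    rsr = rmse / obs_sd
    return MetricReport(model_name=model_name, variable=variable,
                        r=r, rmse=rmse, ve=ve, rsr=rsr, n=n)


def evaluate_member(obs_member: EnsembleMember, member: EnsembleMember,
                    period: tuple[int, int] | None = None,
                    variables: Sequence[str] = ("tmax", "tmin", "tmean")
                    ) -> list[MetricReport]:
    """Evaluate one member against observations on pooled daily values.

    Daily values of all common stations are concatenated per variable over
    the overlap (optionally restricted to calendar years ``period``).
    """
    common = sorted(set(obs_member.series) & set(member.series))
    if not common:
        raise ValidationError("no common stations between member and observations")
    reports = []
    for var in variables:
        obs_parts, mod_parts = [], []
        for sid in common:
            o = obs_member.series[sid].data[var]
            m = member.series[sid].data[var]
            idx = o.index.intersection(m.index)
            if period is not None:
                idx = idx[(idx.year >= period[0]) & (idx.year <= period[1])]
            obs_parts.append(o.loc[idx].to_numpy())
            mod_parts.append(m.loc[idx].to_numpy())
        reports.append(evaluate(np.concatenate(obs_parts), np.concatenate(mod_parts),
                                model_name=member.model_name, variable=var))
    return reports


def reports_to_frame(reports: Sequence[MetricReport]) -> pd.DataFrame:
    """Tidy frame (model, variable, r, rmse, ve, rsr, n)."""
    return pd.DataFrame(
        [{"model": rep.model_name, "variable": rep.variable, "r": rep.r,
          "rmse": rep.rmse, "ve": rep.ve, "rsr": rep.rsr, "n": rep.n}
         for rep in reports])
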