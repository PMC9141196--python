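"""Partition of multi-model projection spread into internal variability,
model uncertainty and scenario uncertainty.

Each member's annual series is decomposed as

    X_{m,s,t} = x_{m,s,t} + i_{m,s} + eps_{m,s,t}

where ``i`` is the mean over a reference period, ``x`` a smooth
(degree-4 polynomial) least-squares fit to the anomaly, and ``eps`` the
residual; the reconstruction is exact by construction.  The three
variance components are

* ``V``     — internal variability: the variance of a model's residuals
  pooled over scenarios and time, averaged over models (constant in t),
* ``M(t)``  — model uncertainty: the across-model variance of the smooth
  fits, averaged over scenarios,
* ``S(t)``  — scenario uncertainty: the across-scenario variance of the
  model-mean smooth fit,

with total ``T(t) = V + M(t) + S(t)`` and fractional contributions
``f = component / T``.  Variances across models and scenarios use the
population (1/N) convention, because the ensemble at hand *is* the
population under study; this is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .station_io import ValidationError

DEFAULT_POLY_DEGREE = 4
DEFAULT_REFERENCE = (1995, 2014)


@dataclass
class MemberDecomposition:
    """Smooth fit + reference offset + residuals of one (model, scenario)."""

    model: str
    scenario: str
    years: np.ndarray
    offset: float               # i_{m,s}: mean over the reference period
    smooth: np.ndarray          # x_{m,s,t}: polynomial fit to the anomaly
    residual: np.ndarray        # eps_{m,s,t}

    def reconstruct(self) -> np.ndarray:
        return self.smooth + self.offset + self.residual


@dataclass
class UncertaintyCurves:
    """Time-resolved variance components and their fractions."""

    years: np.ndarray
    internal: float             # V, squared units
    model: np.ndarray           # M(t)
    scenario: np.ndarray        # S(t)

    @property
    def total(self) -> np.ndarray:
        return self.internal + self.model + self.scenario

    def fractions(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        t = self.total
        if np.any(t <= 0.0):
            raise ValidationError("total uncertainty is zero at some year")
        return self.internal / t, self.model / t, self.scenario / t

    def to_frame(self) -> pd.DataFrame:
        f_v, f_m, f_s = self.fractions()
        return pd.DataFrame({
            "year": self.years.astype(int), "V": self.internal,
            "M": self.model, "S": self.scenario, "total": self.total,
            "f_V": f_v, "f_M": f_m, "f_S": f_s,
        })


def fit_member(years: Sequence[int], values: Sequence[float],
               reference_period: tuple[int, int] = DEFAULT_REFERENCE,
               degree: int = DEFAULT_POLY_DEGREE,
               model: str = "", scenario: str = "") -> MemberDecomposition:
    """Decompose one member's annual series into offset + smooth + residual."""
    y = np.asarray(years, dtype=float)
    x = np.asarray(values, dtype=float)
    if len(y) != len(x):
        raise ValidationError("years and values differ in length")
    if len(x) < max(20, degree + 1):
        raise ValidationError(f"need >= {max(20, degree + 1)} annual values, got {len(x)}")
    ref = (y >= reference_period[0]) & (y <= reference_period[1])
    if not ref.any():
        raise ValidationError(f"reference period {reference_period} outside the span")
    offset = float(x[ref].mean())
    anomaly = x - offset
    tc = y - y.mean()  # centred time axis for numerical stability
    coeffs = np.polynomial.polynomial.polyfit(tc, anomaly, degree)
    smooth = np.polynomial.polynomial.polyval(tc, coeffs)
    return MemberDecomposition(model=model, scenario=scenario, years=y.astype(int),
                               offset=offset, smooth=smooth, residual=anomaly - smooth)


def internal_variability(decomps: Iterable[MemberDecomposition], ddof: int = 0) -> float:
    """V: residual variance pooled per model over scenarios and time, then
    averaged over models (a single time-constant scalar)."""
    decomps = list(decomps)
    if not decomps:
        raise ValidationError("no member decompositions")
    per_model: dict[str, list[np.ndarray]] = {}
    for d in decomps:
        per_model.setdefault(d.model, []).append(d.residual)
    variances = [float(np.var(np.concatenate(residuals), ddof=ddof))
                 for residuals in per_model.values()]
    return float(np.mean(variances))


def model_uncertainty(decomps: Iterable[MemberDecomposition], ddof: int = 0) -> np.ndarray:
    """M(t): across-model variance of the smooth fits, averaged over scenarios."""
    decomps = list(decomps)
    scenarios = sorted({d.scenario for d in decomps})
    curves = []
    for s in scenarios:
        fits = np.vstack([d.smooth for d in decomps if d.scenario == s])
        if fits.shape[0] < 2:
            raise ValidationError(f"model uncertainty needs >= 2 models (scenario {s!r})")
        curves.append(np.var(fits, axis=0, ddof=ddof))
    return np.mean(curves, axis=0)


def scenario_uncertainty(decomps: Iterable[MemberDecomposition], ddof: int = 0) -> np.ndarray:
    """S(t): across-scenario variance of the model-mean smooth fit."""
    decomps = list(decomps)
    scenarios = sorted({d.scenario for d in decomps})
    if len(scenarios) < 2:
        raise ValidationError("scenario uncertainty needs >= 2 scenarios")
    means = np.vstack([
        np.mean(np.vstack([d.smooth for d in decomps if d.scenario == s]), axis=0)
        for s in scenarios])
    return np.var(means, axis=0, ddof=ddof)


def partition(decomps: Sequence[MemberDecomposition], ddof: int = 0) -> UncertaintyCurves:
    """Full V / M(t) / S(t) decomposition of an aligned set of members."""
    decomps = list(decomps)
    years = decomps[0].years
    for d in decomps[1:]:
        if not np.array_equal(d.years, years):
            raise ValidationError("member decompositions are misaligned in time")
    return UncertaintyCurves(
        years=years,
        internal=internal_variability(decomps, ddof=ddof),
        model=model_uncertainty(decomps, ddof=ddof),
        scenario=scenario_uncertainty(decomps, ddof=ddof),
    )
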