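"""Mann–Kendall trend test, Theil–Sen decadal slope, and the
elevation–warming-rate correlation.

The MK statistic is the pairwise sign sum

    S = sum_{k<j} sgn(x_j - x_k),

its variance carries the tie correction

    Var(S) = [n(n-1)(2n+5) - sum_j t_j (t_j - 1)(2 t_j + 5)] / 18

over groups of ``t_j`` tied values, and the standardised statistic uses
the +-1 continuity correction:

    Z = (S - 1)/sqrt(Var S)  if S > 0,   0 if S = 0,
        (S + 1)/sqrt(Var S)  if S < 0.

The companion slope estimate is the Theil–Sen median of all pairwise
slopes, reported per decade (the conventional degC/10a unit); ordinary
least squares is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm, pearsonr

from .station_io import ValidationError


@dataclass(frozen=True)
class TrendResult:
    """MK test outcome with its companion decadal slope."""

    s: int
    var_s: float
    z: float
    p_two_sided: float
    slope_per_decade: float
    n: int

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_two_sided < alpha


def _clean(series: Sequence[float], t: Sequence[float] | None):
    x = np.asarray(series, dtype=float)
    time = np.arange(len(x), dtype=float) if t is None else np.asarray(t, dtype=float)
    keep = ~np.isnan(x)
    x, time = x[keep], time[keep]
    if len(np.unique(time)) != len(time):
        raise ValidationError("timestamp ties are not supported")
    order = np.argsort(time)
    return x[order], time[order]


def mk_statistic(x: np.ndarray) -> tuple[int, float]:
    """(S, Var S) of the Mann–Kendall test, with tie-corrected variance."""
    n = len(x)
    diff_sign = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diff_sign, k=1).sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5)
             - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    return s, float(var_s)


def mk_test(series: Sequence[float], t: Sequence[float] | None = None,
            time_step: float = 1.0) -> TrendResult:
    """Mann–Kendall trend test with Theil–Sen decadal slope.

    ``time_step`` is the spacing of the (implicit) time axis in years;
    missing values are dropped.  Requires n >= 4 after cleaning.
    """
    x, time = _clean(series, t)
    n = len(x)
    if n < 4:
        raise ValidationError(f"Mann-Kendall test needs n >= 4, got {n}")
    s, var_s = mk_statistic(x)
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * norm.sf(abs(z))
    slope = sen_slope(x, t=time * time_step)
    return TrendResult(s=s, var_s=var_s, z=float(z), p_two_sided=float(p),
                       slope_per_decade=slope, n=n)


def sen_slope(series: Sequence[float], t: Sequence[float] | None = None,
              per: float = 10.0) -> float:
    """Theil–Sen slope: the median of all pairwise slopes, per ``per`` years.

    The time axis ``t`` is in years (defaults to 0, 1, 2, ...); the result
    is in units per decade by default.
    """
    x, time = _clean(series, t)
    if len(x) < 2:
        raise ValidationError("Sen slope needs n >= 2")
    dx = x[None, :] - x[:, None]
    dt = time[None, :] - time[:, None]
    iu = np.triu_indices(len(x), k=1)
    slopes = dx[iu] / dt[iu]
    return float(np.median(slopes) * per)


def ols_slope(series: Sequence[float], t: Sequence[float] | None = None,
              per: float = 10.0) -> float:
    """Ordinary least-squares slope per ``per`` years, for comparison."""
    x, time = _clean(series, t)
    if len(x) < 2:
        raise ValidationError("OLS slope needs n >= 2")
    b, _ = np.polyfit(time, x, 1)
    return float(b * per)


def elevation_correlation(slopes: Sequence[float], elevations: Sequence[float]
                          ) -> tuple[float, float]:
    """Pearson r (and two-sided p) between warming rates and elevations."""
    s = np.asarray(slopes, dtype=float)
    e = np.asarray(elevations, dtype=float)
    keep = ~(np.isnan(s) | np.isnan(e))
    s, e = s[keep], e[keep]
    if len(s) < 3:
        raise ValidationError("elevation correlation needs >= 3 stations")
    if np.std(s) == 0.0 or np.std(e) == 0.0:
        raise ValidationError("zero variance in slopes or elevations")
    r, p = pearsonr(s, e)
    return float(r), float(p)
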