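"""Scaffold degradation kinetics: exponential decay fits and threshold times.

Hydrolytic degradation of the polymer scaffold is summarized by sparse
(time, value) series — tensile strength in newtons and weight-average
molecular weight (Mw) in daltons. First-order hydrolysis motivates a
single-exponential law v(t) = v0 * exp(-k t), fitted as a least-squares line
on (t, ln v). The fit quality is always reported (RMSE in log space) because
real series can depart from a single exponential — the late-time Mw plateau
being the standard example — and a silent fit would hide that.

Threshold-crossing utilities answer "when is half the strength gone?"
(time_to_fraction) and "when is the strength below X?" (first_time_below),
either by linear interpolation between the measured points or from the
fitted rate constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import NotCrossedError, ValidationError

__all__ = ["DecaySeries", "DecayFit", "fit_exponential", "time_to_fraction",
           "first_time_below"]


@dataclass
class DecaySeries:
    """Positive-valued decay measurements at strictly increasing times (weeks)."""

    times: np.ndarray
    values: np.ndarray
    quantity: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 3:
            raise ValidationError("times: need >= 3 points")
        if len(self.times) != len(self.values):
            raise ValidationError("values: length must match times")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times: must be strictly increasing")
        if np.any(self.values <= 0) or not np.all(np.isfinite(self.values)):
            raise ValidationError("values: must be positive and finite")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class DecayFit:
    """Single-exponential fit v(t) = v0 * exp(-k t).

    ``k`` is the per-week rate constant, ``rmse`` the root-mean-square
    residual of ln(v) around the fitted line. ``half_life`` is ln(2)/k, or
    infinity for a non-decaying (k <= 0) fit.
    """

    model: str
    v0: float
    k: float
    rmse: float

    @property
    def half_life(self) -> float:
        if self.k <= 0:
            return math.inf
        return math.log(2.0) / self.k


def fit_exponential(series: DecaySeries) -> DecayFit:
    """Fit the first-order decay law by log-linear least squares."""
    logv = np.log(series.values)
    res = stats.linregress(series.times, logv)
    k = -float(res.slope)
    v0 = float(np.exp(res.intercept))
    resid = logv - (res.intercept + res.slope * series.times)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return DecayFit(model="exponential", v0=v0, k=k, rmse=rmse)


def time_to_fraction(series: DecaySeries, fraction: float,
                     method: str = "interpolate") -> float:
    """Time (weeks) at which the value first falls to ``fraction`` of v(0).

    ``method='interpolate'`` (default) interpolates linearly in value between
    the two measured points that bracket the crossing — the way a "half the
    strength is gone between weeks 2 and 3" reading comes straight off the
    measured table. ``method='fit'`` uses the fitted rate: ln(1/f)/k.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValidationError("fraction: must be in (0, 1]")
    if method not in ("interpolate", "fit"):
        raise ValidationError(f"method: unknown '{method}'")

    if method == "fit":
        fit = fit_exponential(series)
        if fit.k <= 0:
            raise NotCrossedError("fitted rate is non-positive; threshold never reached")
        return math.log(1.0 / fraction) / fit.k

    target = fraction * series.values[0]
    return _first_crossing(series, target)


def first_time_below(series: DecaySeries, absolute_threshold: float) -> float:
    """Earliest measured timepoint with value <= ``absolute_threshold`` (weeks).

    No interpolation: this reads the measured table. Raises NotCrossedError
    when the series never reaches the threshold.
    """
    below = series.values <= absolute_threshold
    if not np.any(below):
        raise NotCrossedError(
            f"series never falls to {absolute_threshold} "
            f"(minimum observed: {series.values.min()})"
        )
    return float(series.times[int(np.argmax(below))])


def _first_crossing(series: DecaySeries, target: float) -> float:
    """First time the piecewise-linear interpolant of the series hits target."""
    v = series.values
    t = series.times
    if v[0] <= target:
        return float(t[0])
    idx = np.nonzero(v <= target)[0]
    if len(idx) == 0:
        raise NotCrossedError(
            f"series never falls to {target} (minimum observed: {v.min()})"
        )
    j = int(idx[0])
    frac = (v[j - 1] - target) / (v[j - 1] - v[j])
    return float(t[j - 1] + frac * (t[j] - t[j - 1]))
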