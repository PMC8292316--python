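"""Circular statistics for time-of-day data.

Clock times live on the 24-hour circle: midnight corresponds to angle 0 and
noon to pi.  Averaging bedtimes linearly is wrong whenever a sample straddles
midnight (the linear mean of 23:00 and 01:00 is noon); every time-of-day
aggregation in this package therefore routes through the functions here.

The module provides the hour/angle projection, circular means and bout
midpoints, a three-regime maximum-likelihood approximation for the von Mises
concentration kappa, and the parametric Watson-Williams multisample test for
equality of circular mean directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AngleSeries",
    "CircularSummary",
    "WatsonWilliamsResult",
    "LowConcentrationWarning",
    "hours_to_angle",
    "angle_to_hours",
    "circular_mean",
    "circular_midpoint",
    "estimate_kappa",
    "watson_williams",
    "wrapped_diff_hours",
]

_TWO_PI = 2.0 * np.pi


class LowConcentrationWarning(UserWarning):
    """Sample too dispersed for the von Mises assumptions to be trustworthy."""


@dataclass(frozen=True)
class AngleSeries:
    """A set of time-of-day values as angles in radians on [0, 2*pi)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", np.mod(arr, _TWO_PI))

    @classmethod
    def from_hours(cls, hours) -> "AngleSeries":
        return cls(hours_to_angle(np.asarray(hours, dtype=float)))

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class CircularSummary:
    """Mean direction and concentration of a circular sample.

    ``mean_direction`` is in radians on [0, 2*pi); ``mean_hours`` is the same
    direction projected to clock hours; ``resultant_length`` is the mean
    resultant length r in [0, 1] (1 = all angles identical, 0 = balanced).
    ``mean_direction``/``mean_hours`` are NaN when r is numerically zero,
    in which case the mean direction is undefined.
    """

    mean_direction: float
    mean_hours: float
    resultant_length: float
    n: int


@dataclass(frozen=True)
class WatsonWilliamsResult:
    f_statistic: float
    df1: int
    df2: int
    p_value: float
    kappa_hat: float
    correction_factor: float
    pooled_resultant_length: float


def hours_to_angle(t):
    """Project clock hours onto the circle: theta = (t mod 24) * 2*pi / 24."""
    return np.mod(np.asarray(t, dtype=float), 24.0) * _TWO_PI / 24.0


def angle_to_hours(theta):
    """Inverse projection: clock hours in [0, 24) for angles in radians."""
    return np.mod(np.asarray(theta, dtype=float), _TWO_PI) * 24.0 / _TWO_PI


def circular_mean(series) -> CircularSummary:
    """Mean direction and resultant length by vector averaging.

    Accepts an :class:`AngleSeries` or a raw array of angles in radians.
    Raises ``ValueError`` on an empty sample.  If the resultant length is
    numerically zero the mean direction is undefined: a
    :class:`LowConcentrationWarning` is issued and the direction reported
    as NaN.
    """
    if not isinstance(series, AngleSeries):
        series = AngleSeries(np.asarray(series, dtype=float))
    if series.n == 0:
        raise ValueError("circular mean of an empty series is undefined")
    s = np.mean(np.sin(series.values))
    c = np.mean(np.cos(series.values))
    r = float(np.hypot(s, c))
    if r < 1e-12:
        warnings.warn(
            "resultant length ~ 0: circular mean direction is undefined",
            LowConcentrationWarning,
            stacklevel=2,
        )
        return CircularSummary(np.nan, np.nan, r, series.n)
    theta = float(np.mod(np.arctan2(s, c), _TWO_PI))
    return CircularSummary(theta, float(angle_to_hours(theta)), r, series.n)


def circular_mean_hours(hours) -> float:
    """Circular mean of clock-hour values, returned in clock hours."""
    return circular_mean(AngleSeries.from_hours(hours)).mean_hours


def circular_midpoint(onset_hours, offset_hours):
    """Midpoint of a sleep bout on the 24-h circle, in clock hours.

    The bout runs forward in time from onset to offset; its duration is
    (offset - onset) mod 24, which must be strictly positive (a zero-length
    bout has no midpoint).  Vectorised over arrays.
    """
    onset = np.mod(np.asarray(onset_hours, dtype=float), 24.0)
    offset = np.mod(np.asarray(offset_hours, dtype=float), 24.0)
    duration = np.mod(offset - onset, 24.0)
    if np.any(duration == 0.0):
        raise ValueError("zero-duration bout has no midpoint")
    out = np.mod(onset + duration / 2.0, 24.0)
    return float(out) if out.ndim == 0 else out


def wrapped_diff_hours(a_hours, b_hours):
    """Signed circular difference a - b in hours, wrapped to (-12, 12].

    Used for before/after and free-minus-work comparisons where the sign
    (delay vs advance) matters but the values live on the 24-h circle.
    """
    d = np.mod(np.asarray(a_hours, dtype=float) - np.asarray(b_hours, dtype=float), 24.0)
    d = np.where(d > 12.0, d - 24.0, d)
    return float(d) if d.ndim == 0 else d


def estimate_kappa(resultant_length: float, n: int | None = None) -> float:
    """Approximate ML estimate of the von Mises concentration kappa.

    Inverts the mean-resultant-length function A(kappa) = I1(kappa)/I0(kappa)
    with the standard three-regime closed form:

      r < 0.5         kappa = 2r + r^3 + 5 r^5 / 6
      0.5 <= r < 0.85   kappa = -0.4 + 1.39 r + 0.43 / (1 - r)
      r >= 0.85       kappa = 1 / (r^3 - 4 r^2 + 3 r)

    Published cut-points for the small/mid boundary vary around 0.5-0.53;
    the two formulas differ by < 0.01 on that interval, well inside the
    approximation error of either.

    ``n`` is accepted for interface symmetry with small-sample corrections
    but is not used here.  r = 1 corresponds to infinite concentration and
    raises ``ValueError``.
    """
    r = float(resultant_length)
    if not 0.0 <= r < 1.0:
        if r == 1.0:
            raise ValueError("resultant length 1 implies infinite concentration")
        raise ValueError(f"resultant length must be in [0, 1), got {r}")
    if r < 0.5:
        return 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    return 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)


def watson_williams(groups) -> WatsonWilliamsResult:
    """Parametric Watson-Williams test for equal circular mean directions.

    ``groups`` is a sequence of k >= 2 angle collections (AngleSeries or
    radian arrays), each with at least 2 observations.  Under a shared von
    Mises concentration the corrected statistic

        F = g * (N - k) (sum_i R_i - R) / ((k - 1) (N - sum_i R_i))

    is approximately F-distributed with (k - 1, N - k) degrees of freedom,
    where R_i and R are the un-normalised within-group and pooled resultant
    lengths and g = 1 + 3/(8 kappa_hat) with kappa_hat estimated from the
    weighted mean resultant length r_w = sum_i R_i / N.

    The test assumes concentrated samples; when r_w < 0.45 a
    :class:`LowConcentrationWarning` is issued but the result is still
    returned, since highly dispersed inputs arise only in synthetic edge
    cases for sleep-timing data.
    """
    series = [
        g if isinstance(g, AngleSeries) else AngleSeries(np.asarray(g, dtype=float))
        for g in groups
    ]
    k = len(series)
    if k < 2:
        raise ValueError("Watson-Williams test needs at least two groups")
    ns = np.array([s.n for s in series])
    if np.any(ns < 2):
        raise ValueError("every group needs at least 2 observations")
    N = int(ns.sum())

    # un-normalised resultants: R_i = n_i * r_i
    sums_sin = np.array([np.sum(np.sin(s.values)) for s in series])
    sums_cos = np.array([np.sum(np.cos(s.values)) for s in series])
    R_i = np.hypot(sums_sin, sums_cos)
    R = float(np.hypot(sums_sin.sum(), sums_cos.sum()))

    rw = float(R_i.sum()) / N
    if rw < 0.45:
        warnings.warn(
            f"pooled mean resultant length {rw:.3f} < 0.45: "
            "Watson-Williams assumptions are doubtful",
            LowConcentrationWarning,
            stacklevel=2,
        )
    kappa = estimate_kappa(min(rw, 1.0 - 1e-12), N)
    correction = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else np.inf

    df1, df2 = k - 1, N - k
    between = max(float(R_i.sum() - R), 0.0)  # tiny negative = round-off
    within = float(N - R_i.sum())
    if within <= 0.0:
        # fully concentrated groups: F undefined unless the group means
        # coincide exactly, in which case there is nothing to test
        f = 0.0 if between == 0.0 else np.inf
    else:
        f = float(correction * (between * df2) / (within * df1))
    p = float(stats.f.sf(f, df1, df2))
    return WatsonWilliamsResult(f, df1, df2, p, float(kappa), float(correction), rw)
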