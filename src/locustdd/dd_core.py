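"""Core degree-day computation: threshold crossings, integral DD, degree-hours
DD, overflow DD, oviposition-ineffective DD, and season accounting.

The central quantity is the daily effective heat above a stage's lower
development threshold C_i, measured in degree-days (DD).  With a fitted 24-h
curve f(t) the integral method gives, per crossing interval [a, b] where
f > C_i:

    S = [ integral_a^b f(t) dt  -  C_i * (b - a) ] / 24

(the division by 24 converts degree-hours to degree-days).  Two deductions
make the "standard" DD used for locust voltinism forecasting:

* overflow DD — heat above the 32 degC upper inflection point, which does not
  accelerate development;
* ineffective oviposition DD — heat accrued during the adult egg-laying
  window on days whose mean temperature is below the 21 degC oviposition
  floor, when females cannot reproduce.

    standard DD = effective DD - overflow DD - ineffective DD
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

from .diurnal_fit import DiurnalCurve, fit_diurnal_curve
from .thermal_io import TemperatureDataError, TemperatureSeries

__all__ = [
    "ThresholdCrossing",
    "StageThresholds",
    "DDBreakdown",
    "StageWindow",
    "find_crossings",
    "integral_dd",
    "degree_hours_dd",
    "overflow_dd",
    "day_effective_dd",
    "ineffective_oviposition_dd",
    "season_breakdown",
]

#: Grid step (hours) used to bracket threshold crossings before bisection.
_BRACKET_STEP = 0.01
_ROOT_XTOL = 1e-9

#: Days with fewer hourly readings than this fall back to degree-hours.
MIN_HOURS_FOR_FIT = 20


@dataclass(frozen=True)
class ThresholdCrossing:
    """Interval [a, b] (hours) on which the diurnal curve exceeds a threshold."""

    a: float
    b: float
    threshold: float

    def __post_init__(self) -> None:
        if not self.a < self.b:
            raise ValueError(f"need a < b, got [{self.a}, {self.b}]")

    @property
    def duration(self) -> float:
        return self.b - self.a


@dataclass(frozen=True)
class StageThresholds:
    """Stage-specific temperature thresholds (degC) for the locust.

    Lower development thresholds: 14.2 for eggs and nymphs, 21 for adults.
    Heat above ``upper_overflow`` (32) does not speed development and is
    deducted; days with mean below ``oviposition_floor`` (21) contribute no
    reproductively useful heat during the egg-laying window.
    """

    lower_egg: float = 14.2
    lower_nymph: float = 14.2
    lower_adult: float = 21.0
    upper_overflow: float = 32.0
    oviposition_floor: float = 21.0

    def __post_init__(self) -> None:
        for name in ("lower_egg", "lower_nymph", "lower_adult"):
            if getattr(self, name) >= self.upper_overflow:
                raise ValueError(f"{name} must be below upper_overflow")
        if self.oviposition_floor < self.lower_egg:
            raise ValueError("oviposition_floor must be >= lower_egg")

    def lower_for(self, stage: str) -> float:
        try:
            return {"egg": self.lower_egg, "nymph": self.lower_nymph,
                    "adult": self.lower_adult}[stage]
        except KeyError:
            raise ValueError(f"unknown stage {stage!r}") from None


@dataclass(frozen=True)
class DDBreakdown:
    """Season heat-unit ledger: effective, overflow, ineffective, standard."""

    dd_effective: float
    dd_overflow: float
    dd_ineffective_oviposition: float

    def __post_init__(self) -> None:
        for name in ("dd_effective", "dd_overflow", "dd_ineffective_oviposition"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def dd_standard(self) -> float:
        return self.dd_effective - self.dd_overflow - self.dd_ineffective_oviposition


@dataclass(frozen=True)
class StageWindow:
    """A development-stage occupancy window within the season."""

    stage: str  # egg | nymph | adult
    start: _dt.date
    end: _dt.date  # inclusive

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("window end before start")

    def dates(self) -> Iterable[_dt.date]:
        d = self.start
        while d <= self.end:
            yield d
            d += _dt.timedelta(days=1)


def find_crossings(curve: DiurnalCurve, threshold: float) -> list[ThresholdCrossing]:
    """Disjoint ordered intervals where the curve exceeds *threshold*.

    Crossing times are bracketed on a 0.01-h grid and refined by bisection;
    intervals are clipped to the curve domain when the day starts or ends
    above the threshold.  Empty list if the curve never exceeds it.
    """
    lo, hi = curve.domain
    grid = np.arange(lo, hi + _BRACKET_STEP / 2, _BRACKET_STEP)
    grid[-1] = hi
    vals = np.polyval(curve.coefficients, grid) - threshold

    def root(i: int) -> float:
        return brentq(lambda t: np.polyval(curve.coefficients, t) - threshold,
                      grid[i], grid[i + 1], xtol=_ROOT_XTOL)

    crossings: list[ThresholdCrossing] = []
    above = vals[0] > 0
    a = lo if above else None
    for i in range(len(grid) - 1):
        if (vals[i] > 0) != (vals[i + 1] > 0):
            t = root(i)
            if vals[i] > 0:  # falling through threshold
                if a is not None and t > a:
                    crossings.append(ThresholdCrossing(a, t, threshold))
                a = None
            else:  # rising
                a = t
    if a is not None and hi > a:
        crossings.append(ThresholdCrossing(a, hi, threshold))
    return crossings


def integral_dd(curve: DiurnalCurve, threshold: float) -> float:
    """Integral-method degree-days for one day's curve above *threshold*.

    Sum over crossing intervals of [∫f − C·(b−a)]/24; exact polynomial
    antiderivative, non-negative by construction.
    """
    antider = curve.antiderivative()
    total = 0.0
    for c in find_crossings(curve, threshold):
        area = float(antider(c.b) - antider(c.a)) - threshold * c.duration
        total += max(0.0, area)
    return total / 24.0


def degree_hours_dd(
    temps: Sequence[float], threshold: float, sample_hours: float = 1.0
) -> float:
    """Degree-hours method: sum of hourly excesses over the threshold, /24.

    ``sample_hours`` is the time each reading represents (1 h for standard
    logger data; smaller for sub-hourly sampling, where the sum converges to
    the integral method).
    """
    t = np.asarray(temps, dtype=float)
    if t.size == 0:
        raise TemperatureDataError("no hourly readings supplied")
    if sample_hours == 1.0 and t.size > 24:
        raise TemperatureDataError(f"at most 24 hourly readings per day, got {t.size}")
    return float(np.maximum(0.0, t - threshold).sum() * sample_hours / 24.0)


def overflow_dd(curve: DiurnalCurve, upper: float = 32.0) -> float:
    """Heat above the upper inflection temperature (default 32 degC)."""
    return integral_dd(curve, upper)


def day_effective_dd(
    series: TemperatureSeries,
    date: _dt.date,
    sensor: str,
    threshold: float,
    method: str = "integral",
    degree: int = 6,
) -> float:
    """One day's effective DD above *threshold*, by either method.

    ``integral`` fits the day's degree-6 diurnal polynomial and integrates;
    days with fewer than 20 hourly readings fall back to degree-hours with a
    warning.  ``degree_hours`` sums hourly excesses directly.
    """
    hours, temps = series.day(date, sensor)
    if method == "degree_hours":
        return degree_hours_dd(temps, threshold)
    if method != "integral":
        raise ValueError(f"unknown method {method!r}")
    if len(hours) < MIN_HOURS_FOR_FIT:
        warnings.warn(
            f"{date} ({sensor}): only {len(hours)} hourly readings; "
            "falling back to degree-hours",
            stacklevel=2,
        )
        return degree_hours_dd(temps, threshold)
    curve = fit_diurnal_curve(hours, temps, degree=degree)
    return integral_dd(curve, threshold)


def _day_dd_pair(series, date, sensor, lower, upper, method, degree=6):
    """(effective, overflow) DD for one day."""
    hours, temps = series.day(date, sensor)
    if method == "degree_hours" or len(hours) < MIN_HOURS_FOR_FIT:
        if method == "integral":
            warnings.warn(
                f"{date} ({sensor}): only {len(hours)} hourly readings; "
                "falling back to degree-hours",
                stacklevel=3,
            )
        return degree_hours_dd(temps, lower), degree_hours_dd(temps, upper)
    curve = fit_diurnal_curve(hours, temps, degree=degree)
    return integral_dd(curve, lower), overflow_dd(curve, upper)


def _pick_sensor(series: TemperatureSeries, date: _dt.date, stage: str) -> str:
    # eggs develop underground: prefer the ground sensor when present
    if stage == "egg" and series.has_day(date, "ground"):
        return "ground"
    if series.has_day(date, "air"):
        return "air"
    if series.has_day(date, "ground"):
        return "ground"
    raise TemperatureDataError(f"no data for {date}")


def ineffective_oviposition_dd(
    series: TemperatureSeries,
    oviposition_window: tuple[_dt.date, _dt.date],
    thresholds: StageThresholds = StageThresholds(),
    method: str = "integral",
) -> float:
    """Heat accrued on too-cool days of the egg-laying window.

    Over each day of the (inclusive) window whose daily mean air temperature
    is below the oviposition floor (21 degC), the day's full effective DD at
    the common 14.2 degC base is counted as reproductively ineffective.
    """
    start, end = oviposition_window
    total = 0.0
    d = start
    while d <= end:
        sensor = "air" if series.has_day(d, "air") else _pick_sensor(series, d, "adult")
        _, temps = series.day(d, sensor)
        if float(np.mean(temps)) < thresholds.oviposition_floor:
            eff, _ = _day_dd_pair(series, d, sensor, thresholds.lower_egg,
                                  thresholds.upper_overflow, method)
            total += eff
        d += _dt.timedelta(days=1)
    return total


def season_breakdown(
    series: TemperatureSeries,
    stages: Sequence[StageWindow],
    thresholds: StageThresholds = StageThresholds(),
    method: str = "integral",
    oviposition_windows: Sequence[tuple[_dt.date, _dt.date]] | None = None,
) -> DDBreakdown:
    """Season heat-unit ledger over per-stage occupancy windows.

    Effective and overflow DD are accumulated day by day over every stage
    window (eggs on the ground sensor when available, nymphs/adults on air;
    all stages accumulate at the common 14.2 degC egg/nymph base so the
    ledger balances).  The ineffective-oviposition deduction is taken over
    ``oviposition_windows`` (default: the adult windows).  Overlapping
    windows — generations overlap in the field — are each accounted
    independently.
    """
    if not stages:
        raise ValueError("no stage windows supplied")
    effective = 0.0
    overflow = 0.0
    for w in stages:
        for d in w.dates():
            sensor = _pick_sensor(series, d, w.stage)
            try:
                eff, ovf = _day_dd_pair(
                    series, d, sensor, thresholds.lower_egg,
                    thresholds.upper_overflow, method,
                )
            except TemperatureDataError as exc:
                raise TemperatureDataError(
                    f"stage {w.stage!r} window: missing data for {d}"
                ) from exc
            effective += eff
            overflow += ovf
    if oviposition_windows is None:
        oviposition_windows = [(w.start, w.end) for w in stages if w.stage == "adult"]
    ineffective = sum(
        ineffective_oviposition_dd(series, win, thresholds, method)
        for win in oviposition_windows
    )
    # deductions can exceed the accrued total only through rounding noise
    ineffective = min(ineffective, max(0.0, effective - overflow))
    return DDBreakdown(effective, overflow, ineffective)
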