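"""Development-rate regression, the improved daily development model, and
voltinism accounting.

Constant-temperature rearing gives stage durations D(T); the development rate
V = 1/D is linear in temperature over the locust's linear range (18-31 degC):

    V = slope * T + intercept

from which the lower temperature threshold LTT = -intercept/slope (the
x-intercept) and the thermal constant K = 1/slope (DD to complete the stage)
follow.  Reference regressions: eggs V = 0.005 T - 0.070 (LTT 14.0, K 200 DD)
and nymphs V = 0.003 T - 0.042 (LTT 14.0, K ~333 DD).

The improved daily model caps useful heat at the 32 degC overflow point and
uses stage-specific bases (14.2 degC for eggs/nymphs, 21 degC for adult
oocyte maturation):

    V_i = DD_i / K_i,   DD_i = sum_h max(0, min(T_h, 32) - C_i) / 24

A stage completes when the cumulative V_i reaches 1.  A generation closes
when the female, past her pre-oviposition period, meets a day warm enough
(mean > 21 degC) to lay.  Season totals feed the voltinism ledger:

    actual DD = total DD - (overflow DD + ineffective egg-laying DD)
    generations completed = (n-1) + [actual - 700 (n-1)] / 700
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .dd_core import StageThresholds
from .thermal_io import TemperatureSeries

__all__ = [
    "DevRateObservation",
    "LinearDevModel",
    "StageParams",
    "VoltinismResult",
    "SimulationResult",
    "StageTransition",
    "DEFAULT_STAGES",
    "PER_GENERATION_DD",
    "TRADITIONAL_PER_GENERATION_DD",
    "fit_dev_rate",
    "daily_dev_rate",
    "generations_completed",
    "standard_generation_dd",
    "theoretical_generations",
    "preoviposition_days",
    "simulate_development",
]

#: Standard heat units for one egg-to-egg cycle under the improved model.
PER_GENERATION_DD = 700.0
#: The traditional model's per-generation requirement (used for the
#: theoretical generation count n).
TRADITIONAL_PER_GENERATION_DD = 800.0

#: Pre-oviposition period (days from adult molt to first egg pod) observed at
#: constant rearing temperatures; no oviposition at or below 21 degC.
PREOVIPOSITION_TABLE = ((22.0, 17.4), (23.0, 15.7), (24.0, 14.6),
                        (27.0, 13.1), (30.0, 12.7))


@dataclass(frozen=True)
class DevRateObservation:
    """One constant-temperature rearing outcome for a stage."""

    temperature: float
    stage: str  # egg | nymph | oocyte
    duration: float  # days

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def rate(self) -> float:
        """Development rate, fraction of the stage per day (= 1/duration)."""
        return 1.0 / self.duration


@dataclass(frozen=True)
class LinearDevModel:
    """Linear rate-temperature regression with its thermal derivatives."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def ltt(self) -> float:
        """Lower temperature threshold: the regression's x-intercept (degC)."""
        return -self.intercept / self.slope

    @property
    def thermal_constant_K(self) -> float:
        """Thermal constant: DD needed to complete the stage (= 1/slope)."""
        return 1.0 / self.slope

    def rate_at(self, temperature: float) -> float:
        return self.slope * temperature + self.intercept


@dataclass(frozen=True)
class StageParams:
    """Thermal parameters driving one stage's daily development rate."""

    stage: str
    lower_threshold: float  # C_i, degC
    thermal_constant: float  # K_i, DD
    fit_range: tuple[float, float] = (18.0, 31.0)

    def __post_init__(self) -> None:
        if self.thermal_constant <= 0:
            raise ValueError("thermal_constant must be positive")


#: Default stage parameters: egg and nymph constants from the reference
#: regressions (1/0.005 and 1/0.003); the adult oocyte constant closes the
#: egg-to-egg budget at ~700 DD.
DEFAULT_STAGES = (
    StageParams("egg", 14.2, 200.0),
    StageParams("nymph", 14.2, 1.0 / 0.003),
    StageParams("adult", 21.0, 700.0 - 200.0 - 1.0 / 0.003),
)


def fit_dev_rate(
    observations: Sequence[DevRateObservation],
    fit_range: tuple[float, float] = (18.0, 31.0),
    stage: str | None = None,
) -> LinearDevModel:
    """OLS fit of development rate on temperature within the linear range.

    Observations outside *fit_range* (inclusive) are excluded — above ~32 degC
    the rate plateaus and a line no longer applies.  Optionally restrict to
    one stage.
    """
    obs = [o for o in observations
           if fit_range[0] <= o.temperature <= fit_range[1]
           and (stage is None or o.stage == stage)]
    temps = np.array([o.temperature for o in obs])
    if len(np.unique(temps)) < 2:
        raise ValueError(
            f"need >=2 distinct temperatures inside {fit_range} to fit a line"
        )
    rates = np.array([o.rate for o in obs])
    res = stats.linregress(temps, rates)
    if res.slope <= 0:
        raise ValueError("non-positive rate-temperature slope; no thermal response")
    return LinearDevModel(float(res.slope), float(res.intercept),
                          float(res.rvalue) ** 2)


def daily_dev_rate(day_dd_effective: float, stage: StageParams) -> float:
    """Improved daily development rate V_i = DD_i / K_i (fraction of stage)."""
    if stage.thermal_constant <= 0:
        raise ValueError("thermal constant must be positive")
    if day_dd_effective < 0:
        raise ValueError("daily DD must be >= 0")
    return day_dd_effective / stage.thermal_constant


def generations_completed(
    actual_dd: float, n_theory: int, per_generation: float = PER_GENERATION_DD
) -> float:
    """Generations completed: (n-1) + [actual - per_gen*(n-1)] / per_gen."""
    if actual_dd < 0:
        raise ValueError("actual_dd must be >= 0")
    if n_theory < 1:
        raise ValueError("n_theory must be >= 1")
    n = n_theory
    return (n - 1) + (actual_dd - per_generation * (n - 1)) / per_generation


def standard_generation_dd(
    total: float, overflow: float, ineffective: float, n_generations: int
) -> float:
    """Standard per-generation heat: (total - overflow - ineffective) / n."""
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    if min(total, overflow, ineffective) < 0:
        raise ValueError("heat-unit components must be >= 0")
    return (total - overflow - ineffective) / n_generations


def theoretical_generations(
    total_dd: float, per_generation: float = TRADITIONAL_PER_GENERATION_DD
) -> int:
    """Traditional-model generation count n = max(1, round(total/800))."""
    return max(1, round(total_dd / per_generation))


def preoviposition_days(mean_temperature: float) -> float:
    """Pre-oviposition period (d) interpolated from constant-T observations.

    Clipped to the observed 12.7-17.4 d range; temperatures at or below the
    21 degC floor never permit oviposition regardless of this lag.
    """
    temps = np.array([t for t, _ in PREOVIPOSITION_TABLE])
    days = np.array([d for _, d in PREOVIPOSITION_TABLE])
    return float(np.interp(mean_temperature, temps, days))


@dataclass(frozen=True)
class VoltinismResult:
    """Season heat ledger and the generations it supports."""

    n_theory: int
    total_dd: float
    overflow_dd: float
    ineffective_dd: float

    @property
    def actual_dd(self) -> float:
        return self.total_dd - (self.overflow_dd + self.ineffective_dd)

    @property
    def generations(self) -> float:
        return generations_completed(self.actual_dd, self.n_theory)


@dataclass(frozen=True)
class StageTransition:
    generation: int  # 1-based
    stage: str
    date: _dt.date  # completion date of the stage


@dataclass(frozen=True)
class SimulationResult:
    transitions: tuple[StageTransition, ...]
    egg_to_egg_generations: int
    final_generation_progress: float  # phases completed / phases per cycle
    voltinism: VoltinismResult


def _capped_day_dd(temps: np.ndarray, lower: float, upper: float) -> float:
    """Development-effective DD with the overflow cap: sum (min(T,32)-C)+/24."""
    return float(np.maximum(0.0, np.minimum(temps, upper) - lower).sum() / 24.0)


def simulate_development(
    series: TemperatureSeries,
    stage_params: Sequence[StageParams] = DEFAULT_STAGES,
    thresholds: StageThresholds = StageThresholds(),
    start_date: _dt.date | None = None,
    oviposition_mode: str = "interpolated",
    prelag_days: float = 14.0,
) -> SimulationResult:
    """Run the improved daily-rate model over a season of hourly data.

    Daily rates use hourly degree-hours with the 32 degC overflow cap, so the
    trajectory is exactly invariant to replacing any reading above 32 degC by
    32 degC.  Stages complete when cumulative V_i reaches 1 (linear within
    the completing day, recorded at day resolution).  The adult phase is the
    pre-oviposition lag — either interpolated from the constant-temperature
    observations (``interpolated``) or a fixed ``prelag_days`` (``fixed``) —
    and oviposition, which closes the egg-to-egg generation, happens on the
    first post-lag day whose mean exceeds the 21 degC floor.  Eggs read the
    ground sensor when present; later stages read air.

    The returned ledger accumulates, over the whole simulated season,
    effective DD at the common 14.2 degC base, overflow DD above 32 degC, and
    ineffective DD on post-lag adult days too cool to lay.
    """
    if oviposition_mode not in ("interpolated", "fixed"):
        raise ValueError(f"unknown oviposition_mode {oviposition_mode!r}")
    dd_stages = [s for s in stage_params if s.stage in ("egg", "nymph")]
    if not dd_stages:
        raise ValueError("stage_params must include at least the egg stage")
    phases_per_cycle = len(dd_stages) + 1  # DD-driven stages + adult lag

    all_dates = sorted(set(series.dates("air")) | set(series.dates("ground")))
    if start_date is not None:
        all_dates = [d for d in all_dates if d >= start_date]
    if not all_dates:
        raise ValueError("series has no data on/after start_date")

    transitions: list[StageTransition] = []
    total = overflow = ineffective = 0.0
    generation = 1
    phase_idx = 0  # index into dd_stages, or len(dd_stages) for adult
    cum_v = 0.0
    adult_molt: _dt.date | None = None
    adult_mean_sum, adult_days = 0.0, 0
    completed_phases = 0  # within the current generation
    egg_to_egg = 0

    for date in all_dates:
        in_adult = phase_idx >= len(dd_stages)
        stage_name = "adult" if in_adult else dd_stages[phase_idx].stage
        if stage_name == "egg" and series.has_day(date, "ground"):
            sensor = "ground"
        elif series.has_day(date, "air"):
            sensor = "air"
        else:
            sensor = "ground"
        _, temps = series.day(date, sensor)
        day_mean = float(np.mean(temps))

        # season ledger at the common egg/nymph base
        total += float(np.maximum(0.0, temps - thresholds.lower_egg).sum() / 24.0)
        overflow += float(
            np.maximum(0.0, temps - thresholds.upper_overflow).sum() / 24.0
        )

        if not in_adult:
            sp = dd_stages[phase_idx]
            dd = _capped_day_dd(temps, sp.lower_threshold, thresholds.upper_overflow)
            cum_v += daily_dev_rate(dd, sp)
            if cum_v >= 1.0:
                transitions.append(StageTransition(generation, sp.stage, date))
                completed_phases += 1
                phase_idx += 1
                cum_v = 0.0
                if phase_idx >= len(dd_stages):
                    adult_molt = date
                    adult_mean_sum, adult_days = 0.0, 0
        else:
            adult_mean_sum += day_mean
            adult_days += 1
            if oviposition_mode == "fixed":
                lag = prelag_days
            else:
                lag = preoviposition_days(adult_mean_sum / adult_days)
            past_lag = (date - adult_molt).days >= lag
            if past_lag:
                if day_mean > thresholds.oviposition_floor:
                    # oviposition: generation closes, next one's eggs start
                    transitions.append(StageTransition(generation, "adult", date))
                    egg_to_egg += 1
                    generation += 1
                    phase_idx = 0
                    cum_v = 0.0
                    completed_phases = 0
                    adult_molt = None
                else:
                    # warm-enough heat wasted on a day too cool for laying
                    ineffective += float(
                        np.maximum(0.0, temps - thresholds.lower_egg).sum() / 24.0
                    )

    if phase_idx >= len(dd_stages) and adult_molt is not None:
        if oviposition_mode == "fixed":
            lag = prelag_days
        else:
            lag = preoviposition_days(adult_mean_sum / max(adult_days, 1))
        adult_progress = min(1.0, adult_days / max(lag, 1e-9))
        progress = (completed_phases + adult_progress) / phases_per_cycle
    else:
        progress = (completed_phases + min(cum_v, 1.0)) / phases_per_cycle

    ineffective = min(ineffective, max(0.0, total - overflow))
    voltinism = VoltinismResult(
        n_theory=theoretical_generations(total),
        total_dd=total,
        overflow_dd=overflow,
        ineffective_dd=ineffective,
    )
    return SimulationResult(
        transitions=tuple(transitions),
        egg_to_egg_generations=egg_to_egg,
        final_generation_progress=progress,
        voltinism=voltinism,
    )
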