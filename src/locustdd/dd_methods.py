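"""The four degree-day calculation methods and their comparison.

Methods, in increasing fidelity to the true diurnal course:

1. daily mean:    DD = Tmean - C (signed, may be negative)
2. max-min:       triangle or single-sine interpolation between Tmin and Tmax
3. degree-hours:  sum of hourly excesses over C, / 24
4. 24-h integral: area of the fitted diurnal curve above C, / 24

The integral value is the reference; each method's relative error is
|X - Y| / Y * 100 against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.integrate import quad

from .dd_core import degree_hours_dd, integral_dd
from .diurnal_fit import DiurnalCurve

__all__ = [
    "MethodComparison",
    "daily_mean_dd",
    "maxmin_dd",
    "relative_error",
    "compare_methods",
]


@dataclass(frozen=True)
class MethodComparison:
    """Per-method DD for one day plus relative errors vs the integral value.

    ``tracks_trend`` / ``tracks_interval``: whether each method can describe
    the actual temperature-variation trend and the time interval spent above
    the threshold.  Only the hourly-based methods resolve the interval, and
    only the integral curve tracks the trend.
    """

    daily_mean: float
    maxmin: float
    hours24: float
    integral: float
    relative_errors: dict[str, float]
    tracks_trend: dict[str, bool]
    tracks_interval: dict[str, bool]

    METHODS = ("daily_mean", "maxmin", "hours24", "integral")

    def value(self, method: str) -> float:
        return getattr(self, method)


def daily_mean_dd(mean: float, threshold: float, signed: bool = False) -> float:
    """Daily-mean method: mean minus threshold (floored at 0 unless signed)."""
    dd = mean - threshold
    return dd if signed else max(0.0, dd)


def maxmin_dd(
    tmax: float, tmin: float, threshold: float, variant: str = "triangle"
) -> float:
    """Max-min method DD: triangle or single-sine day reconstruction.

    Both variants give 0 when Tmax <= C and (Tmean - C) when Tmin >= C.  In
    between, the triangle treats the day as a triangular wave between the
    extremes, area (Tmax - C)^2 / (2 (Tmax - Tmin)); the sine variant is the
    classic single-sine half-day formula.
    """
    if tmax < tmin:
        raise ValueError(f"tmax ({tmax}) < tmin ({tmin})")
    if tmax <= threshold:
        return 0.0
    mean = (tmax + tmin) / 2.0
    if tmin >= threshold:
        return mean - threshold
    if variant == "triangle":
        return (tmax - threshold) ** 2 / (2.0 * (tmax - tmin))
    if variant == "sine":
        amp = (tmax - tmin) / 2.0
        theta1 = math.asin((threshold - mean) / amp)
        return ((mean - threshold) * (math.pi / 2.0 - theta1)
                + amp * math.cos(theta1)) / math.pi
    raise ValueError(f"unknown variant {variant!r}")


def maxmin_sine_quadrature(tmax: float, tmin: float, threshold: float) -> float:
    """Numerical check of the single-sine formula (reference only)."""
    mean = (tmax + tmin) / 2.0
    amp = (tmax - tmin) / 2.0
    val, _ = quad(
        lambda th: max(0.0, mean + amp * math.sin(th) - threshold), -math.pi / 2,
        math.pi / 2, limit=200,
    )
    return val / math.pi


def relative_error(x: float, y: float) -> float:
    """|x - y| / y * 100, the comparison-table error metric (percent)."""
    if y == 0:
        raise ZeroDivisionError("reference DD is 0; relative error undefined")
    return abs(x - y) / abs(y) * 100.0


def compare_methods(
    temps: Sequence[float],
    curve: DiurnalCurve,
    threshold: float,
    summary: tuple[float, float, float] | None = None,
    maxmin_variant: str = "triangle",
) -> MethodComparison:
    """Run all four DD methods on one day and tabulate relative errors.

    Parameters
    ----------
    temps
        The day's hourly readings (for the degree-hours method).
    curve
        The fitted diurnal curve (for the integral reference).
    summary
        Optional (min, mean, max) override; otherwise derived from *temps*.
        Useful when only the published rounded summary values are available.

    Notes
    -----
    DD values are rounded to 1 decimal and the relative errors computed from
    the rounded values, matching how such comparison tables are reported; the
    daily-mean entry is signed (a sub-threshold day shows a negative value).
    """
    import numpy as np

    t = np.asarray(temps, dtype=float)
    if summary is None:
        tmin, tmean, tmax = float(t.min()), float(t.mean()), float(t.max())
    else:
        tmin, tmean, tmax = summary

    values = {
        "daily_mean": round(daily_mean_dd(tmean, threshold, signed=True), 1),
        "maxmin": round(maxmin_dd(tmax, tmin, threshold, variant=maxmin_variant), 1),
        "hours24": round(degree_hours_dd(t, threshold), 1),
        "integral": round(integral_dd(curve, threshold), 1),
    }
    ref = values["integral"]
    # a method agreeing exactly with a zero reference has zero error
    errors = {
        m: 0 if values[m] == ref else round(relative_error(values[m], ref))
        for m in values
    }
    return MethodComparison(
        daily_mean=values["daily_mean"],
        maxmin=values["maxmin"],
        hours24=values["hours24"],
        integral=values["integral"],
        relative_errors=errors,
        tracks_trend={"daily_mean": False, "maxmin": False,
                      "hours24": False, "integral": True},
        tracks_interval={"daily_mean": False, "maxmin": False,
                         "hours24": True, "integral": True},
    )
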