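"""Polynomial fit of the 24-h diurnal temperature curve.

A day's hourly logger readings (hours 1..24) are modelled by a least-squares
polynomial f(t) of degree 1..6 (degree 6 by default, the degree used for the
reference worked example).  The fitted curve is what the integral degree-day
method operates on: its threshold crossings and the area above the threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["DiurnalCurve", "FitError", "fit_diurnal_curve", "eval_curve"]

# Fits use hour indices 1..24, but the curve's validity domain spans the full
# 24-h day so that a whole day above threshold integrates to 24 degree-hours
# (consistent with the degree-hours sum over 24 readings divided by 24).
DEFAULT_DOMAIN = (0.0, 24.0)


class FitError(ValueError):
    """Underdetermined or invalid curve fit."""


@dataclass(frozen=True)
class DiurnalCurve:
    """Fitted 24-h temperature polynomial.

    ``coefficients`` are highest-degree first (the Matlab/numpy ``polyfit``
    order); ``domain`` is the closed hour interval the fit is valid on.
    """

    coefficients: tuple[float, ...]
    r_squared: float = 1.0
    domain: tuple[float, float] = DEFAULT_DOMAIN

    def __post_init__(self) -> None:
        coeffs = tuple(float(c) for c in self.coefficients)
        object.__setattr__(self, "coefficients", coeffs)
        if not 2 <= len(coeffs) <= 7:
            raise FitError(f"degree must be 1..6, got {len(coeffs) - 1}")
        if self.r_squared > 1 + 1e-12:
            raise FitError(f"r_squared {self.r_squared} > 1")
        if not self.domain[0] < self.domain[1]:
            raise FitError(f"empty domain {self.domain}")

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, t):
        return eval_curve(self, t, clamp=False)

    def antiderivative(self) -> np.polynomial.Polynomial:
        p = np.polynomial.Polynomial(self.coefficients[::-1])
        return p.integ()

    def to_json(self) -> str:
        return json.dumps(
            {
                "degree": self.degree,
                "coefficients": list(self.coefficients),
                "r_squared": self.r_squared,
                "domain": list(self.domain),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DiurnalCurve":
        d = json.loads(text)
        return cls(
            coefficients=tuple(d["coefficients"]),
            r_squared=d["r_squared"],
            domain=tuple(d["domain"]),
        )


def fit_diurnal_curve(
    hours: Sequence[float],
    temps: Sequence[float],
    degree: int = 6,
    domain: tuple[float, float] = DEFAULT_DOMAIN,
) -> DiurnalCurve:
    """Least-squares polynomial fit of one day's hourly temperatures.

    Parameters
    ----------
    hours, temps
        Sample points (hour indices, typically 1..24) and readings in degC.
    degree
        Polynomial degree, 1..6.

    Returns
    -------
    DiurnalCurve with r_squared = 1 - SS_res / SS_tot (1.0 for a constant
    response fitted exactly, where SS_tot = 0).
    """
    h = np.asarray(hours, dtype=float)
    y = np.asarray(temps, dtype=float)
    if not 1 <= degree <= 6:
        raise FitError(f"degree must be in 1..6, got {degree}")
    if h.shape != y.shape or h.ndim != 1:
        raise FitError("hours and temps must be 1-D sequences of equal length")
    if len(np.unique(h)) < degree + 1:
        raise FitError(
            f"need at least {degree + 1} distinct hours for degree {degree}, "
            f"got {len(np.unique(h))}"
        )
    coeffs = np.polyfit(h, y, degree)
    resid = y - np.polyval(coeffs, h)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return DiurnalCurve(tuple(coeffs), r_squared=min(r2, 1.0), domain=domain)


def eval_curve(curve: DiurnalCurve, t, clamp: bool = False):
    """Evaluate the fitted polynomial at hour(s) *t* (Horner scheme).

    Outside the curve's domain a ValueError is raised unless ``clamp`` is
    set, in which case *t* is clipped to the domain ends first.
    """
    arr = np.asarray(t, dtype=float)
    lo, hi = curve.domain
    if clamp:
        arr = np.clip(arr, lo, hi)
    elif np.any(arr < lo - 1e-9) or np.any(arr > hi + 1e-9):
        raise ValueError(f"t={t} outside curve domain [{lo}, {hi}]")
    out = np.polyval(curve.coefficients, arr)
    return float(out) if np.isscalar(t) else out
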