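import datetime as dt

import numpy as np
import pytest

import locustdd as L

#: Coefficients of the reference April-12 diurnal polynomial (highest first).
APRIL12_COEFFS = (-3.1195e-7, 7.3636e-6, 4.7291e-4, -0.020038,
                  0.23657, -0.60834, 12.4926)


@pytest.fixture(scope="session")
def april12_curve() -> L.DiurnalCurve:
    return L.DiurnalCurve(APRIL12_COEFFS)


@pytest.fixture(scope="session")
def april12_hourly(april12_curve) -> np.ndarray:
    """The reference polynomial evaluated at integer hours 1..24."""
    return np.polyval(april12_curve.coefficients, np.arange(1, 25, dtype=float))


def constant_series(temp: float, n_days: int, sensor: str = "air",
                    start=dt.date(2011, 5, 1)) -> L.TemperatureSeries:
    """A climate of identical constant-temperature days."""
    spec = L.SyntheticClimateSpec(
        decade_means=[temp] * int(np.ceil(n_days / 10)),
        diurnal_amplitude=0.0, season_length_days=n_days,
        sensor=sensor, start_date=start,
    )
    return L.generate_synthetic_climate(spec)


@pytest.fixture
def constant_day_20() -> L.TemperatureSeries:
    return constant_series(20.0, 1)


def random_curve(rng: np.random.Generator, degree: int) -> L.DiurnalCurve:
    """A plausible random diurnal curve: base level plus damped random poly."""
    hours = np.arange(1, 25, dtype=float)
    base = rng.uniform(8, 30)
    amp = rng.uniform(0, 8)
    phase = rng.uniform(0, 24)
    temps = base + amp * np.sin(2 * np.pi * (hours - phase) / 24)
    temps += rng.normal(0, 0.3, size=24)
    return L.fit_diurnal_curve(hours, temps, degree=degree)


def riemann_dd(curve: L.DiurnalCurve, threshold: float, n: int = 10_000) -> float:
    """Midpoint-rule oracle for the integral DD, independent of root finding."""
    lo, hi = curve.domain
    t = lo + (np.arange(n) + 0.5) * (hi - lo) / n
    f = np.polyval(curve.coefficients, t)
    return float(np.maximum(0.0, f - threshold).sum() * (hi - lo) / n / 24.0)
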