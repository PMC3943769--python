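import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import locustdd as L
from locustdd.dd_core import StageWindow, _day_dd_pair
from locustdd.thermal_io import TemperatureDataError

from conftest import constant_series, random_curve, riemann_dd

HOURS = np.arange(1, 25, dtype=float)


def flat_curve(temp: float) -> L.DiurnalCurve:
    return L.fit_diurnal_curve(HOURS, np.full(24, temp), degree=1)


class TestFindCrossings:
    def test_reference_day_single_interval(self, april12_curve):
        crossings = L.find_crossings(april12_curve, 14.2)
        assert len(crossings) == 1
        (c,) = crossings
        # crossings of the printed (rounded) coefficients
        assert c.a == pytest.approx(7.0527, abs=1e-3)
        assert c.b == pytest.approx(18.3814, abs=1e-3)
        assert L.eval_curve(april12_curve, c.a) == pytest.approx(14.2, abs=1e-6)
        assert L.eval_curve(april12_curve, c.b) == pytest.approx(14.2, abs=1e-6)

    def test_always_below_threshold(self):
        assert L.find_crossings(flat_curve(10.0), 14.2) == []

    def test_always_above_threshold_clamped_to_domain(self):
        (c,) = L.find_crossings(flat_curve(20.0), 14.2)
        assert (c.a, c.b) == (0.0, 24.0)

    def test_multiple_intervals_detected(self):
        # two humps above 20 degC within the day
        temps = 18 + 4 * np.sin(2 * np.pi * (HOURS - 1) / 12)
        curve = L.fit_diurnal_curve(HOURS, temps, degree=6)
        crossings = L.find_crossings(curve, 20.0)
        assert len(crossings) >= 2
        for a, b in zip(crossings, crossings[1:]):
            assert a.b < b.a  # disjoint and ordered


class TestIntegralDD:
    def test_reference_day_rounds_to_printed_value(self, april12_curve):
        assert round(L.integral_dd(april12_curve, 14.2), 1) == 0.3

    def test_at_threshold_zero(self):
        assert L.integral_dd(flat_curve(14.2), 14.2) == pytest.approx(0.0, abs=1e-9)

    def test_one_degree_above_full_day_is_one_dd(self):
        assert L.integral_dd(flat_curve(15.2), 14.2) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_quadrature_oracle(self, seed):
        rng = np.random.default_rng(seed)
        curve = random_curve(rng, degree=4)
        assert L.integral_dd(curve, 14.2) == pytest.approx(
            riemann_dd(curve, 14.2), abs=1e-4)


class TestDegreeHours:
    def test_at_threshold_zero(self):
        assert L.degree_hours_dd(np.full(24, 14.2), 14.2) == 0.0

    def test_one_above_is_one(self):
        assert L.degree_hours_dd(np.full(24, 15.2), 14.2) == pytest.approx(1.0)

    def test_reference_day_rounds_to_printed_value(self, april12_hourly):
        assert round(L.degree_hours_dd(april12_hourly, 14.2), 1) == 0.3

    def test_empty_input_rejected(self):
        with pytest.raises(TemperatureDataError):
            L.degree_hours_dd([], 14.2)

    def test_converges_to_integral_with_sampling_density(self, april12_curve):
        """Sub-hourly degree-hours approach the integral value."""
        target = L.integral_dd(april12_curve, 14.2)
        gaps = []
        for n in (24, 240, 2400):
            t = 1 + (np.arange(n) + 0.5) * 23.0 / n
            temps = np.polyval(april12_curve.coefficients, t)
            dd = L.degree_hours_dd(temps, 14.2, sample_hours=23.0 / n)
            gaps.append(abs(dd - target))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 1e-5


class TestOverflow:
    def test_cool_day_no_overflow(self):
        assert L.overflow_dd(flat_curve(30.0)) == 0.0

    def test_constant_33_full_day(self):
        assert L.overflow_dd(flat_curve(33.0)) == pytest.approx(1.0, abs=1e-9)

    def test_quadratic_hot_midday_matches_oracle(self):
        # peaks above 32 degC around midday only
        temps = 36 - 0.12 * (HOURS - 13) ** 2
        curve = L.fit_diurnal_curve(HOURS, temps, degree=2)
        assert L.overflow_dd(curve) == pytest.approx(
            riemann_dd(curve, 32.0), abs=1e-4)

    def test_never_exceeds_effective_dd(self):
        rng = np.random.default_rng(99)
        for _ in range(5):
            curve = random_curve(rng, degree=6)
            assert L.overflow_dd(curve, 32.0) <= L.integral_dd(curve, 14.2) + 1e-12


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    c1=st.floats(5.0, 25.0),
    delta=st.floats(0.5, 10.0),
)
def test_integral_dd_monotone_in_threshold(seed, c1, delta):
    """Raising the threshold can only reduce accumulated heat."""
    curve = random_curve(np.random.default_rng(seed), degree=6)
    assert L.integral_dd(curve, c1) >= L.integral_dd(curve, c1 + delta) - 1e-12


class TestIneffectiveOviposition:
    def test_warm_window_counts_nothing(self):
        series = constant_series(24.0, 10)
        window = (series.dates("air")[0], series.dates("air")[-1])
        assert L.ineffective_oviposition_dd(series, window) == 0.0

    def test_cool_day_counts_full_effective_dd(self):
        series = constant_series(18.0, 1)
        d = series.dates("air")[0]
        dd = L.ineffective_oviposition_dd(series, (d, d))
        assert dd == pytest.approx(18.0 - 14.2, abs=1e-6)

    def test_mixed_autumn_equals_day_by_day_oracle(self):
        spec = L.SyntheticClimateSpec(
            decade_means=[24.0, 20.0, 17.0], diurnal_amplitude=5.0,
            seed=8, noise_sd=0.4,
        )
        series = L.generate_synthetic_climate(spec)
        dates = series.dates("air")
        window = (dates[0], dates[-1])
        expected = 0.0
        for d in dates:
            _, temps = series.day(d)
            if temps.mean() < 21.0:
                eff, _ = _day_dd_pair(series, d, "air", 14.2, 32.0, "integral")
                expected += eff
        got = L.ineffective_oviposition_dd(series, window)
        assert got == pytest.approx(expected, rel=1e-9)
        assert got > 0

    def test_window_outside_series_is_error(self):
        series = constant_series(20.0, 5)
        with pytest.raises(TemperatureDataError):
            L.ineffective_oviposition_dd(
                series, (dt.date(2010, 1, 1), dt.date(2010, 1, 2)))


class TestSeasonBreakdown:
    def test_standard_identity_printed_components(self):
        """The published season ledger: 1437 - 38 - 128 = 1271."""
        b = L.DDBreakdown(1437.0, 38.0, 128.0)
        assert b.dd_standard == 1271.0

    def test_no_deductions_standard_equals_effective(self):
        series = constant_series(24.0, 20)
        dates = series.dates("air")
        stages = [StageWindow("egg", dates[0], dates[9]),
                  StageWindow("nymph", dates[10], dates[19])]
        b = L.season_breakdown(series, stages)
        assert b.dd_overflow == 0.0
        assert b.dd_ineffective_oviposition == 0.0
        assert b.dd_standard == b.dd_effective

    def test_constant_days_match_closed_form(self):
        # 10 egg days at 25: 10.8 DD/day; 5 hot adult days at 34:
        # effective 19.8, overflow 2.0; plus 5 cool adult days at 18:
        # effective 3.8/day, all ineffective (mean < 21)
        parts = [constant_series(25.0, 10, start=dt.date(2011, 5, 1)),
                 constant_series(34.0, 5, start=dt.date(2011, 5, 11)),
                 constant_series(18.0, 5, start=dt.date(2011, 5, 16))]
        records = [
            L.HourlyRecord(r.date, r.hour, r.temperature, r.sensor)
            for p in parts for r in (
                p.to_frame().itertuples(index=False))
        ]
        series = L.TemperatureSeries(records)
        stages = [StageWindow("egg", dt.date(2011, 5, 1), dt.date(2011, 5, 10)),
                  StageWindow("adult", dt.date(2011, 5, 11), dt.date(2011, 5, 20))]
        b = L.season_breakdown(series, stages, method="degree_hours")
        assert b.dd_effective == pytest.approx(10 * 10.8 + 5 * 19.8 + 5 * 3.8)
        assert b.dd_overflow == pytest.approx(5 * 2.0)
        assert b.dd_ineffective_oviposition == pytest.approx(5 * 3.8)
        assert b.dd_standard == pytest.approx(
            b.dd_effective - b.dd_overflow - b.dd_ineffective_oviposition)

    def test_missing_stage_window_reports_dates(self):
        series = constant_series(24.0, 5)
        stages = [StageWindow("egg", dt.date(2012, 1, 1), dt.date(2012, 1, 3))]
        with pytest.raises(TemperatureDataError, match="2012-01-01"):
            L.season_breakdown(series, stages)

    def test_egg_window_prefers_ground_sensor(self):
        air = constant_series(20.0, 3, sensor="air")
        ground = constant_series(25.0, 3, sensor="ground")
        records = [L.HourlyRecord(r.date, r.hour, r.temperature, r.sensor)
                   for p in (air, ground)
                   for r in p.to_frame().itertuples(index=False)]
        series = L.TemperatureSeries(records)
        dates = series.dates("air")
        b = L.season_breakdown(
            series, [StageWindow("egg", dates[0], dates[-1])],
            method="degree_hours")
        assert b.dd_effective == pytest.approx(3 * (25.0 - 14.2))
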