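"""Hourly temperature I/O and synthetic growth-chamber climates.

Field data come from dataloggers (HOBO-style exports) as one row per hour:
``date,hour,temperature[,sensor]`` with hour indexed 1..24 and sensor either
``air`` or ``ground`` (eggs develop underground, nymphs and adults above
ground, so the two series are kept distinct).  The synthetic generator
emulates the growth-chamber protocol used to rear locusts under
location-specific seasonal climates: a seasonal sequence of 10-day mean
temperatures with a +/-5 degC diurnal cycle superimposed on each day.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SENSORS",
    "HourlyRecord",
    "TemperatureSeries",
    "SyntheticClimateSpec",
    "TemperatureDataError",
    "read_hourly_csv",
    "write_hourly_csv",
    "daily_summary",
    "generate_synthetic_climate",
    "LOCATION_SEASON_DAYS",
    "bell_decade_means",
]

SENSORS = ("air", "ground")

#: Growing-season lengths (days with mean air temperature above the 14.2 degC
#: development threshold) for the seven chamber-simulated Chinese locations,
#: from the high-latitude Baiquan (BQ) up to tropical Qiongshan (QS).
LOCATION_SEASON_DAYS = {
    "BQ": 110,
    "CD": 130,
    "TM": 140,
    "WA": 170,
    "RA": 260,
    "QZ": 360,
    "QS": 360,
}

TEMP_MIN, TEMP_MAX = -60.0, 60.0


class TemperatureDataError(ValueError):
    """Malformed or missing temperature data."""


@dataclass(frozen=True)
class HourlyRecord:
    """One hourly reading: temperature (degC) at ``hour`` (1..24) of ``date``."""

    date: _dt.date
    hour: int
    temperature: float
    sensor: str = "air"

    def __post_init__(self) -> None:
        if not 1 <= self.hour <= 24:
            raise TemperatureDataError(f"hour must be in 1..24, got {self.hour}")
        if not np.isfinite(self.temperature) or not TEMP_MIN <= self.temperature <= TEMP_MAX:
            raise TemperatureDataError(
                f"temperature {self.temperature!r} outside plausible range "
                f"[{TEMP_MIN}, {TEMP_MAX}] degC"
            )
        if self.sensor not in SENSORS:
            raise TemperatureDataError(f"sensor must be one of {SENSORS}, got {self.sensor!r}")


class TemperatureSeries:
    """Ordered collection of hourly records for one location.

    Internally a pandas DataFrame with columns ``date, hour, temperature,
    sensor`` sorted by (sensor, date, hour).  At most 24 records per
    (date, sensor).
    """

    def __init__(self, records: Iterable[HourlyRecord], location_label: str = ""):
        rows = [(r.date, r.hour, r.temperature, r.sensor) for r in records]
        df = pd.DataFrame(rows, columns=["date", "hour", "temperature", "sensor"])
        if not df.empty:
            df = df.sort_values(["sensor", "date", "hour"], kind="stable").reset_index(drop=True)
            dup = df.duplicated(subset=["sensor", "date", "hour"])
            if dup.any():
                bad = df.loc[dup.idxmax()]
                raise TemperatureDataError(
                    f"duplicate reading for {bad.sensor} {bad.date} hour {bad.hour}"
                )
        self._df = df
        self.location_label = location_label

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TemperatureSeries):
            return NotImplemented
        return self.location_label == other.location_label and self._df.equals(other._df)

    def to_frame(self) -> pd.DataFrame:
        """Copy of the underlying ``date,hour,temperature,sensor`` frame."""
        return self._df.copy()

    @property
    def sensors(self) -> list[str]:
        return sorted(self._df["sensor"].unique()) if len(self._df) else []

    def dates(self, sensor: str = "air") -> list[_dt.date]:
        sel = self._df[self._df["sensor"] == sensor]
        return sorted(sel["date"].unique())

    def day(self, date: _dt.date, sensor: str = "air") -> tuple[np.ndarray, np.ndarray]:
        """(hours, temperatures) arrays for one (date, sensor), sorted by hour."""
        sel = self._df[(self._df["date"] == date) & (self._df["sensor"] == sensor)]
        if sel.empty:
            raise TemperatureDataError(f"no {sensor} records for {date}")
        return sel["hour"].to_numpy(dtype=float), sel["temperature"].to_numpy(dtype=float)

    def has_day(self, date: _dt.date, sensor: str = "air") -> bool:
        return bool(
            ((self._df["date"] == date) & (self._df["sensor"] == sensor)).any()
        )


def read_hourly_csv(path, sensor_default: str = "air") -> TemperatureSeries:
    """Read an hourly-temperature CSV into a validated :class:`TemperatureSeries`.

    Required columns: ``date`` (ISO), ``hour`` (1..24), ``temperature`` (degC);
    optional ``sensor`` (air|ground, defaulting to *sensor_default*).  Rows
    violating the invariants are rejected with their 1-based data row number.
    """
    try:
        # round_trip parsing so write -> read preserves readings bit for bit
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise TemperatureDataError(f"cannot parse {path}: {exc}") from exc
    missing = {"date", "hour", "temperature"} - set(df.columns)
    if missing:
        raise TemperatureDataError(f"{path}: missing required column(s) {sorted(missing)}")
    if "sensor" not in df.columns:
        df["sensor"] = sensor_default

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            date = _dt.date.fromisoformat(str(row.date))
            hour = int(row.hour)
            temp = float(row.temperature)
        except (TypeError, ValueError) as exc:
            raise TemperatureDataError(f"{path}: row {i}: {exc}") from exc
        try:
            records.append(HourlyRecord(date, hour, temp, str(row.sensor)))
        except TemperatureDataError as exc:
            raise TemperatureDataError(f"{path}: row {i}: {exc}") from exc
    return TemperatureSeries(records, location_label=str(path))


def write_hourly_csv(series: TemperatureSeries, path) -> None:
    """Write a series back to the ``date,hour,temperature,sensor`` CSV dialect."""
    df = series.to_frame()
    df["date"] = df["date"].map(lambda d: d.isoformat())
    df.to_csv(path, index=False)


def daily_summary(
    series: TemperatureSeries, date: _dt.date, sensor: str = "air"
) -> tuple[float, float, float]:
    """(min, mean, max) of the available hourly readings for one day."""
    _, temps = series.day(date, sensor)
    return float(temps.min()), float(temps.mean()), float(temps.max())


@dataclass(frozen=True)
class SyntheticClimateSpec:
    """Growth-chamber climate recipe.

    One mean temperature per 10-day block (chambers were stepped every 10 d),
    a diurnal half-amplitude (the protocol's +/-5 degC), and a season length
    in days.  ``photoperiod_schedule`` is carried as metadata only — the
    thermal model ignores photoperiod.
    """

    decade_means: Sequence[float]
    diurnal_amplitude: float = 5.0
    season_length_days: int | None = None
    seed: int = 0
    noise_sd: float = 0.0
    sensor: str = "air"
    start_date: _dt.date = _dt.date(2011, 5, 1)
    photoperiod_schedule: Sequence[tuple[float, float]] | None = field(
        default=None, compare=False
    )

    def __post_init__(self) -> None:
        if len(self.decade_means) == 0:
            raise TemperatureDataError("decade_means must not be empty")
        if self.diurnal_amplitude < 0:
            raise TemperatureDataError("diurnal_amplitude must be >= 0")
        n_days = self.season_length_days
        if n_days is None:
            object.__setattr__(self, "season_length_days", 10 * len(self.decade_means))
        else:
            if not 10 * (len(self.decade_means) - 1) < n_days <= 10 * len(self.decade_means):
                raise TemperatureDataError(
                    "season_length_days must fit the 10-day blocks "
                    f"(got {n_days} for {len(self.decade_means)} blocks)"
                )


# Diurnal shape: minimum at 05:00, maximum at 14:00.  Each half-cosine limb
# averages to the block mean, so the continuous-time daily mean equals the
# block mean regardless of amplitude.
_T_MIN_HOUR = 5.0
_T_MAX_HOUR = 14.0


def _diurnal_offset(hour: np.ndarray, amplitude: float) -> np.ndarray:
    h = np.asarray(hour, dtype=float) % 24.0
    rise = (h - _T_MIN_HOUR) % 24.0  # hours since the daily minimum
    rise_len = _T_MAX_HOUR - _T_MIN_HOUR          # 9 h warming limb
    fall_len = 24.0 - rise_len                     # 15 h cooling limb
    out = np.where(
        rise <= rise_len,
        -np.cos(np.pi * rise / rise_len),
        np.cos(np.pi * (rise - rise_len) / fall_len),
    )
    return amplitude * out


def generate_synthetic_climate(spec: SyntheticClimateSpec) -> TemperatureSeries:
    """Generate a deterministic chamber-style hourly series from a spec.

    Day ``d`` (0-based) uses ``decade_means[d // 10]`` as its mean, the
    piecewise-cosine diurnal shape scaled by ``diurnal_amplitude``, and
    optional seeded Gaussian noise (sd ``noise_sd``).  The same seed always
    reproduces the same series bit for bit.
    """
    rng = np.random.default_rng(spec.seed)
    hours = np.arange(1, 25)
    offset = _diurnal_offset(hours, spec.diurnal_amplitude)
    records: list[HourlyRecord] = []
    for d in range(int(spec.season_length_days)):
        mean = float(spec.decade_means[d // 10])
        temps = mean + offset
        if spec.noise_sd > 0:
            temps = temps + rng.normal(0.0, spec.noise_sd, size=24)
        date = spec.start_date + _dt.timedelta(days=d)
        temps = np.clip(temps, TEMP_MIN, TEMP_MAX)
        records.extend(
            HourlyRecord(date, int(h), float(t), spec.sensor) for h, t in zip(hours, temps)
        )
    label = f"synthetic(seed={spec.seed})"
    return TemperatureSeries(records, location_label=label)


def bell_decade_means(
    season_length_days: int, peak: float, edge: float = 14.2
) -> list[float]:
    """Smooth seasonal profile of 10-day means rising from *edge* to *peak*.

    Convenience for building chamber specs: a half-sine arc over the season,
    starting and ending at the growing-season boundary temperature (the
    14.2 degC development threshold by default) and peaking mid-season.
    """
    n = int(np.ceil(season_length_days / 10))
    centers = (np.arange(n) + 0.5) / n
    return [float(edge + (peak - edge) * np.sin(np.pi * c)) for c in centers]
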