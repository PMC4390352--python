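"""Readers and writers for the pipeline's CSV formats.

All traces use an internal clock of *minutes since local midnight of the
first day of the record*.  Input timestamps may be ISO-8601 strings, epoch
seconds, or already-converted minute counts; everything is converted on read.
Body temperatures outside the 0–45 °C logger calibration range are flagged
invalid rather than dropped so that trace alignment is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("heliotherm.io")

__all__ = [
    "TbTrace",
    "WeatherTrace",
    "read_tb_trace",
    "read_weather_trace",
    "write_bout_table",
    "read_bout_table",
    "read_sunrise_table",
    "write_summary_table",
    "CALIBRATION_RANGE",
]

#: Logger calibration range in °C; readings outside it are flagged invalid.
CALIBRATION_RANGE = (0.0, 45.0)

MINUTES_PER_DAY = 1440


@dataclass
class TbTrace:
    """Timestamped body-temperature series for one individual.

    ``time`` is minutes since local midnight of the record's first day;
    ``valid`` flags samples inside the calibration range.
    """

    individual: str
    time: np.ndarray
    tb: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.tb = np.asarray(self.tb, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.time.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.time) == len(self.tb) == len(self.valid)):
            raise ValueError("time, tb and valid must have equal length")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def valid_tb(self) -> np.ndarray:
        """Temperatures of the valid samples only."""
        return self.tb[self.valid]

    @property
    def valid_time(self) -> np.ndarray:
        return self.time[self.valid]

    @property
    def n_days(self) -> int:
        return int(self.time[-1] // MINUTES_PER_DAY) + 1 if len(self) else 0

    def gap_mask(self, expected_interval: float) -> np.ndarray:
        """True where the step from the previous sample exceeds the interval."""
        gaps = np.zeros(len(self), dtype=bool)
        if len(self) > 1:
            gaps[1:] = np.diff(self.time) > expected_interval * 1.5
        return gaps

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_min": self.time, "tb_c": self.tb, "valid": self.valid}
        )


@dataclass
class WeatherTrace:
    """Air temperature and solar irradiance time series.

    ``time`` is minutes since local midnight of day 0; ``irradiance`` in
    W m⁻², ``ta`` in °C.
    """

    time: np.ndarray
    ta: np.ndarray
    irradiance: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ta = np.asarray(self.ta, dtype=float)
        self.irradiance = np.asarray(self.irradiance, dtype=float)
        if not (len(self.time) == len(self.ta) == len(self.irradiance)):
            raise ValueError("weather columns must have equal length")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_days(self) -> int:
        return int(self.time[-1] // MINUTES_PER_DAY) + 1 if len(self) else 0

    def ta_at(self, t) -> np.ndarray:
        return np.interp(t, self.time, self.ta)

    def irradiance_at(self, t) -> np.ndarray:
        return np.interp(t, self.time, self.irradiance)

    def morning_mean_irradiance(
        self, day: int, start: float = 420.0, end: float = 540.0
    ) -> float:
        """Mean irradiance between 07h00 and 09h00 of ``day`` (NaN if no samples)."""
        tod = self.time % MINUTES_PER_DAY
        sel = (self.time // MINUTES_PER_DAY == day) & (tod >= start) & (tod < end)
        if not sel.any():
            return float("nan")
        return float(self.irradiance[sel].mean())


# ---------------------------------------------------------------------------
# timestamp parsing


def _times_to_minutes(series: pd.Series) -> np.ndarray:
    """Convert a timestamp column to minutes since the first day's midnight."""
    if pd.api.types.is_numeric_dtype(series):
        vals = series.to_numpy(dtype=float)
        if np.nanmax(vals) > 1e7:  # epoch seconds
            dt = pd.to_datetime(vals, unit="s")
        else:  # already minutes
            return vals
    else:
        dt = pd.to_datetime(series, format="mixed")
    midnight = dt[0].normalize() if isinstance(dt, pd.DatetimeIndex) else dt.iloc[0].normalize()
    delta = pd.DatetimeIndex(dt) - midnight
    return (delta / pd.Timedelta(minutes=1)).to_numpy(dtype=float)


def _find_column(df: pd.DataFrame, names: Sequence[str], fallback: int | None) -> str:
    lowered = {c.lower().strip(): c for c in df.columns}
    for n in names:
        if n in lowered:
            return lowered[n]
    if fallback is not None and len(df.columns) > fallback:
        return df.columns[fallback]
    raise ValueError(f"no column matching any of {list(names)} found")


# ---------------------------------------------------------------------------
# readers


def read_tb_trace(path: str | Path, individual: str) -> TbTrace:
    """Read a body-temperature logger export.

    The CSV must have a header with a timestamp column (ISO-8601, epoch
    seconds, or minutes) and a temperature column in °C.  Timestamps must be
    strictly increasing; readings outside the 0–45 °C calibration range are
    flagged invalid and kept in place.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty body-temperature file")
    tcol = _find_column(df, ("timestamp", "time", "datetime", "date_time", "time_min"), 0)
    vcol = _find_column(df, ("temperature", "tb", "temp", "tb_c"), 1)
    time = _times_to_minutes(df[tcol])
    tb = df[vcol].to_numpy(dtype=float)
    if len(time) > 1 and not np.all(np.diff(time) > 0):
        raise ValueError(f"{path}: non-monotone timestamps (repeats or reversals)")
    lo, hi = CALIBRATION_RANGE
    valid = np.isfinite(tb) & (tb >= lo) & (tb <= hi)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning(
            "%s: %d sample(s) outside the %s–%s °C calibration range flagged invalid",
            path, n_bad, lo, hi,
        )
    return TbTrace(individual=individual, time=time, tb=tb, valid=valid)


def read_weather_trace(path: str | Path) -> WeatherTrace:
    """Read a weather-station export (timestamp, air temperature, irradiance).

    Negative irradiance readings (sensor noise at night) are clipped to zero
    with a logged warning.  A missing irradiance column is an error.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty weather file")
    tcol = _find_column(df, ("timestamp", "time", "datetime", "time_min"), 0)
    try:
        icol = _find_column(
            df, ("irradiance", "solar", "solar_radiation", "irradiance_wm2"), None
        )
    except ValueError:
        raise ValueError(f"{path}: missing irradiance column") from None
    acol = _find_column(df, ("ta", "air_temperature", "air_temp", "temperature", "ta_c"), 1)
    time = _times_to_minutes(df[tcol])
    irr = df[icol].to_numpy(dtype=float)
    n_neg = int((irr < 0).sum())
    if n_neg:
        logger.warning("%s: %d negative irradiance sample(s) clipped to 0", path, n_neg)
        irr = np.clip(irr, 0.0, None)
    return WeatherTrace(time=time, ta=df[acol].to_numpy(dtype=float), irradiance=irr)


def read_sunrise_table(path: str | Path) -> dict[int, float]:
    """Read a per-day sunrise table: columns ``day`` and ``sunrise``.

    ``sunrise`` may be minutes after midnight or an HH:MM string.
    """
    df = pd.read_csv(path)
    out: dict[int, float] = {}
    scol = _find_column(df, ("sunrise", "sunrise_min", "sunrise_time"), 1)
    dcol = _find_column(df, ("day", "date"), 0)
    for _, row in df.iterrows():
        v = row[scol]
        if isinstance(v, str) and ":" in v:
            hh, mm = v.split(":")
            minutes = int(hh) * 60 + int(mm)
        else:
            minutes = float(v)
        out[int(row[dcol])] = float(minutes)
    return out


# ---------------------------------------------------------------------------
# bout tables

_BOUT_COLUMNS = [
    "individual",
    "entry_min",
    "arousal_onset_min",
    "return_to_threshold_min",
    "attainment_min",
    "duration_min",
    "tb_min_c",
    "rewarming_rate_c_per_min",
]


def write_bout_table(bouts: Iterable, path: str | Path) -> None:
    """Write one CSV row per torpor bout, values rounded to 3 decimals.

    The format round-trips losslessly at that precision via
    :func:`read_bout_table`.
    """
    rows = []
    for b in bouts:
        rows.append(
            {
                "individual": b.individual,
                "entry_min": b.entry_time,
                "arousal_onset_min": b.arousal_onset_time,
                "return_to_threshold_min": b.return_to_threshold_time,
                "attainment_min": b.attainment_time,
                "duration_min": b.duration,
                "tb_min_c": b.tb_min,
                "rewarming_rate_c_per_min": b.rewarming_rate,
            }
        )
    df = pd.DataFrame(rows, columns=_BOUT_COLUMNS)
    for c in _BOUT_COLUMNS[1:]:
        df[c] = df[c].astype(float).round(3)
    df.to_csv(path, index=False)


def read_bout_table(path: str | Path) -> pd.DataFrame:
    """Read a bout table written by :func:`write_bout_table`."""
    df = pd.read_csv(path)
    missing = set(_BOUT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing bout-table columns {sorted(missing)}")
    return df


def write_summary_table(summaries: Iterable, path: str | Path) -> None:
    """Write one CSV row per individual heterothermy summary."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "individual": s.individual,
                "hi_c": s.hi,
                "torpor_frequency_pct": s.torpor_frequency,
                "mean_rewarming_rate_c_per_min": s.mean_rewarming_rate,
                "mean_bout_duration_min": s.mean_bout_duration,
                "n_bouts": s.n_bouts,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
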