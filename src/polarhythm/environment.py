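"""Deterministic models of the two environmental cycles rhythms are phased
against: solar elevation and tidal height, plus extrema (event) detection.

The solar model is a standard low-precision solar-position computation
(fractional-year declination and equation of time, then the hour-angle
altitude formula).  It is accurate to a few tenths of a degree for years
2000–2030, which is sufficient to reproduce the diel *shape* of the sun's
altitude and its above/below-horizon status at high latitude; atmospheric
refraction is not modelled.

The tide model is a pure harmonic superposition

    h(t) = z0 + sum_i A_i * cos(2*pi*t/T_i - phi_i)

over user-supplied constituents.  The default is the principal lunar
semidiurnal constituent M2 (period 12.4206 h), which by itself reproduces a
semidiurnal tide of the ~12.4 h period seen at both study stations; no gauge
data are reproduced.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

M2_PERIOD_H = 12.4206  # principal lunar semidiurnal constituent

EVENT_KINDS = ("solar_max", "solar_min", "high_tide", "low_tide")


@dataclass(frozen=True)
class TidalConstituent:
    """One harmonic tidal constituent."""

    name: str
    period_h: float
    amplitude_m: float = 1.0
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if not self.period_h > 0:
            raise ValueError(f"constituent {self.name!r}: period must be positive")
        if self.amplitude_m < 0:
            raise ValueError(f"constituent {self.name!r}: amplitude must be non-negative")


M2 = TidalConstituent("M2", M2_PERIOD_H, 1.0, 0.0)


@dataclass(frozen=True)
class Event:
    time_h: float
    kind: str  # one of EVENT_KINDS


@dataclass
class EnvCycle:
    """Sampled solar-elevation / tidal-height series with detected extrema."""

    times_h: np.ndarray
    solar_elev_deg: np.ndarray
    tide_m: np.ndarray
    events: list[Event] = field(default_factory=list)

    def events_of(self, *kinds: str) -> list[Event]:
        return [e for e in self.events if e.kind in kinds]


# --------------------------------------------------------------------------
# solar position
# --------------------------------------------------------------------------

def _solar_angles(timestamp_utc: dt.datetime) -> tuple[float, float]:
    """Declination (rad) and equation of time (minutes) for a UTC instant."""
    doy = timestamp_utc.timetuple().tm_yday
    hour = (
        timestamp_utc.hour
        + timestamp_utc.minute / 60.0
        + timestamp_utc.second / 3600.0
    )
    year_len = 366.0 if _is_leap(timestamp_utc.year) else 365.0
    g = 2.0 * math.pi / year_len * (doy - 1 + (hour - 12.0) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(g)
        - 0.032077 * math.sin(g)
        - 0.014615 * math.cos(2 * g)
        - 0.040849 * math.sin(2 * g)
    )
    decl = (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )
    return decl, eqtime


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def solar_elevation(
    latitude_deg: float, longitude_deg: float, timestamp_utc: dt.datetime
) -> float:
    """Solar elevation above the horizon, in degrees, at a UTC instant.

    Positive longitudes are east.  Naive datetimes are interpreted as UTC;
    aware datetimes are converted.
    """
    if abs(latitude_deg) > 90.0:
        raise ValueError("latitude must satisfy |lat| <= 90")
    if not isinstance(timestamp_utc, dt.datetime):
        raise TypeError("timestamp must be a datetime.datetime")
    if timestamp_utc.tzinfo is not None:
        timestamp_utc = timestamp_utc.astimezone(dt.timezone.utc).replace(tzinfo=None)

    decl, eqtime = _solar_angles(timestamp_utc)
    minutes = (
        timestamp_utc.hour * 60.0 + timestamp_utc.minute + timestamp_utc.second / 60.0
    )
    # true solar time, minutes; 4 min of time per degree of longitude
    tst = (minutes + eqtime + 4.0 * longitude_deg) % 1440.0
    ha = math.radians(tst / 4.0 - 180.0)
    lat = math.radians(latitude_deg)
    sin_elev = math.sin(lat) * math.sin(decl) + math.cos(lat) * math.cos(decl) * math.cos(ha)
    return math.degrees(math.asin(min(1.0, max(-1.0, sin_elev))))


def midnight_sun(
    latitude_deg: float,
    longitude_deg: float,
    date: dt.date,
    step_min: int = 10,
) -> bool:
    """True when the sun stays above the horizon for the whole civil day.

    The day is scanned at ``step_min``-minute resolution (<= 10 min).
    """
    if step_min > 10 or step_min < 1:
        raise ValueError("step_min must be in 1..10 minutes")
    start = dt.datetime(date.year, date.month, date.day)
    n = (24 * 60) // step_min
    for k in range(n + 1):
        ts = start + dt.timedelta(minutes=k * step_min)
        if solar_elevation(latitude_deg, longitude_deg, ts) <= 0.0:
            return False
    return True


# --------------------------------------------------------------------------
# tides
# --------------------------------------------------------------------------

def tidal_height(
    time_h: float | np.ndarray,
    constituents: Sequence[TidalConstituent],
    z0_m: float = 0.0,
) -> float | np.ndarray:
    """Harmonic tide height h(t) = z0 + sum A_i cos(2*pi*t/T_i - phi_i), metres."""
    if len(constituents) == 0:
        raise ValueError("at least one tidal constituent is required")
    t = np.asarray(time_h, dtype=float)
    h = np.full(t.shape, float(z0_m))
    for c in constituents:
        h = h + c.amplitude_m * np.cos(2.0 * np.pi * t / c.period_h - c.phase_rad)
    if np.ndim(time_h) == 0:
        return float(h)
    return h


# --------------------------------------------------------------------------
# extrema detection
# --------------------------------------------------------------------------

def cycle_extrema(
    times: Sequence[float] | np.ndarray,
    values: Sequence[float] | np.ndarray,
    max_kind: str = "high_tide",
    min_kind: str = "low_tide",
) -> list[Event]:
    """Interior local extrema of a sampled series.

    An extremum is a sign change of the first difference; a flat plateau at
    an extremum is reported once, at its midpoint (deterministic tie-break).
    The series endpoints are never reported.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or v.shape != t.shape:
        raise ValueError("times and values must be 1-D and of equal length")
    if len(t) < 3:
        raise ValueError("extrema detection needs at least 3 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    d = np.sign(np.diff(v))
    events: list[Event] = []
    # last non-zero slope seen, and the index where the current plateau began
    last_sign = 0.0
    plateau_start = 0
    for i, s in enumerate(d):
        if s == 0.0:
            continue
        if last_sign != 0.0 and s != last_sign:
            # extremum spans samples plateau_start..i (flat in between, if any)
            mid = 0.5 * (t[plateau_start] + t[i])
            kind = max_kind if last_sign > 0 else min_kind
            events.append(Event(float(mid), kind))
        last_sign = s
        plateau_start = i + 1
    events.sort(key=lambda e: e.time_h)
    return events


# --------------------------------------------------------------------------
# combined series
# --------------------------------------------------------------------------

def env_series(
    latitude_deg: float,
    longitude_deg: float,
    start_local: dt.datetime,
    hours: float,
    step_min: float = 10.0,
    constituents: Sequence[TidalConstituent] = (M2,),
    z0_m: float = 0.0,
    utc_offset_h: float = 2.0,
) -> EnvCycle:
    """Solar and tidal series over a sampling window, with extrema events.

    ``start_local`` is local clock time; the campaign convention UTC+2 is the
    default offset.  Tide phase is referenced to the window start.
    """
    if hours <= 0 or step_min <= 0:
        raise ValueError("hours and step_min must be positive")
    n = int(round(hours * 60.0 / step_min))
    times_h = np.arange(n + 1) * (step_min / 60.0)
    start_utc = start_local - dt.timedelta(hours=utc_offset_h)
    solar = np.array(
        [
            solar_elevation(
                latitude_deg, longitude_deg, start_utc + dt.timedelta(hours=float(t))
            )
            for t in times_h
        ]
    )
    tide = np.asarray(tidal_height(times_h, constituents, z0_m=z0_m))
    events = cycle_extrema(times_h, solar, max_kind="solar_max", min_kind="solar_min")
    events += cycle_extrema(times_h, tide, max_kind="high_tide", min_kind="low_tide")
    events.sort(key=lambda e: e.time_h)
    return EnvCycle(times_h, solar, tide, events)
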