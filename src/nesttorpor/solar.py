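"""Sunrise/sunset computation for the colony site.

Implements the NOAA solar-position algorithm (geometric rise/set with the
standard atmospheric-refraction correction at solar altitude -0.833 deg).
Nocturnal statistics elsewhere in the package express bout timing relative
to the sunset and sunrise returned here, so the convention — geometric
rise/set, not civil twilight — matters and is configurable through
``altitude_deg``.

The algorithm is accurate to well under a minute for mid-latitudes, far
inside the +/-2 min agreement expected against published almanac values.
Polar latitudes (|lat| >= 66.5 deg) are rejected explicitly: the site this
package targets is at ~51 deg N and no polar day/night handling is provided.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

__all__ = ["SunTimes", "sun_times", "night_window", "PolarLatitudeError"]

#: solar altitude (degrees) defining geometric rise/set with refraction
STANDARD_ALTITUDE = -0.833

#: latitude beyond which the sun may not rise/set on some dates
POLAR_LATITUDE = 66.5


class PolarLatitudeError(ValueError):
    """Raised for latitudes where polar day or night can occur."""


@dataclass(frozen=True)
class SunTimes:
    """Sunset, following sunrise and solar noon for one civil date.

    All timestamps are timezone-aware. ``sunset`` and ``solar_noon`` fall on
    ``date`` (civil, in the supplied timezone); ``next_sunrise`` is the first
    sunrise after that sunset, i.e. on the following morning.
    """

    date: dt.date
    sunset: dt.datetime
    next_sunrise: dt.datetime
    solar_noon: dt.datetime

    def __post_init__(self) -> None:
        if self.sunset >= self.next_sunrise:
            raise ValueError("sunset must precede next_sunrise")


def _julian_day(date: dt.date, tz_offset_hours: float) -> float:
    """Julian day number of local civil noon, in UT."""
    a = (14 - date.month) // 12
    y = date.year + 4800 - a
    m = date.month + 12 * a - 3
    jdn = (
        date.day
        + (153 * m + 2) // 5
        + 365 * y
        + y // 4
        - y // 100
        + y // 400
        - 32045
    )
    # jdn corresponds to 12:00 UT on `date`; shift to local noon in UT
    return jdn - tz_offset_hours / 24.0


def _solar_quantities(jc: float) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (deg) at Julian century jc."""
    rad = math.radians
    l0 = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    c = (
        math.sin(rad(m)) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(rad(2 * m)) * (0.019993 - 0.000101 * jc)
        + math.sin(rad(3 * m)) * 0.000289
    )
    true_long = l0 + c
    omega = 125.04 - 1934.136 * jc
    app_long = true_long - 0.00569 - 0.00478 * math.sin(rad(omega))
    eps0 = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * math.cos(rad(omega))
    declination = math.degrees(math.asin(math.sin(rad(eps)) * math.sin(rad(app_long))))
    y = math.tan(rad(eps) / 2.0) ** 2
    eot = 4.0 * math.degrees(
        y * math.sin(2 * rad(l0))
        - 2.0 * ecc * math.sin(rad(m))
        + 4.0 * ecc * y * math.sin(rad(m)) * math.cos(2 * rad(l0))
        - 0.5 * y * y * math.sin(4 * rad(l0))
        - 1.25 * ecc * ecc * math.sin(2 * rad(m))
    )
    return eot, declination


def _rise_set_minutes(
    latitude: float, longitude: float, date: dt.date, tz_offset_hours: float,
    altitude_deg: float,
) -> tuple[float, float, float]:
    """Sunrise, solar noon and sunset as minutes past local midnight."""
    jd = _julian_day(date, tz_offset_hours)
    jc = (jd - 2451545.0) / 36525.0
    eot, decl = _solar_quantities(jc)
    rad = math.radians
    cos_ha = (
        math.cos(rad(90.0 - altitude_deg)) / (math.cos(rad(latitude)) * math.cos(rad(decl)))
        - math.tan(rad(latitude)) * math.tan(rad(decl))
    )
    if not -1.0 <= cos_ha <= 1.0:
        raise PolarLatitudeError(
            f"sun does not rise or set at latitude {latitude} on {date}"
        )
    ha = math.degrees(math.acos(cos_ha))  # half the daylight arc, degrees
    noon = 720.0 - 4.0 * longitude - eot + tz_offset_hours * 60.0
    return noon - ha * 4.0, noon, noon + ha * 4.0


def sun_times(
    latitude: float,
    longitude: float,
    date: dt.date,
    timezone: dt.tzinfo | float,
    altitude_deg: float = STANDARD_ALTITUDE,
) -> SunTimes:
    """Compute sunset on ``date`` and the following sunrise.

    Parameters
    ----------
    latitude, longitude
        Site coordinates in decimal degrees (east/north positive).
    date
        Civil date (in the site timezone) whose evening sunset anchors the night.
    timezone
        Either a ``tzinfo`` or a fixed UTC offset in hours (e.g. ``2`` for CEST).
    altitude_deg
        Solar altitude defining rise/set; the default -0.833 deg is the
        standard almanac convention (geometric horizon plus refraction).

    Returns
    -------
    SunTimes
        Timezone-aware sunset, next sunrise and solar noon.

    Raises
    ------
    PolarLatitudeError
        For |latitude| >= 66.5 deg — polar day/night is out of scope.
    """
    if abs(latitude) >= POLAR_LATITUDE:
        raise PolarLatitudeError(
            f"latitude {latitude} not supported (|lat| must be < {POLAR_LATITUDE})"
        )
    if isinstance(timezone, (int, float)):
        tzinfo: dt.tzinfo = dt.timezone(dt.timedelta(hours=timezone))
    else:
        tzinfo = timezone
    offset = tzinfo.utcoffset(dt.datetime.combine(date, dt.time(12)))
    assert offset is not None
    tz_hours = offset.total_seconds() / 3600.0

    _, noon_min, set_min = _rise_set_minutes(latitude, longitude, date, tz_hours, altitude_deg)
    next_date = date + dt.timedelta(days=1)
    rise_min_next, _, _ = _rise_set_minutes(
        latitude, longitude, next_date, tz_hours, altitude_deg
    )

    def at(day: dt.date, minutes: float) -> dt.datetime:
        base = dt.datetime.combine(day, dt.time(0), tzinfo=tzinfo)
        return base + dt.timedelta(minutes=minutes)

    return SunTimes(
        date=date,
        sunset=at(date, set_min),
        next_sunrise=at(next_date, rise_min_next),
        solar_noon=at(date, noon_min),
    )


def night_window(sun: SunTimes) -> tuple[dt.datetime, dt.datetime]:
    """Half-open interval [sunset, next_sunrise) used by all nocturnal statistics."""
    return (sun.sunset, sun.next_sunrise)
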