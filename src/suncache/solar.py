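"""Solar ephemeris: position, sunrise/sunset, observation-period scheduling.

Implements the NOAA low-precision solar position algorithm (Meeus-style
truncated series for declination and the equation of time).  Accuracy is of
order 0.01-0.1 degrees over 1950-2050, far below the angular noise induced
by +/-1.5 m GPS accuracy at the spatial scales this pipeline works on.

Conventions
-----------
* All instants are timezone-aware UTC ``datetime`` objects (naive datetimes
  are rejected).
* Azimuth is measured in degrees clockwise from true north, wrapped to
  ``[0, 360)``.
* Elevation is geometric (no refraction); sunrise/sunset use the standard
  -0.833 degree horizon (refraction + solar semidiameter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as _date
from datetime import datetime, timedelta, timezone

from .errors import InvalidInputError, NoSunEventError

__all__ = [
    "GeoPoint",
    "SolarPosition",
    "DaySchedule",
    "STUDY_SITE",
    "solar_position",
    "sunrise_sunset",
    "observation_periods",
    "mirrored_azimuth",
]

_SUN_HORIZON_DEG = -0.833  # refraction + solar radius


@dataclass(frozen=True)
class GeoPoint:
    """Geographic coordinate in decimal degrees (WGS84-ish sphere)."""

    lat_deg: float
    lon_deg: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat_deg <= 90.0):
            raise InvalidInputError(f"latitude out of range: {self.lat_deg}")
        if not (-180.0 <= self.lon_deg <= 180.0):
            raise InvalidInputError(f"longitude out of range: {self.lon_deg}")


#: Kalahari study site, 26 deg 58' S, 21 deg 49' E.
STUDY_SITE = GeoPoint(lat_deg=-(26 + 58 / 60), lon_deg=21 + 49 / 60)


@dataclass(frozen=True)
class SolarPosition:
    azimuth_deg: float  # clockwise from true north, [0, 360)
    elevation_deg: float  # geometric, [-90, 90]


@dataclass(frozen=True)
class DaySchedule:
    """Sunrise, sunset and the 4 equally spaced observation-period starts
    obtained by dividing daylight into 5 equal intervals."""

    sunrise: datetime
    sunset: datetime
    period_starts: tuple = field(default_factory=tuple)


def _require_utc(t: datetime) -> datetime:
    if not isinstance(t, datetime):
        raise InvalidInputError(f"expected datetime, got {type(t).__name__}")
    if t.tzinfo is None:
        raise InvalidInputError("timestamp must be timezone-aware (UTC)")
    t = t.astimezone(timezone.utc)
    if not (1950 <= t.year <= 2050):
        raise InvalidInputError(
            f"timestamp {t.isoformat()} outside ephemeris validity window 1950-2050"
        )
    return t


def _julian_day(t: datetime) -> float:
    return t.timestamp() / 86400.0 + 2440587.5


def _solar_coordinates(jc: float) -> tuple[float, float, float]:
    """Return (declination_deg, equation_of_time_min, apparent_lon_deg)
    for Julian century ``jc`` since J2000.0 (TT approximated by UT)."""
    l0 = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mrad = math.radians(m)
    eq_center = (
        math.sin(mrad) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * mrad) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * mrad) * 0.000289
    )
    true_lon = l0 + eq_center
    omega = math.radians(125.04 - 1934.136 * jc)
    app_lon = true_lon - 0.00569 - 0.00478 * math.sin(omega)
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(omega)
    obl_rad = math.radians(obliq)
    decl = math.degrees(math.asin(math.sin(obl_rad) * math.sin(math.radians(app_lon))))
    vary = math.tan(obl_rad / 2.0) ** 2
    l0r = math.radians(l0)
    eot = 4.0 * math.degrees(
        vary * math.sin(2 * l0r)
        - 2 * ecc * math.sin(mrad)
        + 4 * ecc * vary * math.sin(mrad) * math.cos(2 * l0r)
        - 0.5 * vary * vary * math.sin(4 * l0r)
        - 1.25 * ecc * ecc * math.sin(2 * mrad)
    )
    return decl, eot, app_lon


def solar_position(t: datetime, loc: GeoPoint = STUDY_SITE) -> SolarPosition:
    """Sun azimuth/elevation at UTC instant ``t`` seen from ``loc``."""
    t = _require_utc(t)
    jd = _julian_day(t)
    jc = (jd - 2451545.0) / 36525.0
    decl, eot, _ = _solar_coordinates(jc)

    minutes_utc = t.hour * 60.0 + t.minute + t.second / 60.0 + t.microsecond / 6e7
    true_solar_min = (minutes_utc + eot + 4.0 * loc.lon_deg) % 1440.0
    hour_angle = true_solar_min / 4.0 - 180.0

    lat = math.radians(loc.lat_deg)
    dec = math.radians(decl)
    ha = math.radians(hour_angle)

    sin_elev = math.sin(lat) * math.sin(dec) + math.cos(lat) * math.cos(dec) * math.cos(ha)
    elev = math.degrees(math.asin(max(-1.0, min(1.0, sin_elev))))

    # azimuth from south (westward positive), then rotated to from-north CW
    az_south = math.atan2(
        math.sin(ha),
        math.cos(ha) * math.sin(lat) - math.tan(dec) * math.cos(lat),
    )
    az = (math.degrees(az_south) + 180.0) % 360.0
    return SolarPosition(azimuth_deg=az, elevation_deg=elev)


def _noon_utc(date: _date, loc: GeoPoint) -> datetime:
    midnight = datetime(date.year, date.month, date.day, tzinfo=timezone.utc)
    jc = (_julian_day(midnight) + 0.5 - 2451545.0) / 36525.0
    _, eot, _ = _solar_coordinates(jc)
    noon_min = 720.0 - 4.0 * loc.lon_deg - eot
    return midnight + timedelta(minutes=noon_min)


def _refine_horizon_crossing(lo: datetime, hi: datetime, loc: GeoPoint) -> datetime:
    """Bisect to the instant where elevation crosses the -0.833 deg horizon."""
    f_lo = solar_position(lo, loc).elevation_deg - _SUN_HORIZON_DEG
    f_hi = solar_position(hi, loc).elevation_deg - _SUN_HORIZON_DEG
    if f_lo * f_hi > 0:
        raise NoSunEventError("no horizon crossing in bracketing window")
    for _ in range(40):  # ~ sub-millisecond resolution
        mid = lo + (hi - lo) / 2
        f_mid = solar_position(mid, loc).elevation_deg - _SUN_HORIZON_DEG
        if f_lo * f_mid <= 0:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
    return lo + (hi - lo) / 2


def sunrise_sunset(date: _date, loc: GeoPoint = STUDY_SITE) -> tuple[datetime, datetime]:
    """UTC sunrise and sunset instants (standard -0.833 deg horizon).

    Raises :class:`NoSunEventError` during polar day/night.
    """
    noon = _noon_utc(date, loc)
    jc = (_julian_day(noon) - 2451545.0) / 36525.0
    decl, _, _ = _solar_coordinates(jc)
    lat = math.radians(loc.lat_deg)
    dec = math.radians(decl)
    cos_ha = (
        math.cos(math.radians(90.0 - _SUN_HORIZON_DEG)) / (math.cos(lat) * math.cos(dec))
        - math.tan(lat) * math.tan(dec)
    )
    if cos_ha > 1.0:
        raise NoSunEventError(f"polar night at {loc} on {date}")
    if cos_ha < -1.0:
        raise NoSunEventError(f"polar day at {loc} on {date}")
    ha_min = timedelta(minutes=4.0 * math.degrees(math.acos(cos_ha)))
    pad = timedelta(minutes=20)
    sunrise = _refine_horizon_crossing(noon - ha_min - pad, noon - ha_min + pad, loc)
    sunset = _refine_horizon_crossing(noon + ha_min - pad, noon + ha_min + pad, loc)
    return sunrise, sunset


def observation_periods(date: _date, loc: GeoPoint = STUDY_SITE) -> DaySchedule:
    """Divide daylight into 5 equal intervals -> 4 interior period starts."""
    sunrise, sunset = sunrise_sunset(date, loc)
    step = (sunset - sunrise) / 5
    starts = tuple(sunrise + step * (i + 1) for i in range(4))
    return DaySchedule(sunrise=sunrise, sunset=sunset, period_starts=starts)


def mirrored_azimuth(az: float) -> float:
    """Reflect an azimuth across the North-South plane: ``(360 - az) % 360``.

    The sun's arc is symmetric about the meridian, so azimuths at mirror-image
    positions on the arc are reflections of one another.
    """
    return (360.0 - float(az) % 360.0) % 360.0
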