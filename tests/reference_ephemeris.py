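"""Independent reference solar-position implementation for oracle tests.

Michalsky (1988) Astronomical Almanac low-precision algorithm, written
separately from the package's NOAA-style implementation: different series,
different sidereal-time/hour-angle path.  Stated accuracy ~0.01 deg over
1950-2050.  Used only as a cross-check; the package never imports this.
"""

import math
from datetime import datetime, timezone


def michalsky_position(t: datetime, lat_deg: float, lon_deg: float):
    """Return (azimuth_deg from north CW, elevation_deg) at UTC instant t."""
    t = t.astimezone(timezone.utc)
    jd = t.timestamp() / 86400.0 + 2440587.5
    n = jd - 2451545.0

    mean_lon = (280.460 + 0.9856474 * n) % 360.0
    mean_anom = math.radians((357.528 + 0.9856003 * n) % 360.0)
    ecl_lon = math.radians(
        (mean_lon + 1.915 * math.sin(mean_anom) + 0.020 * math.sin(2 * mean_anom)) % 360.0
    )
    obliq = math.radians(23.439 - 0.0000004 * n)

    dec = math.asin(math.sin(obliq) * math.sin(ecl_lon))
    ra = math.atan2(math.cos(obliq) * math.sin(ecl_lon), math.cos(ecl_lon))

    ut_hours = t.hour + t.minute / 60.0 + t.second / 3600.0 + t.microsecond / 3.6e9
    # n measured from the same instant includes the UT fraction, so use the
    # midnight-based day number for the GMST polynomial
    n0 = (jd - ut_hours / 24.0) - 2451545.0
    gmst = (6.697375 + 0.0657098242 * n0 + 1.00273790935 * ut_hours) % 24.0
    lmst = (gmst + lon_deg / 15.0) % 24.0
    ha = math.radians(((lmst * 15.0 - math.degrees(ra)) + 180.0) % 360.0 - 180.0)

    lat = math.radians(lat_deg)
    sin_el = math.sin(dec) * math.sin(lat) + math.cos(dec) * math.cos(lat) * math.cos(ha)
    el = math.asin(max(-1.0, min(1.0, sin_el)))
    az = math.atan2(
        -math.cos(dec) * math.sin(ha),
        math.sin(dec) * math.cos(lat) - math.cos(dec) * math.sin(lat) * math.cos(ha),
    )
    return math.degrees(az) % 360.0, math.degrees(el)
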