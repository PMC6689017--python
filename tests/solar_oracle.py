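"""Independent solar-position oracle for sunrise checks.

Low-precision solar ephemeris from the Astronomical Almanac (Meeus-style:
mean longitude/anomaly -> ecliptic longitude -> RA/declination, hour angle
via sidereal time), deliberately different equations from the package's
NOAA implementation. Sunrise is found by scanning apparent solar elevation
minute-by-minute for the ascending threshold crossing, then bisecting.
"""

import math
from datetime import date, datetime, timedelta, timezone


def _julian_day(dt: datetime) -> float:
    y, m = dt.year, dt.month
    d = dt.day + (dt.hour + dt.minute / 60 + dt.second / 3600) / 24
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return int(365.25 * (y + 4716)) + int(30.6001 * (m + 1)) + d + b - 1524.5


def solar_elevation(dt_utc: datetime, lat: float, lon: float) -> float:
    """Geometric solar elevation (degrees) from the Almanac low-precision series."""
    n = _julian_day(dt_utc) - 2451545.0
    L = (280.460 + 0.9856474 * n) % 360.0
    g = math.radians((357.528 + 0.9856003 * n) % 360.0)
    lam = math.radians(L + 1.915 * math.sin(g) + 0.020 * math.sin(2 * g))
    eps = math.radians(23.439 - 0.0000004 * n)
    ra = math.atan2(math.cos(eps) * math.sin(lam), math.cos(lam))
    decl = math.asin(math.sin(eps) * math.sin(lam))
    gmst_h = (18.697374558 + 24.06570982441908 * n) % 24.0
    lst = math.radians((gmst_h * 15.0 + lon) % 360.0)
    ha = lst - ra
    phi = math.radians(lat)
    sin_alt = (math.sin(phi) * math.sin(decl)
               + math.cos(phi) * math.cos(decl) * math.cos(ha))
    return math.degrees(math.asin(max(-1.0, min(1.0, sin_alt))))


def sunrise_by_rootfind(civil_date: date, lat: float, lon: float,
                        threshold_deg: float):
    """UTC sunrise on a civil date: ascending crossing of the threshold."""
    start = datetime(civil_date.year, civil_date.month, civil_date.day,
                     tzinfo=timezone.utc)
    prev = solar_elevation(start, lat, lon)
    for minute in range(1, 24 * 60 + 1):
        t = start + timedelta(minutes=minute)
        cur = solar_elevation(t, lat, lon)
        if prev < threshold_deg <= cur:
            lo, hi = t - timedelta(minutes=1), t
            for _ in range(25):
                mid = lo + (hi - lo) / 2
                if solar_elevation(mid, lat, lon) < threshold_deg:
                    lo = mid
                else:
                    hi = mid
            return lo + (hi - lo) / 2
        prev = cur
    return None
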