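"""Zeitgeber-time normalisation of death times.

A subject's clock time of death is converted to UTC (caller-supplied
timezone offset and daylight-saving flag) and then expressed relative to
sunrise at the death place: ZT = t hours after the previous sunrise when
0 <= t < 18, or t hours before the next sunrise when -6 <= t < 0, giving
a ZT scale on [-6, 18) with ZT 0 at sunrise.

Sunrise is computed with the NOAA solar-position equations (fractional
year, equation of time, solar declination). The sunrise threshold is an
apparent solar elevation of -0.833 deg (atmospheric refraction plus the
solar radius), further depressed by the horizon dip for elevated sites:
dip = 1.76 deg * sqrt(elevation_m) / 60.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone
from typing import Optional

from .datatypes import SubjectRecord, ValidationError

logger = logging.getLogger(__name__)

SUNRISE_ELEVATION_DEG = -0.833


@dataclass
class SolarQuery:
    """Civil date and location for a sunrise computation."""

    date: date
    latitude: float
    longitude: float  # degrees east positive
    elevation: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.latitude) > 90:
            raise ValidationError("|latitude| must be <= 90")
        if self.elevation < -500:
            raise ValidationError("elevation below -500 m is not supported")


def _julian_day_midnight(d: date) -> float:
    y, m = d.year, d.month
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return int(365.25 * (y + 4716)) + int(30.6001 * (m + 1)) + d.day + b - 1524.5


def _eqtime_decl(jd: float):
    """NOAA sunrise-calculator ephemeris: (equation of time [min], declination [rad]).

    Julian-century polynomial form: geometric mean longitude and anomaly,
    equation of center, apparent longitude, obliquity with nutation
    correction. Accurate to a few thousandths of a degree over +-2 centuries
    of J2000.
    """
    jc = (jd - 2451545.0) / 36525.0
    l0 = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    m_anom = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mr = math.radians(m_anom)
    eq_center = (
        math.sin(mr) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * mr) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * mr) * 0.000289
    )
    omega = math.radians(125.04 - 1934.136 * jc)
    app_long = math.radians(l0 + eq_center - 0.00569 - 0.00478 * math.sin(omega))
    eps0 = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    eps = math.radians(eps0 + 0.00256 * math.cos(omega))
    decl = math.asin(math.sin(eps) * math.sin(app_long))
    y = math.tan(eps / 2.0) ** 2
    l0r = math.radians(l0)
    eqtime = 4.0 * math.degrees(
        y * math.sin(2 * l0r)
        - 2.0 * ecc * math.sin(mr)
        + 4.0 * ecc * y * math.sin(mr) * math.cos(2 * l0r)
        - 0.5 * y * y * math.sin(4 * l0r)
        - 1.25 * ecc * ecc * math.sin(2 * mr)
    )
    return eqtime, decl


def solar_elevation_deg(when_utc: datetime, latitude: float,
                        longitude: float) -> float:
    """Apparent-geometry solar elevation (no refraction term) in degrees."""
    minutes = (when_utc.hour * 60.0 + when_utc.minute
               + when_utc.second / 60.0 + when_utc.microsecond / 6e7)
    jd = _julian_day_midnight(when_utc.date()) + minutes / 1440.0
    eqtime, decl = _eqtime_decl(jd)
    tst = minutes + eqtime + 4.0 * longitude  # true solar time, minutes
    ha = math.radians(tst / 4.0 - 180.0)  # hour angle
    lat = math.radians(latitude)
    cos_zen = math.sin(lat) * math.sin(decl) + math.cos(lat) * math.cos(decl) * math.cos(ha)
    cos_zen = min(1.0, max(-1.0, cos_zen))
    return 90.0 - math.degrees(math.acos(cos_zen))


def sunrise_threshold_deg(elevation_m: float) -> float:
    """Solar elevation at sunrise: -0.833 deg minus horizon dip."""
    dip = 1.76 * math.sqrt(max(0.0, elevation_m)) / 60.0
    return SUNRISE_ELEVATION_DEG - dip


def sunrise_utc(q: SolarQuery) -> Optional[datetime]:
    """UTC instant of sunrise on the given civil (UTC) date, or None.

    Returns None in polar regimes where the sun never crosses the sunrise
    threshold on that date (polar day or polar night).
    """
    threshold = sunrise_threshold_deg(q.elevation)
    zenith = math.radians(90.0 - threshold)
    lat = math.radians(q.latitude)
    jd0 = _julian_day_midnight(q.date)

    # First pass with solar noon, then refine the ephemeris at the estimate.
    minutes = 720.0 - 4.0 * q.longitude
    for _ in range(3):
        eqtime, decl = _eqtime_decl(jd0 + minutes / 1440.0)
        cos_ha = (math.cos(zenith) - math.sin(lat) * math.sin(decl)) / (
            math.cos(lat) * math.cos(decl)
        )
        if cos_ha > 1.0 or cos_ha < -1.0:
            return None  # sun never reaches / never leaves the threshold
        ha_deg = math.degrees(math.acos(cos_ha))
        # wrap into the queried civil date (matters near the antimeridian)
        minutes = (720.0 - 4.0 * (q.longitude + ha_deg) - eqtime) % 1440.0
    base = datetime(q.date.year, q.date.month, q.date.day, tzinfo=timezone.utc)
    return base + timedelta(minutes=minutes)


def local_death_to_utc(death_local: datetime, tz_offset_hours: float,
                       dst_flag: bool) -> datetime:
    """UTC = local - tz_offset - (1 h if daylight saving was in effect)."""
    if not (-12.0 <= tz_offset_hours <= 14.0):
        raise ValidationError("tz_offset_hours must lie in [-12, +14]")
    naive = death_local.replace(tzinfo=None)
    utc = naive - timedelta(hours=tz_offset_hours) - timedelta(hours=1 if dst_flag else 0)
    return utc.replace(tzinfo=timezone.utc)


def utc_to_zt(death_utc: datetime, q: SolarQuery) -> float:
    """Zeitgeber time of a UTC death instant, in hours on [-6, 18).

    Finds the most recent sunrise at the death place before death (t1 hours
    ago) and the next sunrise after it; returns t1 when t1 < 18, otherwise
    the negative count-down to the next sunrise. Because consecutive
    sunrises are not exactly 24 h apart the second branch can drift slightly
    outside [-6, 0); the result is wrapped back into [-6, 18) and a warning
    is logged when the adjustment exceeds 0.25 h.
    """
    if death_utc.tzinfo is None:
        death_utc = death_utc.replace(tzinfo=timezone.utc)
    sunrises = []
    for delta in range(-2, 3):
        d = death_utc.date() + timedelta(days=delta)
        s = sunrise_utc(SolarQuery(d, q.latitude, q.longitude, q.elevation))
        if s is not None:
            sunrises.append(s)
    if not any(abs((s - death_utc).total_seconds()) <= 48 * 3600 for s in sunrises):
        raise ValidationError("polar regime; ZT undefined (no sunrise within 48 h)")
    before = [s for s in sunrises if s <= death_utc]
    after = [s for s in sunrises if s > death_utc]
    if not before or not after:
        raise ValidationError("polar regime; ZT undefined (no bracketing sunrises)")
    t1 = (death_utc - max(before)).total_seconds() / 3600.0
    if t1 < 18.0:
        zt = t1
    else:
        zt = -(min(after) - death_utc).total_seconds() / 3600.0
    wrapped = ((zt + 6.0) % 24.0) - 6.0
    if abs(wrapped - zt) > 0.25 and abs(abs(wrapped - zt) - 24.0) > 0.25:
        logger.warning("ZT %0.3f wrapped to %0.3f (sunrise-interval drift)", zt, wrapped)
    return wrapped


def day_night_label(zt: float) -> str:
    """"day" iff zt in [0, 12); the rest of [-6, 18) maps to ZT12-24 night."""
    if not (-6.0 <= zt < 18.0):
        raise ValidationError(f"zt {zt} outside [-6, 18)")
    return "day" if 0.0 <= zt < 12.0 else "night"


def derive_zt(record: SubjectRecord) -> float:
    """ZT for one subject: precomputed value if present, else solar-derived."""
    if record.zt is not None:
        return record.zt
    if not record.has_death_place:
        raise ValidationError(f"{record.subject_id}: no zt and no death-place fields")
    death_utc = local_death_to_utc(
        record.death_local, record.tz_offset_hours, record.dst_flag
    )
    q = SolarQuery(death_utc.date(), record.latitude, record.longitude,
                   record.elevation)
    return utc_to_zt(death_utc, q)


def annotate_zt(records: list[SubjectRecord]) -> list[SubjectRecord]:
    """Fill in zt (and leave existing values untouched) for a cohort."""
    for r in records:
        if r.zt is None:
            r.zt = derive_zt(r)
    return records
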