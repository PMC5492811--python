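"""Solar position and sensor-footprint geometry.

The solar ephemeris follows the NOAA general solar position
calculations (truncated VSOP-style series for the solar longitude,
obliquity and equation of time), accurate to well under 0.1 degree for
the satellite era — ample for acquisition metadata, where the dominant
uncertainty is the exact image-center location.  Azimuth is measured
clockwise from north; zenith is the complement of the (unrefracted)
solar elevation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timezone

__all__ = ["Acquisition", "solar_position", "sensor_footprint"]


@dataclass(frozen=True)
class Acquisition:
    """Acquisition metadata of one flight or measurement session."""

    timestamp: datetime
    latitude: float
    longitude: float
    sza: float
    saa: float

    def __post_init__(self):
        if not 0 <= self.sza <= 90:
            raise ValueError("sza must lie in [0, 90] deg (daytime)")
        if not 0 <= self.saa < 360:
            raise ValueError("saa must lie in [0, 360) deg")


def _julian_day(dt_utc: datetime) -> float:
    y, m = dt_utc.year, dt_utc.month
    d = dt_utc.day + (dt_utc.hour + dt_utc.minute / 60 + dt_utc.second / 3600) / 24
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def solar_position(lat: float, lon: float, when: datetime) -> tuple[float, float]:
    """Solar zenith and azimuth (degrees) at a site and time.

    ``when`` must be timezone-aware (it is converted to UTC).  Azimuth
    is clockwise from north; zenith + elevation = 90 exactly.
    """
    if when.tzinfo is None:
        raise ValueError("timestamp must be timezone-aware")
    dt = when.astimezone(timezone.utc)
    jd = _julian_day(dt)
    t = (jd - 2451545.0) / 36525.0

    mean_long = (280.46646 + t * (36000.76983 + 0.0003032 * t)) % 360
    mean_anom = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    ecc = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    ma = math.radians(mean_anom)
    eq_center = (
        math.sin(ma) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + math.sin(2 * ma) * (0.019993 - 0.000101 * t)
        + math.sin(3 * ma) * 0.000289
    )
    true_long = mean_long + eq_center
    omega = math.radians(125.04 - 1934.136 * t)
    app_long = true_long - 0.00569 - 0.00478 * math.sin(omega)
    mean_obliq = 23 + (26 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60) / 60
    obliq = mean_obliq + 0.00256 * math.cos(omega)

    decl = math.asin(math.sin(math.radians(obliq)) * math.sin(math.radians(app_long)))
    y = math.tan(math.radians(obliq / 2)) ** 2
    ml = math.radians(mean_long)
    eq_time_min = 4 * math.degrees(
        y * math.sin(2 * ml)
        - 2 * ecc * math.sin(ma)
        + 4 * ecc * y * math.sin(ma) * math.cos(2 * ml)
        - 0.5 * y * y * math.sin(4 * ml)
        - 1.25 * ecc * ecc * math.sin(2 * ma)
    )
    minutes_utc = dt.hour * 60 + dt.minute + dt.second / 60
    true_solar_min = (minutes_utc + eq_time_min + 4 * lon) % 1440
    hour_angle = true_solar_min / 4 - 180 if true_solar_min / 4 >= 0 else true_solar_min / 4 + 180

    phi = math.radians(lat)
    ha = math.radians(hour_angle)
    cos_zen = math.sin(phi) * math.sin(decl) + math.cos(phi) * math.cos(decl) * math.cos(ha)
    cos_zen = max(-1.0, min(1.0, cos_zen))
    zenith = math.degrees(math.acos(cos_zen))
    sin_zen = math.sin(math.radians(zenith))
    if sin_zen == 0:
        return zenith, 0.0
    cos_az = (math.sin(phi) * cos_zen - math.sin(decl)) / (math.cos(phi) * sin_zen)
    cos_az = max(-1.0, min(1.0, cos_az))
    az = math.degrees(math.acos(cos_az))
    azimuth = (az + 180) % 360 if hour_angle > 0 else (540 - az) % 360
    return zenith, azimuth


def sensor_footprint(fov_degrees: float, height_m: float) -> tuple[float, float]:
    """Footprint (diameter m, area m^2) of a conical-FOV sensor.

    diameter = 2 * height * tan(fov / 2); area of the circular
    footprint on a flat canopy top.  A 28-degree FOV at 1 m gives a
    diameter of about 0.5 m and an area of about 0.20 m^2.
    """
    if not 0 < fov_degrees < 180:
        raise ValueError("field of view must lie in (0, 180) deg")
    if height_m <= 0:
        raise ValueError("height must be positive")
    diameter = 2.0 * height_m * math.tan(math.radians(fov_degrees) / 2.0)
    area = math.pi * (diameter / 2.0) ** 2
    return diameter, area
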