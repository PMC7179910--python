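"""Independent reference ephemeris used only by the test suite.

Implements the *Astronomical Almanac* low-precision formulas for the sun
(accuracy ~0.01 deg) and moon (accuracy ~0.3 deg in ecliptic position,
horizontal parallax from its own cosine series) — a different published
formulation from the package's NOAA/Meeus core, serving as a
cross-implementation oracle.  Scalar-only, deliberately plain.
"""

from __future__ import annotations

import math

import pandas as pd

D2R = math.pi / 180.0
R2D = 180.0 / math.pi


def _jd(timestamp) -> float:
    ts = pd.Timestamp(timestamp)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    return ts.value / 86400.0e9 + 2440587.5


def _gmst_deg(jd: float) -> float:
    # Almanac approximation: GMST = 18.697374558 + 24.06570982441908*D hours
    d = jd - 2451545.0
    return (18.697374558 + 24.06570982441908 * d) * 15.0 % 360.0


def _altitude(jd: float, ra: float, dec: float, lon: float, lat: float) -> float:
    h = (_gmst_deg(jd) + lon - ra) * D2R
    sin_alt = (math.sin(lat * D2R) * math.sin(dec * D2R)
               + math.cos(lat * D2R) * math.cos(dec * D2R) * math.cos(h))
    return math.asin(max(-1.0, min(1.0, sin_alt))) * R2D


def sun_equatorial(timestamp):
    """Almanac page-C24 low-precision solar RA/dec (deg), distance (AU)."""
    jd = _jd(timestamp)
    n = jd - 2451545.0
    g = (357.528 + 0.9856003 * n) * D2R
    lam = ((280.460 + 0.9856474 * n) + 1.915 * math.sin(g)
           + 0.020 * math.sin(2 * g)) * D2R
    eps = (23.439 - 0.0000004 * n) * D2R
    ra = math.atan2(math.cos(eps) * math.sin(lam), math.cos(lam)) * R2D % 360.0
    dec = math.asin(math.sin(eps) * math.sin(lam)) * R2D
    dist = 1.00014 - 0.01671 * math.cos(g) - 0.00014 * math.cos(2 * g)
    return ra, dec, dist


def sun_altitude(timestamp, lon: float, lat: float) -> float:
    jd = _jd(timestamp)
    ra, dec, _ = sun_equatorial(timestamp)
    return _altitude(jd, ra, dec, lon, lat)


def moon_equatorial(timestamp):
    """Almanac low-precision lunar RA/dec (deg) and horizontal parallax (deg)."""
    jd = _jd(timestamp)
    t = (jd - 2451545.0) / 36525.0
    lam = (218.32 + 481267.881 * t
           + 6.29 * math.sin((135.0 + 477198.87 * t) * D2R)
           - 1.27 * math.sin((259.3 - 413335.36 * t) * D2R)
           + 0.66 * math.sin((235.7 + 890534.22 * t) * D2R)
           + 0.21 * math.sin((269.9 + 954397.74 * t) * D2R)
           - 0.19 * math.sin((357.5 + 35999.05 * t) * D2R)
           - 0.11 * math.sin((186.5 + 966404.03 * t) * D2R))
    beta = (5.13 * math.sin((93.3 + 483202.02 * t) * D2R)
            + 0.28 * math.sin((228.2 + 960400.89 * t) * D2R)
            - 0.28 * math.sin((318.3 + 6003.15 * t) * D2R)
            - 0.17 * math.sin((217.6 - 407332.21 * t) * D2R))
    parallax = (0.9508
                + 0.0518 * math.cos((135.0 + 477198.87 * t) * D2R)
                + 0.0095 * math.cos((259.3 - 413335.36 * t) * D2R)
                + 0.0078 * math.cos((235.7 + 890534.22 * t) * D2R)
                + 0.0028 * math.cos((269.9 + 954397.74 * t) * D2R))
    eps = (23.439 - 0.0000004 * (jd - 2451545.0)) * D2R
    lr, br = lam * D2R, beta * D2R
    ra = math.atan2(math.sin(lr) * math.cos(eps) - math.tan(br) * math.sin(eps),
                    math.cos(lr)) * R2D % 360.0
    dec = math.asin(math.sin(br) * math.cos(eps)
                    + math.cos(br) * math.sin(eps) * math.sin(lr)) * R2D
    return ra, dec, parallax


def moon_altitude(timestamp, lon: float, lat: float) -> float:
    """Topocentric lunar altitude, same first-order parallax convention."""
    jd = _jd(timestamp)
    ra, dec, parallax = moon_equatorial(timestamp)
    alt_geo = _altitude(jd, ra, dec, lon, lat)
    return alt_geo - parallax * math.cos(alt_geo * D2R)


def moon_illuminated_fraction(timestamp) -> float:
    ra_s, dec_s, dist_s_au = sun_equatorial(timestamp)
    ra_m, dec_m, parallax = moon_equatorial(timestamp)
    dist_m = 6378.14 / math.sin(parallax * D2R)
    cos_psi = (math.sin(dec_s * D2R) * math.sin(dec_m * D2R)
               + math.cos(dec_s * D2R) * math.cos(dec_m * D2R)
               * math.cos((ra_s - ra_m) * D2R))
    psi = math.acos(max(-1.0, min(1.0, cos_psi)))
    dist_s = dist_s_au * 149597870.7
    i = math.atan2(dist_s * math.sin(psi), dist_m - dist_s * math.cos(psi))
    return (1.0 + math.cos(i)) / 2.0
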