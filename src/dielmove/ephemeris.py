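"""Sun and moon geometry for biologging covariates.

Computes the three astronomical covariates attached to every sensor record:
``SunAlt`` (solar altitude, degrees, signed), ``MoonAlt`` (lunar altitude,
degrees, signed, with a single mean-parallax topocentric correction) and
``MoonIlluminatedFrac`` (fraction of the lunar disc illuminated, 0-1).

Solar position follows the NOAA / Meeus low-precision algorithm (geometric
altitude, no atmospheric refraction; accuracy well under 0.1 deg for
2010-2030).  Lunar ecliptic position uses a truncated Meeus periodic series
(the dominant longitude/latitude/distance terms plus the additive arguments),
good to a few hundredths of a degree, followed by the standard equatorial
transform and the first-order parallax correction
``alt_topo = alt_geo - pi_moon * cos(alt_geo)``.

All timestamps are UTC (treated as UT1; the ~1 min difference from TT moves
the lunar altitude by well under the documented tolerance).  Everything is
vectorised over numpy arrays; scalar inputs return scalars.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "julian_day",
    "sun_altitude",
    "moon_altitude",
    "moon_illuminated_fraction",
    "attribute_ephemeris",
    "moon_phase_instants",
]

_D2R = np.pi / 180.0
_R2D = 180.0 / np.pi

# equatorial Earth radius / mean lunar-distance parallax convention
_EARTH_RADIUS_KM = 6378.14


def _check_site(lon: float, lat: float) -> None:
    if not (-180.0 <= lon <= 180.0):
        raise ValueError(f"longitude {lon!r} outside [-180, 180]")
    if not (-90.0 <= lat <= 90.0):
        raise ValueError(f"latitude {lat!r} outside [-90, 90]")


def julian_day(timestamp) -> np.ndarray | float:
    """Julian day (UTC) for a timestamp or array of timestamps."""
    ts = pd.to_datetime(timestamp, utc=True)
    if isinstance(ts, pd.Timestamp):
        epoch_ns = ts.value
        return epoch_ns / 86400.0e9 + 2440587.5
    ts = pd.DatetimeIndex(ts)
    return ts.asi8.astype(float) / 86400.0e9 + 2440587.5


def _gmst_deg(jd):
    """Greenwich mean sidereal time in degrees."""
    t = (jd - 2451545.0) / 36525.0
    gmst = (
        280.46061837
        + 360.98564736629 * (jd - 2451545.0)
        + 0.000387933 * t * t
        - t ** 3 / 38710000.0
    )
    return gmst % 360.0


def _sun_equatorial(jd):
    """Geocentric solar RA/dec (deg) and distance (AU), NOAA/Meeus."""
    t = (jd - 2451545.0) / 36525.0
    l0 = (280.46646 + 36000.76983 * t + 0.0003032 * t * t) % 360.0
    m = 357.52911 + 35999.05029 * t - 0.0001537 * t * t
    e = 0.016708634 - 0.000042037 * t - 0.0000001267 * t * t
    mr = m * _D2R
    c = (
        (1.914602 - 0.004817 * t - 0.000014 * t * t) * np.sin(mr)
        + (0.019993 - 0.000101 * t) * np.sin(2 * mr)
        + 0.000289 * np.sin(3 * mr)
    )
    true_lon = l0 + c
    true_anom = m + c
    dist_au = (1.000001018 * (1 - e * e)) / (1 + e * np.cos(true_anom * _D2R))
    omega = 125.04 - 1934.136 * t
    app_lon = true_lon - 0.00569 - 0.00478 * np.sin(omega * _D2R)
    eps0 = (
        23.0 + (26.0 + 21.448 / 60.0) / 60.0
        - (46.8150 * t + 0.00059 * t * t - 0.001813 * t ** 3) / 3600.0
    )
    eps = eps0 + 0.00256 * np.cos(omega * _D2R)
    lr, er = app_lon * _D2R, eps * _D2R
    ra = np.arctan2(np.cos(er) * np.sin(lr), np.cos(lr)) * _R2D
    dec = np.arcsin(np.sin(er) * np.sin(lr)) * _R2D
    return ra % 360.0, dec, dist_au


def _altitude_from_equatorial(jd, ra_deg, dec_deg, lon, lat):
    """Geometric altitude (deg) from RA/dec and site."""
    h = (_gmst_deg(jd) + lon - ra_deg) * _D2R
    latr = lat * _D2R
    decr = dec_deg * _D2R
    sin_alt = np.sin(latr) * np.sin(decr) + np.cos(latr) * np.cos(decr) * np.cos(h)
    return np.arcsin(np.clip(sin_alt, -1.0, 1.0)) * _R2D


def sun_altitude(timestamp, lon: float, lat: float):
    """Geometric solar altitude in degrees (positive above the horizon)."""
    _check_site(lon, lat)
    jd = julian_day(timestamp)
    ra, dec, _ = _sun_equatorial(jd)
    return _altitude_from_equatorial(jd, ra, dec, lon, lat)


# Meeus truncated lunar periodic terms: (D, M, M', F, sigma_l [1e-6 deg],
# sigma_r [1e-3 km]) -- the dominant longitude/distance terms.
_MOON_LR = np.array([
    (0, 0, 1, 0, 6288774, -20905355),
    (2, 0, -1, 0, 1274027, -3699111),
    (2, 0, 0, 0, 658314, -2955968),
    (0, 0, 2, 0, 213618, -569925),
    (0, 1, 0, 0, -185116, 48888),
    (0, 0, 0, 2, -114332, -3149),
    (2, 0, -2, 0, 58793, 246158),
    (2, -1, -1, 0, 57066, -152138),
    (2, 0, 1, 0, 53322, -170733),
    (2, -1, 0, 0, 45758, -204586),
    (0, 1, -1, 0, -40923, -129620),
    (1, 0, 0, 0, -34720, 108743),
    (0, 1, 1, 0, -30383, 104755),
    (2, 0, 0, -2, 15327, 10321),
    (0, 0, 1, 2, -12528, 0),
    (0, 0, 1, -2, 10980, 79661),
    (4, 0, -1, 0, 10675, -34782),
    (0, 0, 3, 0, 10034, -23210),
    (4, 0, -2, 0, 8548, -21636),
    (2, 1, -1, 0, -7888, 24208),
    (2, 1, 0, 0, -6766, 30824),
    (1, 0, -1, 0, -5163, -8379),
    (1, 1, 0, 0, 4987, -16675),
    (2, -1, 1, 0, 4036, -12831),
    (2, 0, 2, 0, 3994, -10445),
    (4, 0, 0, 0, 3861, -11650),
    (2, 0, -3, 0, 3665, 14403),
    (0, 1, -2, 0, -2689, -7003),
    (2, 0, -1, 2, -2602, 0),
    (2, -1, -2, 0, 2390, 10056),
    (1, 0, 1, 0, -2348, 6322),
    (2, -2, 0, 0, 2236, -9884),
], dtype=float)

# latitude terms: (D, M, M', F, sigma_b [1e-6 deg])
_MOON_B = np.array([
    (0, 0, 0, 1, 5128122),
    (0, 0, 1, 1, 280602),
    (0, 0, 1, -1, 277693),
    (2, 0, 0, -1, 173237),
    (2, 0, -1, 1, 55413),
    (2, 0, -1, -1, 46271),
    (2, 0, 0, 1, 32573),
    (0, 0, 2, 1, 17198),
    (2, 0, 1, -1, 9266),
    (0, 0, 2, -1, 8822),
    (2, -1, 0, -1, 8216),
    (2, 0, -2, -1, 4324),
    (2, 0, 1, 1, 4200),
    (2, 1, 0, -1, -3359),
    (2, -1, -1, 1, 2463),
    (2, -1, 0, 1, 2211),
    (2, -1, -1, -1, 2065),
    (0, 1, -1, -1, -1870),
    (4, 0, -1, -1, 1828),
    (0, 1, 0, 1, -1794),
], dtype=float)


def _moon_ecliptic(jd):
    """Geocentric lunar ecliptic lon/lat (deg) and distance (km), Meeus."""
    jd_in = np.asarray(jd, dtype=float)
    scalar = jd_in.ndim == 0
    jd = np.atleast_1d(jd_in)
    t = (jd - 2451545.0) / 36525.0
    lp = (218.3164477 + 481267.88123421 * t - 0.0015786 * t * t
          + t ** 3 / 538841.0 - t ** 4 / 65194000.0)
    d = (297.8501921 + 445267.1114034 * t - 0.0018819 * t * t
         + t ** 3 / 545868.0 - t ** 4 / 113065000.0)
    m = 357.5291092 + 35999.0502909 * t - 0.0001536 * t * t + t ** 3 / 24490000.0
    mp = (134.9633964 + 477198.8675055 * t + 0.0087414 * t * t
          + t ** 3 / 69699.0 - t ** 4 / 14712000.0)
    f = (93.2720950 + 483202.0175233 * t - 0.0036539 * t * t
         - t ** 3 / 3526000.0 + t ** 4 / 863310000.0)
    ecc = 1.0 - 0.002516 * t - 0.0000074 * t * t

    args = np.stack([d, m, mp, f], axis=-1)  # (n, 4)

    def _angles_efac(table):
        ang = args @ table[:, :4].T * _D2R  # (n, n_terms)
        m_mult = np.abs(table[:, 1])  # eccentricity damping for M-terms
        e_fac = np.ones_like(ang)
        e_fac[:, m_mult == 1] = ecc[:, None]
        e_fac[:, m_mult == 2] = (ecc ** 2)[:, None]
        return ang, e_fac

    ang_lr, e_lr = _angles_efac(_MOON_LR)
    sum_l = (e_lr * np.sin(ang_lr)) @ _MOON_LR[:, 4]
    sum_r = (e_lr * np.cos(ang_lr)) @ _MOON_LR[:, 5]
    ang_b, e_b = _angles_efac(_MOON_B)
    sum_b = (e_b * np.sin(ang_b)) @ _MOON_B[:, 4]

    a1 = (119.75 + 131.849 * t) * _D2R
    a2 = (53.09 + 479264.290 * t) * _D2R
    a3 = (313.45 + 481266.484 * t) * _D2R
    sum_l = sum_l + 3958 * np.sin(a1) + 1962 * np.sin((lp - f) * _D2R) + 318 * np.sin(a2)
    sum_b = (sum_b - 2235 * np.sin(lp * _D2R) + 382 * np.sin(a3)
             + 175 * np.sin(a1 - f * _D2R) + 175 * np.sin(a1 + f * _D2R)
             + 127 * np.sin((lp - mp) * _D2R) - 115 * np.sin((lp + mp) * _D2R))

    lon = (lp + sum_l * 1e-6) % 360.0
    lat = sum_b * 1e-6
    dist = 385000.56 + sum_r * 1e-3
    if scalar:
        return float(lon[0]), float(lat[0]), float(dist[0])
    return lon, lat, dist


def _moon_equatorial(jd):
    lon, lat, dist = _moon_ecliptic(jd)
    t = (jd - 2451545.0) / 36525.0
    eps = (23.0 + (26.0 + 21.448 / 60.0) / 60.0
           - (46.8150 * t + 0.00059 * t * t - 0.001813 * t ** 3) / 3600.0) * _D2R
    lr, br = lon * _D2R, lat * _D2R
    ra = np.arctan2(
        np.sin(lr) * np.cos(eps) - np.tan(br) * np.sin(eps), np.cos(lr)
    ) * _R2D
    dec = np.arcsin(
        np.clip(np.sin(br) * np.cos(eps) + np.cos(br) * np.sin(eps) * np.sin(lr),
                -1.0, 1.0)
    ) * _R2D
    return ra % 360.0, dec, dist


def moon_altitude(timestamp, lon: float, lat: float):
    """Topocentric lunar altitude in degrees (first-order parallax)."""
    _check_site(lon, lat)
    jd = julian_day(timestamp)
    ra, dec, dist = _moon_equatorial(jd)
    alt_geo = _altitude_from_equatorial(jd, ra, dec, lon, lat)
    parallax = np.arcsin(_EARTH_RADIUS_KM / dist) * _R2D
    return alt_geo - parallax * np.cos(alt_geo * _D2R)


def moon_illuminated_fraction(timestamp):
    """Fraction (0-1) of the lunar disc illuminated, from the phase angle."""
    jd = julian_day(timestamp)
    ra_s, dec_s, dist_s = _sun_equatorial(jd)
    ra_m, dec_m, dist_m = _moon_equatorial(jd)
    cos_psi = (
        np.sin(dec_s * _D2R) * np.sin(dec_m * _D2R)
        + np.cos(dec_s * _D2R) * np.cos(dec_m * _D2R)
        * np.cos((ra_s - ra_m) * _D2R)
    )
    psi = np.arccos(np.clip(cos_psi, -1.0, 1.0))
    dist_s_km = dist_s * 149597870.7
    # phase angle at the moon: sun-moon-earth triangle
    i = np.arctan2(dist_s_km * np.sin(psi), dist_m - dist_s_km * np.cos(psi))
    return (1.0 + np.cos(i)) / 2.0


def attribute_ephemeris(records: pd.DataFrame, lon: float, lat: float,
                        timestamp_col: str = "timestamp") -> pd.DataFrame:
    """Attach SunAlt, MoonAlt and MoonIlluminatedFrac columns to records.

    One-to-one augmentation: the output has the same rows in the same order
    with three additional columns.  Duplicate timestamps receive identical
    values (the computation is a pure function of timestamp and site).
    """
    _check_site(lon, lat)
    out = records.copy()
    if len(out) == 0:
        out["SunAlt"] = pd.Series(dtype=float)
        out["MoonAlt"] = pd.Series(dtype=float)
        out["MoonIlluminatedFrac"] = pd.Series(dtype=float)
        return out
    ts = pd.DatetimeIndex(pd.to_datetime(out[timestamp_col], utc=True))
    out["SunAlt"] = np.asarray(sun_altitude(ts, lon, lat))
    out["MoonAlt"] = np.asarray(moon_altitude(ts, lon, lat))
    out["MoonIlluminatedFrac"] = np.asarray(moon_illuminated_fraction(ts))
    return out


def moon_phase_instants(start, end, kind: str = "full",
                        step_minutes: int = 30) -> pd.DatetimeIndex:
    """Instants of full ('full') or new ('new') moon between two timestamps.

    Located as local extrema of the illuminated fraction on a coarse grid,
    then refined by golden-section search to ~1 minute.  Used by the
    synthetic collar scheduler to centre high-frequency windows.
    """
    if kind not in ("full", "new"):
        raise ValueError("kind must be 'full' or 'new'")
    start = pd.Timestamp(start, tz="UTC") if pd.Timestamp(start).tzinfo is None else pd.Timestamp(start)
    end = pd.Timestamp(end, tz="UTC") if pd.Timestamp(end).tzinfo is None else pd.Timestamp(end)
    pad = pd.Timedelta(days=2)
    grid = pd.date_range(start - pad, end + pad, freq=f"{step_minutes}min")
    frac = np.asarray(moon_illuminated_fraction(grid))
    sign = 1.0 if kind == "full" else -1.0
    y = sign * frac
    idx = np.nonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:]))[0] + 1
    out = []
    for i in idx:
        lo, hi = grid[i - 1], grid[i + 1]
        for _ in range(25):  # golden-section refine
            m1 = lo + (hi - lo) * 0.382
            m2 = lo + (hi - lo) * 0.618
            if sign * float(moon_illuminated_fraction(m1)) > sign * float(moon_illuminated_fraction(m2)):
                hi = m2
            else:
                lo = m1
        t = lo + (hi - lo) / 2
        if start <= t <= end:
            out.append(t.round("min"))
    return pd.DatetimeIndex(out)
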