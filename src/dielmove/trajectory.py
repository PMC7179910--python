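"""GPS fixes to censored high-frequency step velocities ("True Velocity").

A step velocity is the great-circle distance between consecutive retained
fixes divided by the time lag in hours, stamped at the interval end.  Fixes
are censored on HDOP (fix-quality) and on the lag falling inside the
high-frequency window around the nominal 30-min schedule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["haversine_m", "censor_fixes", "step_velocity", "true_velocity"]

EARTH_RADIUS_M = 6_371_000.0

GPS_COLUMNS = ["individual_id", "species", "timestamp", "lon", "lat", "hdop"]


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in metres on a sphere of mean Earth radius."""
    lon1, lat1, lon2, lat2 = (np.deg2rad(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _check_sorted(fixes: pd.DataFrame) -> None:
    for ind, grp in fixes.groupby("individual_id", sort=False):
        ts = pd.DatetimeIndex(grp["timestamp"])
        if len(ts) > 1 and not (ts[1:] > ts[:-1]).all():
            raise ValueError(
                f"fixes for individual {ind!r} are not strictly increasing "
                "in time; sort (and deduplicate) before censoring")


def censor_fixes(fixes: pd.DataFrame, hdop_max: float = 10.0,
                 interval_min: float = 25.0,
                 interval_max: float = 35.0) -> pd.DataFrame:
    """Retain high-quality, high-frequency fixes.

    First drops fixes with ``hdop > hdop_max`` (the boundary value is kept),
    then keeps only fixes participating in at least one consecutive pair
    whose lag lies in ``[interval_min, interval_max]`` minutes.  Idempotent.
    Raises on unsorted input rather than silently sorting.
    """
    _check_sorted(fixes)
    good = fixes[fixes["hdop"] <= hdop_max]
    keep = []
    for _, grp in good.groupby("individual_id", sort=False):
        ts = pd.DatetimeIndex(grp["timestamp"])
        if len(ts) == 0:
            continue
        lag_min = np.diff(ts.asi8) / 60e9
        in_window = (lag_min >= interval_min) & (lag_min <= interval_max)
        mask = np.zeros(len(ts), dtype=bool)
        mask[:-1] |= in_window
        mask[1:] |= in_window
        keep.append(grp[mask])
    if not keep:
        return good.iloc[0:0]
    return pd.concat(keep).sort_index()


def step_velocity(fix_a: pd.Series, fix_b: pd.Series) -> dict:
    """Velocity record (type True) for one consecutive fix pair."""
    if fix_a["individual_id"] != fix_b["individual_id"]:
        raise ValueError("fixes belong to different individuals")
    lag_h = (pd.Timestamp(fix_b["timestamp"]) - pd.Timestamp(fix_a["timestamp"])
             ).total_seconds() / 3600.0
    if lag_h <= 0:
        raise ValueError("non-positive time lag between fixes")
    dist = float(haversine_m(fix_a["lon"], fix_a["lat"],
                             fix_b["lon"], fix_b["lat"]))
    return {
        "individual_id": fix_b["individual_id"],
        "species": fix_b.get("species"),
        "timestamp": pd.Timestamp(fix_b["timestamp"]),
        "velocity": dist / lag_h,
        "type": "True",
    }


def true_velocity(fixes: pd.DataFrame, hdop_max: float = 10.0,
                  interval_min: float = 25.0,
                  interval_max: float = 35.0) -> pd.DataFrame:
    """Censor fixes and compute the True Velocity series per individual.

    Output columns: individual_id, species, timestamp (interval end),
    velocity (m/h), type ("True").  Only pairs whose lag lies in the
    high-frequency window contribute a record.
    """
    kept = censor_fixes(fixes, hdop_max, interval_min, interval_max)
    out = []
    for _, grp in kept.groupby("individual_id", sort=False):
        ts = pd.DatetimeIndex(grp["timestamp"])
        if len(ts) < 2:
            continue
        lag_h = np.diff(ts.asi8) / 3600e9
        in_window = (lag_h * 60 >= interval_min) & (lag_h * 60 <= interval_max)
        lon = grp["lon"].to_numpy()
        lat = grp["lat"].to_numpy()
        dist = haversine_m(lon[:-1], lat[:-1], lon[1:], lat[1:])
        rec = pd.DataFrame({
            "individual_id": grp["individual_id"].iloc[0],
            "species": grp["species"].iloc[0] if "species" in grp else None,
            "timestamp": ts[1:],
            "velocity": dist / lag_h,
            "type": "True",
        })
        out.append(rec[in_window])
    if not out:
        return pd.DataFrame(columns=["individual_id", "species", "timestamp",
                                     "velocity", "type"])
    return pd.concat(out, ignore_index=True)
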