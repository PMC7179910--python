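"""Covariate attribution and discrete time-period categorization.

Maps the continuous astronomical and weather covariates onto the discrete
factors used for activity comparisons:

* ``Diel``: Day (sun > 13.5 deg above horizon), Night (> 13.5 deg below),
  Crepuscular otherwise (boundaries inclusive to Crepuscular).
* ``MoonPhase``: Full (illuminated fraction >= 0.9 and moon above horizon),
  Dark (fraction < 0.1 or moon at/below horizon), Mid otherwise.
* ``LunarDiel``: moon phase crossed with diel period for Night and
  Crepuscular only; all Day records collapse to the single level "Day",
  giving exactly 7 levels.
* ``Season``: Hot iff TMAX >= 33 C (upper bound of the ocelot thermoneutral
  zone), else Cool.

Velocity is standardized per species: v -> log(1 + v), then centred and
scaled to unit standard deviation, giving the dimensionless ``log_velocity``
response.  (Centering first would make the subsequent log undefined for
sub-mean records, so the log is applied first; the additive offset is
configurable.)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "attach_tmax",
    "standardize_velocity",
    "classify_diel",
    "classify_moon",
    "lunar_diel",
    "classify_season",
    "categorize",
    "LUNAR_DIEL_LEVELS",
]

DIEL_ANGLE = 13.5
MOON_DARK_FRAC = 0.1
MOON_FULL_FRAC = 0.9
HOT_TMAX = 33.0

LUNAR_DIEL_LEVELS = [
    "Dark Moon Night", "Mid Moon Night", "Full Moon Night",
    "Dark Moon Crepuscular", "Mid Moon Crepuscular", "Full Moon Crepuscular",
    "Day",
]


def attach_tmax(records: pd.DataFrame, weather: pd.DataFrame,
                tz_offset_hours: float = -6.0) -> pd.DataFrame:
    """Join each record to the TMAX (and TMIN, diagnostics only) of its
    local civil date.  A date missing from the weather table is an explicit
    error naming the gap."""
    out = records.copy()
    local_dates = (pd.DatetimeIndex(out["timestamp"])
                   + pd.Timedelta(hours=tz_offset_hours)).date
    out["date"] = local_dates
    merged = out.merge(weather[["date", "tmax", "tmin"]], on="date", how="left")
    missing = merged.loc[merged["tmax"].isna(), "date"].unique()
    if len(missing):
        raise ValueError(
            "weather table missing dates required by records: "
            + ", ".join(str(d) for d in sorted(missing)[:10]))
    merged = merged.rename(columns={"tmax": "TMAX", "tmin": "TMIN"})
    return merged.drop(columns=["date"])


def tmax_tmin_correlation(weather: pd.DataFrame) -> float:
    """Diagnostic Pearson correlation between daily TMAX and TMIN."""
    return float(np.corrcoef(weather["tmax"], weather["tmin"])[0, 1])


def standardize_velocity(records: pd.DataFrame, offset: float = 1.0,
                         velocity_col: str = "velocity") -> pd.DataFrame:
    """Per-species standardized log velocity.

    ``log_velocity = (log(offset + v) - mean) / sd`` with mean and sd taken
    within species, so each species' stream has mean 0 and sd 1.  A species
    with fewer than 2 records, or zero variance, is an error.
    """
    if (records[velocity_col] < 0).any():
        raise ValueError("velocities must be >= 0")
    out = records.copy()
    logv = np.log(offset + out[velocity_col].to_numpy(dtype=float))
    out["log_velocity"] = logv
    for sp, grp in out.groupby("species", sort=False):
        if len(grp) < 2:
            raise ValueError(f"species {sp!r} has fewer than 2 records")
        sd = grp["log_velocity"].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"species {sp!r} has zero log-velocity variance")
        out.loc[grp.index, "log_velocity"] = (
            (grp["log_velocity"] - grp["log_velocity"].mean()) / sd)
    return out


def classify_diel(sun_alt, angle: float = DIEL_ANGLE) -> np.ndarray | str:
    """Day / Night / Crepuscular from solar altitude (deg); the +/-13.5 deg
    boundaries belong to Crepuscular."""
    a = np.asarray(sun_alt, dtype=float)
    out = np.full(a.shape, "Crepuscular", dtype=object)
    out[a > angle] = "Day"
    out[a < -angle] = "Night"
    return out if out.ndim else str(out[()])


def classify_moon(moon_frac, moon_alt, dark_frac: float = MOON_DARK_FRAC,
                  full_frac: float = MOON_FULL_FRAC) -> np.ndarray | str:
    """Dark / Mid / Full moon phase from illuminated fraction and altitude.

    Full requires the moon strictly above the horizon; a moon at or below
    the horizon is Dark regardless of fraction (altitude exactly 0 counts
    as below — not illuminating).
    """
    f = np.asarray(moon_frac, dtype=float)
    alt = np.asarray(moon_alt, dtype=float)
    out = np.full(f.shape, "Mid", dtype=object)
    out[(f >= full_frac) & (alt > 0)] = "Full"
    out[(f < dark_frac) | (alt <= 0)] = "Dark"
    return out if out.ndim else str(out[()])


def lunar_diel(diel, moon_phase) -> np.ndarray | str:
    """Seven-level factor: moon phase crossed with Night/Crepuscular, Day
    collapsed to a single level."""
    d = np.asarray(diel, dtype=object)
    m = np.asarray(moon_phase, dtype=object)
    d_b, m_b = np.broadcast_arrays(d, m)
    out = np.where(d_b == "Day", "Day",
                   np.char.add(np.char.add(m_b.astype(str), " Moon "),
                               d_b.astype(str)))
    out = out.astype(object)
    return out if out.ndim else str(out[()])


def classify_season(tmax, hot_tmax: float = HOT_TMAX) -> np.ndarray | str:
    """Hot iff TMAX >= 33 C, else Cool."""
    t = np.asarray(tmax, dtype=float)
    out = np.where(t >= hot_tmax, "Hot", "Cool").astype(object)
    return out if out.ndim else str(out[()])


def categorize(records: pd.DataFrame, angle: float = DIEL_ANGLE,
               dark_frac: float = MOON_DARK_FRAC,
               full_frac: float = MOON_FULL_FRAC,
               hot_tmax: float = HOT_TMAX) -> pd.DataFrame:
    """Attach Diel, MoonPhase, LunarDiel and Season factor columns.

    Expects SunAlt, MoonAlt, MoonIlluminatedFrac and TMAX columns (from
    ``ephemeris.attribute_ephemeris`` and ``attach_tmax``).
    """
    out = records.copy()
    out["Diel"] = classify_diel(out["SunAlt"].to_numpy(), angle)
    out["MoonPhase"] = classify_moon(out["MoonIlluminatedFrac"].to_numpy(),
                                     out["MoonAlt"].to_numpy(),
                                     dark_frac, full_frac)
    out["LunarDiel"] = lunar_diel(out["Diel"].to_numpy(),
                                  out["MoonPhase"].to_numpy())
    out["Season"] = classify_season(out["TMAX"].to_numpy(), hot_tmax)
    return out
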