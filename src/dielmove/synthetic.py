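"""Synthetic biologging cohorts with known activity drivers.

Generates the three data streams the analysis pipeline consumes — GPS fix
tables, bi-axial 5-min accelerometer tables, and a daily TMAX/TMIN weather
table — from a latent movement-velocity process whose drivers (diel period,
lunar illumination, hot-day suppression) are known exactly.  The latent
series is retained as ground truth so every downstream stage can be tested
for recovery.

The generative model per individual, on a 5-minute grid:

    v_t = baseline * diel_mult(SunAlt_t) * lunar_mod_t * heat_mod_t * exp(x_t)

where ``diel_mult`` uses the same +/-13.5 deg twilight rule the analysis
applies, ``lunar_mod`` multiplies nocturnal velocity by
``exp(lunar_effect * frac * [moon above horizon])``, ``heat_mod`` multiplies
diurnal velocity by the profile's hot-day multiplier when TMAX >= 33 C, and
``x_t`` is a stationary AR1 process on the log scale.  Positions evolve by a
correlated random walk with step length ``v_t * dt``; accelerometer counts
are a saturating monotone map of ``v_t`` plus AR1 count noise shared between
the two axes, rounded and clipped to [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import ephemeris

__all__ = [
    "SpeciesProfile",
    "CollarSchedule",
    "WeatherParams",
    "CohortConfig",
    "SyntheticDataset",
    "OCELOT_PROFILE",
    "BOBCAT_PROFILE",
    "simulate_weather",
    "simulate_individual",
    "simulate_cohort",
    "DEFAULT_SITE",
]

# El Sauz Ranch study site, South Texas
DEFAULT_SITE = (-97.44, 26.54)

DIEL_ANGLE = 13.5
HOT_TMAX = 33.0
METRES_PER_DEG_LAT = 111_320.0


@dataclass(frozen=True)
class SpeciesProfile:
    """Latent activity drivers for one species archetype.

    Multipliers act on ``baseline_velocity`` (m/h).  ``lunar_effect`` is the
    signed coefficient of illuminated-fraction-above-horizon on log nocturnal
    velocity.  ``heat_day_suppression`` is the diurnal multiplier applied on
    days with TMAX >= 33 C (1.0 = no suppression).
    """

    name: str
    baseline_velocity: float = 150.0
    night_multiplier: float = 1.0
    crepuscular_multiplier: float = 1.0
    day_multiplier: float = 1.0
    lunar_effect: float = 0.0
    heat_day_suppression: float = 1.0
    ar1_phi: float = 0.6          # AR1 coefficient of log-velocity at 5-min steps
    log_sd: float = 0.4           # stationary sd of the log-velocity innovation
    accel_v50: float = 400.0      # velocity (m/h) at half-saturation of the count map
    accel_shared_noise_sd: float = 10.0
    accel_axis_noise_sd: float = 3.0
    turn_sd: float = 0.4          # heading innovation sd (radians) per 5-min step

    def __post_init__(self):
        for name in ("baseline_velocity", "night_multiplier",
                     "crepuscular_multiplier", "day_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.heat_day_suppression <= 1.0:
            raise ValueError("heat_day_suppression must lie in [0, 1]")


OCELOT_PROFILE = SpeciesProfile(
    "ocelot", baseline_velocity=150.0, night_multiplier=2.2,
    crepuscular_multiplier=1.4, day_multiplier=0.6,
    lunar_effect=-0.6, heat_day_suppression=0.5)

BOBCAT_PROFILE = SpeciesProfile(
    "bobcat", baseline_velocity=180.0, night_multiplier=1.3,
    crepuscular_multiplier=2.0, day_multiplier=0.7,
    lunar_effect=0.4, heat_day_suppression=0.9)


@dataclass(frozen=True)
class CollarSchedule:
    """GPS duty cycle: continuous 30-min fixes, or high-frequency windows
    centred on full/new moon instants plus daily noon/midnight anchors."""

    mode: str = "continuous"
    fix_interval: int = 30        # minutes
    window_hours: int = 24        # lunar_window mode: 24 or 72
    daily_fixes: bool = True      # noon/midnight anchors in lunar_window mode

    def __post_init__(self):
        if self.mode not in ("continuous", "lunar_window"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        if self.fix_interval <= 0:
            raise ValueError("fix_interval must be > 0")
        if self.mode == "lunar_window" and self.window_hours not in (24, 72):
            raise ValueError("window_hours must be 24 or 72")


@dataclass(frozen=True)
class WeatherParams:
    """Sinusoidal seasonal TMAX with correlated TMAX/TMIN anomalies."""

    mean_tmax: float = 31.0       # deg C, annual mean of daily maxima
    amplitude: float = 6.0        # deg C, seasonal half-range
    diurnal_range: float = 10.0   # deg C, mean TMAX - TMIN
    noise_sd: float = 2.5         # deg C, sd of daily anomalies per variable
    tmax_tmin_corr: float = 0.85  # target Pearson correlation
    peak_doy: int = 200           # day of year of the seasonal maximum


def simulate_weather(start_date, n_days: int,
                     params: WeatherParams | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Daily (date, tmax, tmin) table with TMAX >= TMIN guaranteed.

    Both series share the seasonal cycle, which already induces correlation;
    the daily anomaly is split into a shared and an independent part such
    that the *total* population Pearson correlation over the simulated span
    equals ``tmax_tmin_corr`` (when feasible: if the seasonal cycle alone
    exceeds the target, the anomalies are fully independent and the realised
    correlation is the seasonal floor).
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    p = params or WeatherParams()
    rng = np.random.default_rng(seed)
    dates = pd.date_range(pd.Timestamp(start_date), periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    seasonal = p.mean_tmax + p.amplitude * np.cos(
        2 * np.pi * (doy - p.peak_doy) / 365.25)
    rho = p.tmax_tmin_corr
    s_var = float(np.var(seasonal))          # seasonal contribution
    n_var = p.noise_sd ** 2                  # anomaly variance per series
    # corr = (s_var + shared_var) / (s_var + n_var); solve for shared_var
    shared_var = float(np.clip(rho * (s_var + n_var) - s_var, 0.0, n_var))
    shared = rng.normal(0.0, np.sqrt(shared_var), n_days)
    ind_sd = np.sqrt(n_var - shared_var)
    tmax = seasonal + shared + rng.normal(0.0, ind_sd, n_days)
    tmin = seasonal - p.diurnal_range + shared + rng.normal(0.0, ind_sd, n_days)
    tmin = np.minimum(tmin, tmax - 0.5)
    return pd.DataFrame({"date": dates.date, "tmax": tmax, "tmin": tmin})


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR1 series of length n with marginal sd ``sd``."""
    x = np.empty(n)
    if n == 0:
        return x
    innov_sd = sd * np.sqrt(max(1.0 - phi * phi, 0.0))
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def _diel_multiplier(profile: SpeciesProfile, sun_alt: np.ndarray) -> np.ndarray:
    out = np.full(sun_alt.shape, profile.crepuscular_multiplier)
    out[sun_alt > DIEL_ANGLE] = profile.day_multiplier
    out[sun_alt < -DIEL_ANGLE] = profile.night_multiplier
    return out


def latent_velocity(profile: SpeciesProfile, times: pd.DatetimeIndex,
                    site, weather: pd.DataFrame, seed: int = 0,
                    tz_offset_hours: float = -6.0) -> pd.DataFrame:
    """Latent 5-min velocity series (m/h) plus its deterministic drivers."""
    lon, lat = site
    rng = np.random.default_rng(seed)
    sun_alt = np.asarray(ephemeris.sun_altitude(times, lon, lat))
    moon_alt = np.asarray(ephemeris.moon_altitude(times, lon, lat))
    frac = np.asarray(ephemeris.moon_illuminated_fraction(times))

    local_dates = (times + pd.Timedelta(hours=tz_offset_hours)).date
    tmax_by_date = dict(zip(weather["date"], weather["tmax"]))
    missing = sorted({d for d in local_dates if d not in tmax_by_date})
    if missing:
        raise ValueError(
            f"weather table does not cover dates: {missing[:5]}"
            + ("..." if len(missing) > 5 else ""))
    tmax = np.array([tmax_by_date[d] for d in local_dates])

    mult = _diel_multiplier(profile, sun_alt)
    night = sun_alt < -DIEL_ANGLE
    day = sun_alt > DIEL_ANGLE
    mult = mult * np.where(
        night, np.exp(profile.lunar_effect * frac * (moon_alt > 0)), 1.0)
    mult = mult * np.where(day & (tmax >= HOT_TMAX),
                           profile.heat_day_suppression, 1.0)
    x = _ar1(rng, len(times), profile.ar1_phi, profile.log_sd)
    v = profile.baseline_velocity * mult * np.exp(x)
    return pd.DataFrame({
        "timestamp": times, "velocity": v, "sun_alt": sun_alt,
        "moon_alt": moon_alt, "moon_frac": frac, "tmax": tmax,
    })


def _walk_positions(rng: np.random.Generator, v: np.ndarray, site,
                    turn_sd: float, dt_hours: float):
    """Correlated random walk; returns lon/lat arrays, one per grid point."""
    lon0, lat0 = site
    n = len(v)
    heading = np.cumsum(
        np.concatenate([[rng.uniform(0, 2 * np.pi)],
                        rng.normal(0.0, turn_sd, n - 1)]))
    step = v * dt_hours  # metres per 5-min step
    dnorth = step * np.cos(heading)
    deast = step * np.sin(heading)
    lat = lat0 + np.cumsum(np.concatenate([[0.0], dnorth[:-1]])) / METRES_PER_DEG_LAT
    lon = lon0 + np.cumsum(np.concatenate([[0.0], deast[:-1]])) / (
        METRES_PER_DEG_LAT * np.cos(np.deg2rad(lat0)))
    return lon, lat


def _schedule_times(schedule: CollarSchedule, start: pd.Timestamp,
                    end: pd.Timestamp, tz_offset_hours: float) -> pd.DatetimeIndex:
    if schedule.mode == "continuous":
        return pd.date_range(start, end, freq=f"{schedule.fix_interval}min")
    times = []
    if schedule.daily_fixes:
        # noon and midnight anchors in local time
        local = pd.date_range((start + pd.Timedelta(hours=tz_offset_hours)).normalize(),
                              end + pd.Timedelta(hours=tz_offset_hours), freq="12h")
        anchors = local - pd.Timedelta(hours=tz_offset_hours)
        times.append(anchors[(anchors >= start) & (anchors <= end)])
    half = pd.Timedelta(hours=schedule.window_hours / 2)
    for kind in ("full", "new"):
        for instant in ephemeris.moon_phase_instants(start, end, kind):
            lo = max(start, instant - half)
            hi = min(end, instant + half)
            # high-frequency fixes on the collar's own interval grid
            offset = (lo - start) % pd.Timedelta(minutes=schedule.fix_interval)
            first = lo + (pd.Timedelta(minutes=schedule.fix_interval) - offset) % pd.Timedelta(
                minutes=schedule.fix_interval)
            times.append(pd.date_range(first, hi, freq=f"{schedule.fix_interval}min"))
    return pd.DatetimeIndex(np.unique(np.concatenate(
        [t.values for t in times if len(t)]))).tz_localize("UTC") if times else pd.DatetimeIndex([])


def simulate_individual(profile: SpeciesProfile, schedule: CollarSchedule,
                        site, start, n_days: int, weather: pd.DataFrame,
                        seed: int = 0, individual_id: str = "A1",
                        malfunction: bool = False,
                        accel_noise_scale: float = 1.0,
                        gps_jitter_m: float = 15.0,
                        tz_offset_hours: float = -6.0):
    """Simulate one collared animal.

    Returns ``(truth, gps, accel)``: the latent 5-min velocity series with
    its drivers, the GPS fix table (id, timestamp, lon, lat, hdop) under the
    collar schedule with positional jitter and right-skewed HDOP, and the
    5-min accelerometer table (id, timestamp, activity_x, activity_y).
    """
    if n_days < 2:
        raise ValueError("period must span at least 2 days")
    start = pd.Timestamp(start)
    start = start.tz_localize("UTC") if start.tzinfo is None else start
    end = start + pd.Timedelta(days=n_days)
    times = pd.date_range(start, end, freq="5min", inclusive="left")

    ss = np.random.SeedSequence([seed, 0xD1E1])
    r_vel, r_walk, r_gps, r_acc = [np.random.default_rng(s) for s in ss.spawn(4)]

    truth = latent_velocity(profile, times, site, weather, seed=r_vel.integers(2**31),
                            tz_offset_hours=tz_offset_hours)
    v = truth["velocity"].to_numpy()
    path_lon, path_lat = _walk_positions(r_walk, v, site, profile.turn_sd, 5.0 / 60.0)

    # --- GPS stream ---
    fix_times = _schedule_times(schedule, start, end - pd.Timedelta(minutes=5),
                                tz_offset_hours)
    tsec = times.asi8.astype(float) / 1e9
    fsec = fix_times.asi8.astype(float) / 1e9
    flon = np.interp(fsec, tsec, path_lon)
    flat = np.interp(fsec, tsec, path_lat)
    jitter_deg_lat = r_gps.normal(0.0, gps_jitter_m, len(fix_times)) / METRES_PER_DEG_LAT
    jitter_deg_lon = r_gps.normal(0.0, gps_jitter_m, len(fix_times)) / (
        METRES_PER_DEG_LAT * np.cos(np.deg2rad(site[1])))
    hdop = 1.0 + r_gps.gamma(2.0, 1.9, len(fix_times))
    gps = pd.DataFrame({
        "individual_id": individual_id, "species": profile.name,
        "timestamp": fix_times, "lon": flon + jitter_deg_lon,
        "lat": flat + jitter_deg_lat, "hdop": hdop,
    })

    # --- accelerometer stream ---
    if malfunction:
        signal = np.full(len(times), 30.0)  # decoupled from velocity
    else:
        signal = 255.0 * v / (v + profile.accel_v50)
    shared = _ar1(r_acc, len(times), profile.ar1_phi,
                  profile.accel_shared_noise_sd * accel_noise_scale)
    ax = _ar1(r_acc, len(times), profile.ar1_phi,
              profile.accel_axis_noise_sd * accel_noise_scale)
    ay = _ar1(r_acc, len(times), profile.ar1_phi,
              profile.accel_axis_noise_sd * accel_noise_scale)
    accel = pd.DataFrame({
        "individual_id": individual_id, "species": profile.name,
        "timestamp": times,
        "activity_x": np.clip(np.round(signal + shared + ax), 0, 255).astype(int),
        "activity_y": np.clip(np.round(0.95 * signal + shared + ay), 0, 255).astype(int),
    })
    truth.insert(0, "individual_id", individual_id)
    truth.insert(1, "species", profile.name)
    return truth, gps, accel


@dataclass(frozen=True)
class IndividualSpec:
    individual_id: str
    profile: SpeciesProfile
    schedule: CollarSchedule = CollarSchedule()
    malfunction: bool = False
    has_accelerometer: bool = True


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the field deployment the pipeline is designed for:
    8 ocelot-like and 6 bobcat-like individuals at a single South Texas
    site, a mix of continuous and lunar-window collar schedules.
    """

    individuals: list[IndividualSpec] = field(default_factory=list)
    site: tuple[float, float] = DEFAULT_SITE
    start: str = "2016-03-01"
    n_days: int = 60
    weather: WeatherParams = field(default_factory=WeatherParams)
    tz_offset_hours: float = -6.0
    accel_noise_scale: float = 1.0

    def __post_init__(self):
        if not self.individuals:
            self.individuals = default_cohort_individuals()


def default_cohort_individuals() -> list[IndividualSpec]:
    cont = CollarSchedule("continuous")
    lw24 = CollarSchedule("lunar_window", window_hours=24)
    lw72 = CollarSchedule("lunar_window", window_hours=72)
    specs = []
    for i in range(8):
        sched = cont if i < 3 else lw24
        specs.append(IndividualSpec(f"O{i + 1}", OCELOT_PROFILE, sched))
    for i in range(6):
        sched = cont if i < 2 else (lw72 if i == 5 else lw24)
        specs.append(IndividualSpec(f"B{i + 1}", BOBCAT_PROFILE, sched))
    return specs


@dataclass
class SyntheticDataset:
    gps: pd.DataFrame
    accel: pd.DataFrame
    weather: pd.DataFrame
    truth: pd.DataFrame
    config: CohortConfig

    def write_csv(self, outdir) -> dict[str, Path]:
        """Write gps.csv, accel.csv, weather.csv and truth.csv (ISO-8601 UTC)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [("gps", self.gps), ("accel", self.accel),
                         ("weather", self.weather), ("truth", self.truth)]:
            p = outdir / f"{name}.csv"
            out = df.copy()
            if "timestamp" in out:
                out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime(
                    "%Y-%m-%dT%H:%M:%SZ")
            out.to_csv(p, index=False)
            paths[name] = p
        return paths


def simulate_cohort(config: CohortConfig | None = None,
                    seed: int = 0) -> SyntheticDataset:
    """Simulate a full cohort; reproducible for a fixed seed."""
    config = config or CohortConfig()
    ids = [s.individual_id for s in config.individuals]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual ids in cohort config")
    # pad one day either side so the local-civil-date join always resolves
    weather_start = pd.Timestamp(config.start) - pd.Timedelta(days=1)
    weather = simulate_weather(weather_start, config.n_days + 3,
                               config.weather, seed=seed)
    truths, gpss, accels = [], [], []
    ss = np.random.SeedSequence([seed, 0xC0807])
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(ids))]
    for spec, child in zip(config.individuals, child_seeds):
        truth, gps, accel = simulate_individual(
            spec.profile, spec.schedule, config.site, config.start,
            config.n_days, weather, seed=child,
            individual_id=spec.individual_id, malfunction=spec.malfunction,
            accel_noise_scale=config.accel_noise_scale,
            tz_offset_hours=config.tz_offset_hours)
        truths.append(truth)
        gpss.append(gps)
        if spec.has_accelerometer:
            accels.append(accel)
    return SyntheticDataset(
        gps=pd.concat(gpss, ignore_index=True),
        accel=(pd.concat(accels, ignore_index=True) if accels
               else pd.DataFrame(columns=["individual_id", "species",
                                          "timestamp", "activity_x", "activity_y"])),
        weather=weather,
        truth=pd.concat(truths, ignore_index=True),
        config=config)
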