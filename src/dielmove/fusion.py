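"""Accelerometer-to-velocity prediction and True/Predicted stream fusion.

The 30-min trailing window over the 5-min bi-axial activity stream yields 8
summary features (min/max/mean/variance per axis).  A random-forest
regression (1,000 trees, floor(p/3)=2 variables per split) trained on
GPS-derived True Velocity predicts velocity at every accelerometer timestamp
("Predicted Velocity").  The fused "Velocity Combined" series prefers True
Velocity wherever a GPS-derived record exists.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestRegressor
from statsmodels.stats.diagnostic import het_breuschpagan

log = logging.getLogger(__name__)

__all__ = [
    "FEATURE_COLUMNS",
    "window_features",
    "build_training_table",
    "VelocityModel",
    "fit_velocity_model",
    "predict_velocity",
    "validate_prediction",
    "interaction_check",
    "detect_accel_malfunction",
    "combine_velocity",
]

FEATURE_COLUMNS = ["min_x", "max_x", "mean_x", "var_x",
                   "min_y", "max_y", "mean_y", "var_y"]

WINDOW_MINUTES = 30
CADENCE_MINUTES = 5
READINGS_PER_WINDOW = WINDOW_MINUTES // CADENCE_MINUTES  # 6


def window_features(accel: pd.DataFrame,
                    interval_end: pd.Timestamp | None = None) -> pd.DataFrame:
    """Summary features of the 6 readings in the trailing half-open window.

    For each candidate window end ``t`` the readings with timestamps in
    ``(t - 30 min, t]`` are summarised per axis (min, max, mean, sample
    variance with n-1).  Window ends with fewer than 6 readings are missing
    — dropped from the output, not an error.  With ``interval_end`` given,
    only that single window is evaluated (empty frame if incomplete).

    Input must be a single individual's stream, sorted, on the 5-min grid.
    """
    ts = pd.DatetimeIndex(accel["timestamp"])
    if len(ts) > 1 and not (ts[1:] > ts[:-1]).all():
        raise ValueError("accelerometer stream must be sorted in time")
    if len(ts) == 0:
        return pd.DataFrame(columns=["timestamp", *FEATURE_COLUMNS])
    grid = pd.date_range(ts.min(), ts.max(), freq=f"{CADENCE_MINUTES}min")
    s = accel.set_index("timestamp").reindex(grid)
    feats = {}
    for axis in ("x", "y"):
        col = s[f"activity_{axis}"]
        r = col.rolling(READINGS_PER_WINDOW, min_periods=READINGS_PER_WINDOW)
        feats[f"min_{axis}"] = r.min()
        feats[f"max_{axis}"] = r.max()
        feats[f"mean_{axis}"] = r.mean()
        feats[f"var_{axis}"] = r.var(ddof=1)
    out = pd.DataFrame(feats, index=grid).dropna()
    out.index.name = "timestamp"
    out = out.reset_index()
    if interval_end is not None:
        out = out[out["timestamp"] == pd.Timestamp(interval_end)]
    return out


def _per_individual_features(accel: pd.DataFrame) -> pd.DataFrame:
    parts = []
    for ind, grp in accel.groupby("individual_id", sort=False):
        f = window_features(grp)
        f.insert(0, "individual_id", ind)
        if "species" in grp:
            f.insert(1, "species", grp["species"].iloc[0])
        parts.append(f)
    if not parts:
        return pd.DataFrame(columns=["individual_id", "timestamp", *FEATURE_COLUMNS])
    return pd.concat(parts, ignore_index=True)


def build_training_table(true_velocities: pd.DataFrame,
                         accel: pd.DataFrame) -> pd.DataFrame:
    """One row per True Velocity record with a complete feature window.

    Joins on (individual_id, timestamp).  Duplicate velocity records are
    deduplicated by key; records lacking a complete window are dropped and
    counted in the log.  An empty join is an explicit error.
    """
    if len(true_velocities) == 0 or len(accel) == 0:
        raise ValueError("empty training join: no velocity records or no "
                         "accelerometer data")
    vel = true_velocities.drop_duplicates(["individual_id", "timestamp"])
    feats = _per_individual_features(accel)
    table = vel.merge(feats.drop(columns=["species"], errors="ignore"),
                      on=["individual_id", "timestamp"], how="inner")
    dropped = len(vel) - len(table)
    if len(table) == 0:
        raise ValueError(
            "empty training join: no temporal overlap between True Velocity "
            "records and complete accelerometer windows")
    log.info("training table: %d rows (%d velocity records without a "
             "complete window dropped)", len(table), dropped)
    return table


@dataclass
class VelocityModel:
    """Fitted tree ensemble with its training-target range and fit report."""

    forest: RandomForestRegressor
    target_min: float
    target_max: float
    n_training_rows: int
    oob_r2: float | None
    oob_rmse: float | None
    resub_r2: float
    resub_rmse: float
    seed: int


def fit_velocity_model(table: pd.DataFrame, n_trees: int = 1000,
                       vars_per_split: int | None = None,
                       seed: int = 0, min_rows: int = 50) -> VelocityModel:
    """Random-forest regression of velocity on the 8 window features.

    ``vars_per_split`` defaults to floor(p/3) = 2 for the 8 features.  The
    report carries both out-of-bag and resubstitution (training-set) R2 and
    RMSE.  A constant target triggers a degenerate-fit warning; the model is
    still returned and predicts the constant.
    """
    if len(table) < min_rows:
        raise ValueError(f"need >= {min_rows} training rows, got {len(table)}")
    X = table[FEATURE_COLUMNS].to_numpy()
    y = table["velocity"].to_numpy()
    if vars_per_split is None:
        vars_per_split = max(1, len(FEATURE_COLUMNS) // 3)
    degenerate = np.ptp(y) == 0
    if degenerate:
        warnings.warn("constant velocity target: degenerate fit", stacklevel=2)
    forest = RandomForestRegressor(
        n_estimators=n_trees, max_features=vars_per_split,
        oob_score=not degenerate, random_state=seed, n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # oob warning on tiny samples
        forest.fit(X, y)
    pred = forest.predict(X)
    resid = y - pred
    resub_rmse = float(np.sqrt(np.mean(resid ** 2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    resub_r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    oob_r2 = oob_rmse = None
    if not degenerate and hasattr(forest, "oob_prediction_"):
        oob = forest.oob_prediction_
        oob_r2 = float(forest.oob_score_)
        oob_rmse = float(np.sqrt(np.mean((y - oob) ** 2)))
    return VelocityModel(forest, float(y.min()), float(y.max()), len(table),
                         oob_r2, oob_rmse, resub_r2, resub_rmse, seed)


def predict_velocity(model: VelocityModel, accel: pd.DataFrame) -> pd.DataFrame:
    """Predicted Velocity at every accelerometer timestamp with a complete
    trailing window.  Predictions are clipped to the training-target range
    (the ensemble mean already lies within it)."""
    feats = _per_individual_features(accel)
    if len(feats) == 0:
        return pd.DataFrame(columns=["individual_id", "species", "timestamp",
                                     "velocity", "type"])
    pred = model.forest.predict(feats[FEATURE_COLUMNS].to_numpy())
    pred = np.clip(pred, model.target_min, model.target_max)
    out = feats[["individual_id", "timestamp"]].copy()
    if "species" in feats:
        out.insert(1, "species", feats["species"])
    out["velocity"] = pred
    out["type"] = "Predicted"
    return out


def validate_prediction(true_vel: pd.DataFrame,
                        predicted_vel: pd.DataFrame) -> dict:
    """OLS of predicted on true velocity plus the studentized Breusch-Pagan
    heteroscedasticity test (auxiliary regressor: the fitted values)."""
    pairs = true_vel.merge(predicted_vel, on=["individual_id", "timestamp"],
                           suffixes=("_true", "_pred"))
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 paired records, got {len(pairs)}")
    x = pairs["velocity_true"].to_numpy()
    y = pairs["velocity_pred"].to_numpy()
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    bp_stat, bp_p, _, _ = het_breuschpagan(
        fit.resid, sm.add_constant(fit.fittedvalues))
    return {
        "n": len(pairs),
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "r2": float(fit.rsquared),
        "bp_stat": float(bp_stat),
        "bp_df": 1,
        "bp_p": float(bp_p),
    }


def interaction_check(pairs: pd.DataFrame, covariate: str) -> float:
    """Added variance (percent) from a covariate main effect + interaction.

    Compares R2 of ``predicted ~ true`` against
    ``predicted ~ true * covariate``; returns 100 * (R2_full - R2_base).
    Categorical covariates are dummy-coded.  A constant covariate adds
    nothing and triggers a warning.
    """
    x = pairs["velocity_true"].to_numpy(dtype=float)
    y = pairs["velocity_pred"].to_numpy(dtype=float)
    cov = pairs[covariate]
    if cov.nunique() <= 1:
        warnings.warn(f"covariate {covariate!r} is constant; added R2 is 0",
                      stacklevel=2)
        return 0.0
    base = sm.OLS(y, sm.add_constant(x)).fit()
    if cov.dtype == object or isinstance(cov.dtype, pd.CategoricalDtype):
        dummies = pd.get_dummies(cov, drop_first=True).to_numpy(dtype=float)
    else:
        dummies = cov.to_numpy(dtype=float)[:, None]
    cols = [x[:, None], dummies, x[:, None] * dummies]
    full = sm.OLS(y, sm.add_constant(np.hstack(cols))).fit()
    return 100.0 * float(full.rsquared - base.rsquared)


def detect_accel_malfunction(training_table: pd.DataFrame,
                             vel_hi_quantile: float = 0.9,
                             act_lo_quantile: float = 0.1,
                             min_events: int = 3) -> dict[str, bool | None]:
    """Flag individuals whose activity counts decouple from velocity.

    An individual is flagged when at least ``min_events`` paired intervals
    show velocity above the cohort's ``vel_hi_quantile`` while mean combined
    activity sits below the cohort's ``act_lo_quantile``.  Individuals with
    no paired data map to None (unassessable).
    """
    act = (training_table["mean_x"] + training_table["mean_y"]) / 2.0
    v_hi = training_table["velocity"].quantile(vel_hi_quantile)
    a_lo = act.quantile(act_lo_quantile)
    suspect = (training_table["velocity"] > v_hi) & (act < a_lo)
    counts = suspect.groupby(training_table["individual_id"]).sum()
    flags: dict[str, bool | None] = {
        str(ind): bool(c >= min_events) for ind, c in counts.items()}
    for ind, flagged in flags.items():
        if flagged:
            log.warning("individual %s flagged for accelerometer malfunction "
                        "(%d high-velocity/low-activity intervals)",
                        ind, int(counts[ind]))
    return flags


def combine_velocity(true_series: pd.DataFrame,
                     predicted_series: pd.DataFrame) -> pd.DataFrame:
    """Velocity Combined: True Velocity where available, Predicted elsewhere.

    Keys are (individual_id, timestamp); duplicate keys *within* one series
    are an error.  GPS-only individuals pass through as their True series.
    """
    for name, s in (("true", true_series), ("predicted", predicted_series)):
        if len(s) and s.duplicated(["individual_id", "timestamp"]).any():
            raise ValueError(f"duplicate (individual, timestamp) keys in "
                             f"{name} series")
    if len(predicted_series) == 0:
        return true_series.copy()
    claimed = predicted_series.merge(
        true_series[["individual_id", "timestamp"]], how="left",
        on=["individual_id", "timestamp"], indicator=True)["_merge"]
    keep = (claimed == "left_only").to_numpy()
    out = pd.concat([true_series, predicted_series[keep]], ignore_index=True)
    return out.sort_values(["individual_id", "timestamp"]).reset_index(drop=True)
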