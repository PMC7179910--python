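"""End-to-end orchestration: data -> velocities -> covariates -> inference.

``run_pipeline`` drives the full analysis from a single config, logging the
record count at every censoring step into a JSON-serialisable manifest, and
writes the tabular products (velocity_combined.csv, analysis_table.csv,
model_comparison.csv, coefficients.csv, emmeans.csv, contrasts_*.csv,
sun_angle_profile.csv).  Identical seed + config gives identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covariates, ephemeris, fusion, inference, synthetic, trajectory

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "sun_angle_profile"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on.

    In synthetic mode (``input_dir`` None) a cohort is simulated from
    ``cohort``; otherwise gps.csv / accel.csv / weather.csv are read from
    ``input_dir``.
    """

    outdir: str = "dielmove_out"
    seed: int = 0
    input_dir: str | None = None
    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    site: tuple[float, float] = synthetic.DEFAULT_SITE
    tz_offset_hours: float = -6.0
    hdop_max: float = 10.0
    diel_angle: float = 13.5
    moon_dark_frac: float = 0.1
    moon_full_frac: float = 0.9
    hot_tmax: float = 33.0
    n_trees: int = 1000
    run_candidates: bool = True
    thin_predicted: int = 1   # keep every k-th Predicted record (1 = all)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", None)
        cfg = cls(**raw)
        if cohort_raw:
            inds = cohort_raw.pop("individuals", None)
            cohort = synthetic.CohortConfig(
                individuals=[], **{k: v for k, v in cohort_raw.items()
                                   if k != "weather"})
            if "weather" in cohort_raw:
                cohort.weather = synthetic.WeatherParams(**cohort_raw["weather"])
            if inds:
                profiles = {"ocelot": synthetic.OCELOT_PROFILE,
                            "bobcat": synthetic.BOBCAT_PROFILE}
                cohort.individuals = [
                    synthetic.IndividualSpec(
                        d["individual_id"], profiles[d["profile"]],
                        synthetic.CollarSchedule(**d.get("schedule", {})),
                        malfunction=d.get("malfunction", False),
                        has_accelerometer=d.get("has_accelerometer", True))
                    for d in inds]
            cfg.cohort = cohort
        if isinstance(cfg.site, list):
            cfg.site = tuple(cfg.site)
        return cfg


def _load_inputs(config: PipelineConfig):
    d = Path(config.input_dir)
    gps = pd.read_csv(d / "gps.csv", parse_dates=["timestamp"])
    accel_path = d / "accel.csv"
    accel = (pd.read_csv(accel_path, parse_dates=["timestamp"])
             if accel_path.exists() else pd.DataFrame(
                 columns=["individual_id", "species", "timestamp",
                          "activity_x", "activity_y"]))
    weather = pd.read_csv(d / "weather.csv")
    weather["date"] = pd.to_datetime(weather["date"]).dt.date
    return gps, accel, weather


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the run manifest.

    A stage failure is recorded in the manifest (stage name and cause) and
    the partial outputs already written are retained; the manifest's
    ``status`` is then "failed".
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "status": "ok", "stages": {}}

    def stage(name):
        manifest["stages"][name] = {"status": "ok"}
        return manifest["stages"][name]

    try:
        # --- ingest / simulate -------------------------------------------
        st = stage("data")
        if config.input_dir is None:
            ds = synthetic.simulate_cohort(config.cohort, seed=config.seed)
            ds.write_csv(outdir / "data")
            gps, accel, weather = ds.gps, ds.accel, ds.weather
        else:
            gps, accel, weather = _load_inputs(config)
        st.update(n_gps_fixes=int(len(gps)), n_accel_readings=int(len(accel)),
                  n_weather_days=int(len(weather)),
                  n_individuals=int(gps["individual_id"].nunique()))

        # --- trajectory ---------------------------------------------------
        st = stage("trajectory")
        true_vel = trajectory.true_velocity(gps, hdop_max=config.hdop_max)
        kept = trajectory.censor_fixes(gps, hdop_max=config.hdop_max)
        st.update(n_fixes_in=int(len(gps)), n_fixes_retained=int(len(kept)),
                  n_true_velocity=int(len(true_vel)))

        # --- fusion ---------------------------------------------------------
        st = stage("fusion")
        validation = None
        if len(accel) and len(true_vel):
            table = fusion.build_training_table(true_vel, accel)
            flags = fusion.detect_accel_malfunction(table)
            bad = [k for k, v in flags.items() if v]
            train = table[~table["individual_id"].isin(bad)]
            model = fusion.fit_velocity_model(train, n_trees=config.n_trees,
                                              seed=config.seed)
            pred = fusion.predict_velocity(
                model, accel[~accel["individual_id"].isin(bad)])
            validation = fusion.validate_prediction(true_vel, pred)
            if config.thin_predicted > 1:
                pred = pred.iloc[::config.thin_predicted]
            combined = fusion.combine_velocity(true_vel, pred)
            st.update(n_training_rows=int(len(train)),
                      n_malfunction_censored=len(bad),
                      malfunction_ids=bad,
                      n_predicted=int(len(pred)),
                      oob_r2=model.oob_r2, oob_rmse=model.oob_rmse,
                      resub_r2=model.resub_r2, resub_rmse=model.resub_rmse,
                      validation=validation)
        else:
            combined = true_vel.copy()
            st.update(n_training_rows=0, n_predicted=0,
                      note="no accelerometer data; Predicted stream empty")
        if len(true_vel) == 0:
            log.warning("no True Velocity records (all fixes censored); "
                        "pipeline degrades to the Predicted stream only")
            manifest["warning"] = ("no True Velocity records after censoring;"
                                   " Predicted-only degradation")
        st["n_velocity_combined"] = int(len(combined))
        if len(combined) == 0:
            # nothing to analyse: skip inference stages, keep partials
            log.warning("no velocity records at all; inference stages skipped")
            manifest["warning"] = ("no velocity records after censoring; "
                                   "inference stages skipped")
            for name in ("covariates", "candidate_models", "final_model"):
                manifest["stages"][name] = {"status": "skipped"}
            (outdir / "manifest.json").write_text(
                json.dumps(_jsonable(manifest), indent=2, sort_keys=True))
            return manifest

        # --- covariates -----------------------------------------------------
        st = stage("covariates")
        lon, lat = config.site
        rec = ephemeris.attribute_ephemeris(combined, lon, lat)
        rec = covariates.attach_tmax(rec, weather, config.tz_offset_hours)
        rec = covariates.standardize_velocity(rec)
        rec = covariates.categorize(
            rec, angle=config.diel_angle, dark_frac=config.moon_dark_frac,
            full_frac=config.moon_full_frac, hot_tmax=config.hot_tmax)
        rec = rec.rename(columns={"species": "Species"})
        st.update(n_records=int(len(rec)),
                  tmax_tmin_corr=covariates.tmax_tmin_correlation(weather),
                  lunar_diel_counts={k: int(v) for k, v in
                                     rec["LunarDiel"].value_counts().items()})
        analysis = rec
        analysis.to_csv(outdir / "analysis_table.csv", index=False)
        combined.to_csv(outdir / "velocity_combined.csv", index=False)

        # --- sun-angle profile -----------------------------------------------
        profile = sun_angle_profile(analysis.rename(columns={"Species": "species"}))
        profile.to_csv(outdir / "sun_angle_profile.csv", index=False)

        # --- candidate models -------------------------------------------------
        if config.run_candidates:
            st = stage("candidate_models")
            tables = []
            for sp, grp in analysis.groupby("Species", sort=False):
                fits = [inference.fit_lme(s, grp)
                        for s in inference.build_candidate_models()]
                tab = inference.rank_aic(fits)
                tab.insert(0, "species", sp)
                tables.append(tab)
            comparison = pd.concat(tables, ignore_index=True)
            comparison.to_csv(outdir / "model_comparison.csv", index=False)
            st.update(n_models=int(len(comparison)),
                      best={sp: t.iloc[0]["model"]
                            for sp, t in comparison.groupby("species")})

        # --- final model and contrasts ----------------------------------------
        st = stage("final_model")
        final = inference.fit_final_model(analysis)
        coef = pd.DataFrame({
            "term": final.params.index, "value": final.params.to_numpy(),
            "std_error": final.bse.to_numpy(), "t_value": final.tvalues.to_numpy(),
            "p_value": final.pvalues.to_numpy()})
        coef.to_csv(outdir / "coefficients.csv", index=False)
        emm = inference.estimate_marginal_means(
            final, ["LunarDiel", "Season", "Species"])
        emm.grid.to_csv(outdir / "emmeans.csv", index=False)
        within = inference.pairwise_contrasts(emm, group_by=["Species"])
        within.to_csv(outdir / "contrasts_within_species.csv", index=False)
        between = inference.pairwise_contrasts(
            emm, group_by=["LunarDiel", "Season"])
        between.to_csv(outdir / "contrasts_between_species.csv", index=False)
        st.update(loglik=final.loglik, aic=final.aic, phi=final.phi,
                  re_variances=final.re_variances,
                  n_emmeans=int(len(emm.grid)),
                  n_contrasts_within=int(len(within)),
                  n_contrasts_between=int(len(between)))
    except Exception as exc:  # record the failing stage, keep partials
        failed = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        manifest["status"] = "failed"
        manifest["stages"].setdefault(failed, {})["status"] = "failed"
        manifest["failed_stage"] = failed
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        log.exception("pipeline failed at stage %s", failed)

    (outdir / "manifest.json").write_text(json.dumps(_jsonable(manifest),
                                                     indent=2, sort_keys=True))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def sun_angle_profile(records: pd.DataFrame, bin_width: float = 10.0,
                      velocity_col: str = "velocity") -> pd.DataFrame:
    """Mean velocity and SEM per 10-degree sun-angle bin, by species and
    record type.  Bins are half-open [lo, hi) spanning [-90, 90); empty bins
    are reported with count 0 and missing mean."""
    if "SunAlt" not in records:
        raise ValueError("records must carry a SunAlt column")
    edges = np.arange(-90.0, 90.0 + bin_width, bin_width)
    rows = []
    for (sp, typ), grp in records.groupby(["species", "type"], sort=False):
        idx = np.digitize(grp["SunAlt"].to_numpy(), edges) - 1
        v = grp[velocity_col].to_numpy()
        for b in range(len(edges) - 1):
            sel = v[idx == b]
            rows.append({
                "species": sp, "type": typ,
                "bin_lo": edges[b], "bin_hi": edges[b + 1], "n": len(sel),
                "mean_velocity": float(sel.mean()) if len(sel) else np.nan,
                "sem": (float(sel.std(ddof=1) / np.sqrt(len(sel)))
                        if len(sel) > 1 else np.nan),
            })
    return pd.DataFrame(rows)
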