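# dielmove

Temporal activity analysis of sympatric felids from fused GPS +
accelerometer biologging data.

## The problem

Ecologically similar carnivores such as ocelots (*Leopardus pardalis*) and
bobcats (*Lynx rufus*) overlap in body size, diet and habitat; one route to
coexistence is **temporal niche partitioning** — concentrating activity in
different parts of the diel cycle. Testing that hypothesis from collar data
requires a nearly continuous measure of movement rate, but high-frequency
GPS schedules drain collar batteries. `dielmove` implements the standard
remedy: fuse sparse high-frequency GPS fixes with continuous bi-axial
accelerometer counts.

The pipeline:

1. **Trajectory** — censor fixes (HDOP > 10 removed, only ~30-min lags
   kept) and compute *True Velocity*: haversine step distance (m) divided by
   the time lag (h).
2. **Fusion** — summarise each trailing 30-min accelerometer window
   (min/max/mean/variance of the six 5-min ActivityX and ActivityY
   readings, 8 features), fit a random-forest regression of True Velocity
   on these features (1,000 trees, ⌊p/3⌋ = 2 variables per split), predict
   velocity at every accelerometer timestamp (*Predicted Velocity*), and
   merge the streams into *Velocity Combined* (True wins wherever both
   exist). Validation reports the OLS slope/R² of predicted on true
   velocity, a studentized Breusch–Pagan heteroscedasticity test, and the
   added variance from Species/SunAlt/moon/TMAX interaction terms.
   Individuals whose counts decouple from velocity (accelerometer
   malfunction) are flagged and censored from training.
3. **Covariates** — attach solar altitude, lunar altitude and illuminated
   fraction from the built-in ephemeris, join daily TMAX by local civil
   date, standardize velocity per species (log(1+v), then centre/scale),
   and categorize: Diel (Day / Night / Crepuscular at ±13.5°), MoonPhase
   (Dark / Mid / Full at 0.1 / 0.9 illuminated fraction with the moon above
   the horizon), the 7-level LunarDiel merge, and Season (Hot iff
   TMAX ≥ 33 °C, the upper bound of the ocelot thermoneutral zone).
4. **Inference** — linear mixed-effects models of standardized log
   velocity with random intercepts for individual and record provenance
   (Type: True vs Predicted) and AR1 residual correlation by observation
   order within individual, fitted by maximum likelihood. Nine candidate
   fixed structures over {SunAlt, MoonIlluminatedFrac, TMAX} are ranked by
   AIC per species; the final interactive LunarDiel × Season × Species
   model feeds estimated marginal means with 95% CIs and Tukey-adjusted
   pairwise contrasts (within-species across time periods, and
   between-species within a time period).

The model for the response y (standardized log velocity) is

    y = Xβ + Z_id·b_id + Z_type·b_type + ε,
    b_id ~ N(0, σ²_id), b_type ~ N(0, σ²_type),
    corr(ε_t, ε_{t+k}) = φ^k within an individual.

The marginal likelihood is evaluated exactly in O(n) per iteration using
the tridiagonal AR1 inverse plus a Woodbury identity, with β and the
residual variance profiled out; tests verify it against a dense
multivariate-normal oracle to 1e-8.

Because no field dataset ships with the package, a first-class
**synthetic-cohort generator** produces all three input streams (GPS,
accelerometer, GHCN-style daily weather) from a latent velocity process
with known diel, lunar and thermal drivers, and retains the ground truth so
every stage can be tested for recovery.

## Worked example

```python
from dielmove import synthetic as syn, pipeline as pl

inds = [
    syn.IndividualSpec("O1", syn.OCELOT_PROFILE, syn.CollarSchedule("continuous")),
    syn.IndividualSpec("O2", syn.OCELOT_PROFILE, syn.CollarSchedule("lunar_window", window_hours=24)),
    syn.IndividualSpec("B1", syn.BOBCAT_PROFILE, syn.CollarSchedule("continuous")),
    syn.IndividualSpec("B2", syn.BOBCAT_PROFILE, syn.CollarSchedule("lunar_window", window_hours=72)),
]
cfg = pl.PipelineConfig(
    outdir="demo_out", seed=1, thin_predicted=6,
    cohort=syn.CohortConfig(individuals=inds, start="2016-05-01", n_days=35))
manifest = pl.run_pipeline(cfg)
```

On this 4-animal, 35-day cohort the run prints (seed 1):

```
True Velocity records : 3370
validation slope/R2   : 0.926 / 0.9737
out-of-bag R2 / RMSE  : 0.7885 / 58.38
BP statistic (df=1)   : 263.34, p = 3.21e-59
final model AR1 phi   : 0.302

emmeans (ocelot, Cool season):
            LunarDiel  emmean    SE  lower  upper
Dark Moon Crepuscular   0.525 0.064  0.401  0.650
      Dark Moon Night   1.080 0.052  0.978  1.182
                  Day  -0.502 0.041 -0.583 -0.421
Full Moon Crepuscular   0.219 0.148 -0.072  0.510
      Full Moon Night   0.393 0.093  0.211  0.576
 Mid Moon Crepuscular   0.475 0.085  0.310  0.641
       Mid Moon Night   0.576 0.065  0.449  0.702
```

Reading the output: the regression of predicted on true velocity is close
to the identity (slope 0.93, R² 0.97) with significant heteroscedasticity
(variance grows with velocity — expected for accelerometer-based
predictions), and the out-of-bag R² of 0.79 is the honest generalisation
estimate. The marginal means recover the generated ocelot pattern:
strongly nocturnal (Night > Crepuscular > Day on the standardized log
scale), with dark-moon nights (1.08) well above full-moon nights (0.39) —
the negative lunar-illumination effect built into the ocelot archetype.
Tukey-adjusted contrasts are written to `contrasts_within_species.csv` and
`contrasts_between_species.csv`; e.g. ocelot "Dark Moon Night Cool − Day
Cool" = 1.58 (SE 0.05, t = 30.5, p < 0.001).

The same run is available from the shell:

```bash
dielmove run --seed 1 --outdir demo_out
dielmove report --indir demo_out     # sun-angle profile + emmeans figures
dielmove simulate --seed 1 --days 35 --outdir demo_data   # raw streams only
```

## Layout

```
src/dielmove/
  synthetic.py    # cohort generator with ground-truth ledger
  ephemeris.py    # sun/moon altitude, illuminated fraction, phase instants
  trajectory.py   # fix censoring, haversine step velocities
  fusion.py       # feature windows, random forest, validation, stream merge
  covariates.py   # TMAX join, standardization, discrete time periods
  inference.py    # AR1 mixed models, AIC ranking, emmeans, Tukey contrasts
  evaluation.py   # synthetic-cohort recovery/fidelity studies
  pipeline.py     # orchestration, manifest, sun-angle profile
  cli.py          # dielmove simulate | run | report
docs/methods.md   # model and design notes
```
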