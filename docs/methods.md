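# Methods notes

This note documents the models, the synthetic data-generating process, the
numerical choices, and the known limitations of `dielmove`.

## Ephemeris

Solar position uses the NOAA/Meeus low-precision algorithm (mean longitude,
equation of centre, apparent longitude with nutation-in-longitude
correction, obliquity, equatorial transform, hour angle from GMST).
Altitudes are geometric: no atmospheric refraction. The diel thresholds the
analysis uses (±13.5°) sit far from the ~0.5° refraction scale; the one
boundary where refraction-scale effects could matter, MoonAlt = 0, is
tie-broken deterministically in the covariates module (a moon exactly at
the horizon is treated as not illuminating, i.e. Dark).

Lunar ecliptic position uses a truncated Meeus periodic series (32
longitude/distance terms, 20 latitude terms, plus the additive A1/A2/A3
arguments and eccentricity damping of the solar-anomaly terms), then the
standard equatorial transform. The altitude receives a single first-order
topocentric parallax correction, `alt_topo = alt_geo − π·cos(alt_geo)` with
`π = asin(6378.14 km / Δ)` from the series distance Δ. Higher-order
topocentric effects (observer ellipsoidal position, parallax in azimuth)
are deliberately out of scope; the documented accuracy target for MoonAlt
is 1°, and the cross-implementation tests (against an independent
Astronomical Almanac low-precision implementation that lives only in the
test suite) observe ≈0.35° maximum disagreement over 2010–2030.

Illuminated fraction is `(1 + cos i)/2` where the phase angle `i` comes
from the sun–moon elongation and the finite sun and moon distances.
Timestamps are treated as UT1 (ΔT is neglected — about one minute in this
era, well under the stated tolerances, and applied identically in the test
oracle). All computation is in UTC; the site is a single (lon, lat) pair
per dataset, configurable, defaulting to a South Texas rangeland site
(−97.44, 26.54).

Full/new-moon instants (used by the lunar-window collar scheduler) are
local extrema of the illuminated fraction located on a 30-min grid and
refined by golden-section search; no external almanac is consulted.

## Synthetic cohorts

The generator's defaults are the package's study conditions; they were
fixed once, on field-realism grounds, and all tests run against them.

Latent velocity per animal, on a 5-min grid:

    v_t = baseline × diel(SunAlt_t) × lunar_t × heat_t × exp(x_t)

* `diel`: the species' Night/Crepuscular/Day multiplier via the same ±13.5°
  rule the analysis applies. Ocelot archetype 2.2 / 1.4 / 0.6 (nocturnal);
  bobcat archetype 1.3 / 2.0 / 0.7 (crepuscular). Baselines 150 and
  180 m/h — the order of magnitude of felid hourly displacement.
* `lunar = exp(lunar_effect × frac × [MoonAlt > 0])` on Night records only;
  ocelot −0.6 (dark-moon hunter), bobcat +0.4.
* `heat`: on Day records of days with TMAX ≥ 33 °C, multiply by the
  species' hot-day multiplier (ocelot 0.5, bobcat 0.9; 1.0 means no
  suppression).
* `x_t`: stationary AR1 on the log scale, φ = 0.6 per 5-min step, marginal
  sd 0.4 — the serial structure the accelerometer series is expected to
  inherit.

Positions evolve by a correlated random walk (heading innovation sd 0.4
rad/step, step length v_t·dt); GPS fixes sample the path per collar
schedule with 15 m Gaussian jitter per axis and HDOP = 1 + Gamma(2, 1.9),
which puts ≈5% of fixes above the HDOP 10 censoring threshold so the
censoring path is always exercised. Collar schedules mirror real
deployments: continuous 30-min fixes, or daily noon/midnight anchors plus
30-min fixes in 24-h or 72-h windows centred on each full and new moon.

Accelerometer counts per axis are a saturating map of latent velocity,
`255·v/(v + 400)` (counts are bounded at 255 while velocity is not), plus
AR1 count noise shared between axes (sd 10) and per-axis (sd 3), rounded
and clipped to [0, 255]. The shared noise plus the common velocity signal
reproduce the strong inter-axis rank correlation of real bi-axial collars
(target ≈0.96; realised values run 0.96–0.99 depending on how much diel
spread the cohort exhibits). An
injected "malfunction" replaces the signal with a constant, decoupling
counts from velocity, to exercise the malfunction detector. The field
device aggregates 4 Hz acceleration differences into one 0–255 value per
5 min by an unpublished rule; the generator emits the 5-min values directly
rather than simulating the within-interval aggregation.

Daily weather is a sinusoidal seasonal TMAX (annual mean 31 °C, half-range
6 °C, peak at day-of-year 200) with anomalies split into shared and
independent parts so the *total* TMAX/TMIN Pearson correlation over the
simulated span hits the configured 0.85 (the seasonal cycle alone already
correlates the two; the split solves for the remainder and floors at fully
independent anomalies when the target is infeasible). TMIN is clamped at
least 0.5 °C below TMAX.

What the generator does **not** emulate: home-range geometry and site
fidelity, habitat selection, inter-individual interactions, denning
behaviour, cloud-cover light modulation, and GPS fix failure/irregular
dropout. Passing recovery tests therefore demonstrate that the pipeline's
statistics recover the drivers *when the model family matches the
generating process*; they do not validate behaviour under movement
processes outside that family.

## Trajectory

Step velocity is haversine distance on a sphere (R = 6,371,000 m) divided
by the lag in hours, stamped at the interval end. At sub-kilometre steps
the sphere-vs-ellipsoid discrepancy is far below GPS jitter. "High
frequency" is lag ∈ [25, 35] min, absorbing collar timing jitter around
the nominal 30-min schedule. HDOP censoring removes values strictly
greater than 10 (the boundary is kept). Censoring never sorts silently:
unsorted input is an error, because a silent sort could mask duplicated or
interleaved collar downloads.

Note the generator's ground truth is the *latent* 5-min speed, while True
Velocity is a 30-min net-displacement rate; turning within the interval
makes the latter systematically smaller (tortuosity). The transform is
monotone in practice, which is all the rank-based fidelity checks and the
ordinal activity comparisons require.

## Fusion

Feature windows are trailing and half-open, (t−30 min, t], so a window is
exactly the six 5-min readings ending at the GPS interval end; features are
attributed to the ending location. Variance is the sample variance (n−1).
Windows with fewer than six readings are missing data, not errors.

The regression is a random forest (1,000 trees, 2 of 8 features per split,
fixed seed). Both resubstitution and out-of-bag R²/RMSE are reported and
labelled: resubstitution numbers flatter any forest, and the two are kept
side by side rather than guessing which convention an external report
used. Predictions are clipped to the training-target range (the ensemble
mean already lies inside it).

Malfunction detection quantifies "high velocity with abnormally low
counts": an individual is flagged when ≥ 3 paired intervals have velocity
above the cohort's 0.9 quantile while mean combined activity falls below
the cohort's 0.1 quantile. Flagged individuals are censored from model
training and prediction but keep their GPS-only records.

The studentized Breusch–Pagan test regresses scaled squared residuals on
the fitted values (statsmodels implementation); simulation places its size
at ≈5% and its power against variance ∝ fitted value near 1 at n = 500.

## Covariates

The stated field convention — scale/centre velocity, then log — is
undefined for sub-mean values, so the package applies log(1 + v) first and
then centres/scales per species (mean 0, sd 1 within species). The offset
1 is configurable (`offset=` in `standardize_velocity`); no claim is made
about which convention the original field analysis used. Standardizing per
species removes baseline differences so the cross-species factor contrasts
compare *patterns*, not absolute speed.

The TMAX join uses the local civil date at a fixed UTC−6 offset
(configurable); TMIN is carried for diagnostics only, since TMAX and TMIN
are too correlated (r ≈ 0.85) to coexist in one linear model.

Boundary decisions, all inclusive-to-the-middle and covered by tests:
SunAlt exactly ±13.5° is Crepuscular; MoonAlt exactly 0 is Dark;
TMAX exactly 33 °C is Hot.

## Inference

The AR1 index runs over observation order within individual, not elapsed
time — the discrete-lag convention of classical mixed-model software. With
mixed 5-min (Predicted) and 30-min (True) cadences, consecutive
observations therefore carry the same correlation φ regardless of the gap;
this is a documented limitation inherited from the convention, acceptable
because φ acts as a nuisance absorbing short-range dependence rather than
as a quantity of interest.

Random intercepts for individual and Type are crossed and independent. The
Type factor has only two levels, so its variance component is weakly
identified and frequently lands at the boundary; the fit reports boundary
components in `fit.boundary` rather than failing. Fitting maximizes the
marginal likelihood over (log λ_id, log λ_type, arctanh φ) with β and σ²
profiled out in closed form; the AR1 correlation inverse is applied
analytically (tridiagonal) and the random-effect contribution enters
through a symmetric Woodbury factorisation that is stable as λ → 0.
L-BFGS-B runs from three fixed starts (ftol 1e-10); the best finite
optimum wins, and total failure raises an error carrying all optimizer
traces. AIC counts p fixed coefficients + 2 variance ratios + φ + σ².

Wald t statistics and CIs use residual degrees of freedom (n − rank), the
conditional-t convention of the classical software; no Satterthwaite or
Kenward–Roger correction is attempted.

Estimated marginal means are built on the full reference grid of the
model's categorical factors with numeric covariates at their sample means,
then averaged with equal weight over the levels of factors outside the
requested grid. Pairwise contrasts within a family (all cells sharing the
`group_by` values) are adjusted by the studentized range with the family's
cell count; the scipy distribution is cross-checked in the tests against a
direct numeric integration of the studentized-range tail, and the residual
df passed to it is capped at 2000, where the distribution is already
asymptotic (difference < 1e-4). Degenerate zero-SE contrasts report p = 1.
Empty factor cells are logged; their coefficients are handled by
pseudo-inverse, and contrasts touching unsupported cells should be read
with care (the evaluation helpers average only over data-supported cells).

## Problem sizes

The shipped studies use sizes chosen to make their statistical targets
decisive on a single CPU: the pattern-recovery study runs 20 replicates of
8 continuous-collar animals over 43 days (~15,000 True Velocity records
each, the scale of a multi-year field deployment's retained fixes); fusion
fidelity uses 2 animals over 30 days (~2,600 training windows) with the
full 1,000-tree forest; the Breusch–Pagan operating characteristics use
200 replicates at n = 500; ephemeris accuracy uses 1,000 random instants
over 2010–2030 at random mid-latitude sites.

## Known limitations

* The likelihood treats the AR1 over observation order; irregular gaps are
  not downweighted (see above).
* Velocity as an activity proxy under-counts in-place activity; the
  malfunction detector exploits the converse asymmetry (high velocity with
  low counts is anomalous, low velocity with high counts is not).
* The lunar covariate is geometric (fraction × above-horizon); cloud cover
  and anthropogenic light are not modelled.
* The moon-phase instants and the LunarDiel factor share the package's own
  ephemeris; an error there would propagate coherently to both (mitigated
  by the independent-oracle accuracy tests).
* `lunar_window` schedules centre windows on phase-extremum instants, not
  on local night; the real collars centred on the full/new-moon *night*,
  a subtlety that at most shifts window edges by a few hours.
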