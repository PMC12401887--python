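# Methods

This note documents the models, conventions and design choices behind
`thermoreg`, in the order data flow through the pipeline.

## Measurement model and preprocessing

A plant's record is a 1-min paired (T_leaf, T_air) series over local clock
time. Analyses use the equilibrated window **12:30–15:00 inclusive**
(loggers run from 12:00; the first half hour is treated as equilibration).
Timestamps are clock times without timezone or date arithmetic, because all
windowing is clock-based.

Evaporative-cooler cycles produce transient air-temperature drops with high
variance; these minutes are removed by trimming pairs whose **air** reading
is at or below 16 °C (benign treatment) or 31 °C (high treatment). The
choice of channel is a package decision: the artefact being removed is an
air-circulation effect, so the air channel drives the filter (trimming on
the leaf channel instead would remove structurally different minutes for
strongly decoupled leaves). Retention is strictly greater-than. Pairs, not
single channels, are removed, so the two channels stay aligned. Both
filters are idempotent row filters and commute; the staged row counts are
reported per plant and never silently dropped.

## Thermal offset and coupling strength

ΔT(t) = T_leaf(t) − T_air(t) per retained minute; the per-plant summary is
its unweighted mean. Coupling strength β is estimated from
**non-overlapping 30-min windows** left-anchored at the analysis-window
start: within each window the OLS slope of T_leaf on T_air is computed,
and β is the unweighted mean of retained window slopes. Partitioning (not
a rolling window) reflects the "at 30-min intervals" protocol; the
window-mean aggregation is one of two defensible readings, and the
alternative (one pooled regression over all retained minutes) is exposed
as `method="pooled"`.

Window retention guards: a window needs ≥ 10 points and an air range of
≥ 0.2 °C (thermostated rooms can produce near-constant regressors whose
slopes are numerically meaningless). Skipped windows are reported, never
imputed. Classification uses a tolerance ε = 0.1 around β = 1 (inclusive
at the boundary, with a 1-ulp float guard): β < 1 − ε limited homeothermy,
|β − 1| ≤ ε poikilothermy, β > 1 + ε megathermy. ε = 0.1 is motivated by
the ~0.7–1.3 range of β reported as viable across large canopy data sets,
and is configurable.

## Leaf traits and PCA

From a single measured leaf per plant: LWC = (wet − dry)/wet,
LDMC = dry/wet (so LWC + LDMC = 1 identically), LMA = dry/area converted
to kg m⁻², LD = dry/(area × thickness) in g cm⁻³. Validation rejects
dry > wet and non-positive measures.

The six-trait PCA (area, width, thickness, LWC, LD, g_sw) standardizes each
trait and eigendecomposes the correlation matrix. Standardization is the
package default because the traits mix cm², mm, fractions and
mol m⁻² s⁻¹; covariance-matrix PCA is available via `standardize=False`.
Components are ordered by decreasing eigenvalue; each loading vector is
oriented so its largest-magnitude element is positive (a pure sign
convention). Contributions are squared loadings expressed as percentages of
each component. Plants without g_sw (unmeasurable on very small leaves) are
excluded from the PCA but retained everywhere else.

## Thermal time constant

τ = φ·LMA·[c_p,w/(LDMC·h) + (c_p,d − c_p,w)/h] seconds. The bracket times
LMA is the wet leaf's heat capacity per projected area: a leaf with dry
mass per area LMA carries water mass LMA·(1/LDMC − 1), giving mass-specific
heat C_mass = c_p,w/LDMC + c_p,d − c_p,w; dividing by the heat transfer
coefficient h yields a time. This is the unique reading of the composite
expression that is dimensionally correct and reduces to
heat-capacity-over-conductance. φ (projected-to-total area, default 0.5)
multiplies the whole bracket once. Defaults c_p,w = 4181 and
c_p,d = 2814 J kg⁻¹ K⁻¹.

h uses the laminar forced-convection flat-plate correlation collapsed to a
single coefficient, h = a_h·√(u/w) with leaf width w as characteristic
length, a_h = 3.87 W m⁻² K⁻¹ (m s)^½ (from 0.664·k_air·Pr^⅓/ν^½ at ~25 °C)
and wind speed u = 1 m s⁻¹ by default. Both are configurable; because the
true boundary-layer formulation and wind speed of any given glasshouse
differ, absolute τ values are comparable across leaves in rank and ratio,
not anchored in absolute scale. There is no free-convection fallback: u ≤ 0
or w ≤ 0 is a domain error.

Monotonicity built into (and tested against) the model: τ increases with
LMA and width, decreases with LDMC (wetter leaves respond more slowly) and
with h.

Psychrometrics use the Tetens saturation vapour pressure
e_s = 0.6108·exp(17.27·T/(T + 237.3)) kPa, VPD = e_s·(1 − RH/100). Note:
reported glasshouse conditions of 38.5 °C at 23.8 % RH imply ~5.2 kPa under
Tetens, whereas 6.3 kPa has been reported for such conditions; the package
computes, it does not reconcile.

## Statistics

The treatment×biome analysis is a **fixed-effects** Type III ANOVA:
sum-to-zero (effect) coding; each term's sum of squares is the RSS increase
when its columns are dropped from the full interaction model; denominator
df from the full-model residual. Random intercepts (species within family,
growth form, plant identity) are deliberately not fitted: mixed-model REML
is well served by existing packages and is not what this pipeline is for.
Consequently F statistics are the fixed-effects analogue, not numerically
comparable to a mixed-model fit of the same data; with one value per
plant×treatment the repeated-measures correlation is ignored.

Pairwise contrasts use Tukey's HSD via the studentized-range distribution,
with the Tukey–Kramer standard error for unequal group sizes and residual
df from the one-way cell-means model (no Kenward–Roger). Holm-adjusted
pooled-t comparisons are the alternative. Groups with n = 1 are excluded
with a warning.

Group-mean CIs are seeded nonparametric percentile bootstraps (default
1000 resamples, 95 %). Percentile intervals at n = 25–30 undercover
slightly (~93–95 % for Normal data), which is the known behaviour of the
method, verified by simulation in the acceptance suite.

## Synthetic experiment generator

The generator emulates the study the pipeline is designed for, so every
stage is exercisable end to end without raw data:

- **Design**: 15 species (5 per biome, the study's species/family/growth
  form table), 5 replicate plants each, two sequential treatments →
  75 plants, 150 logger series; 18 plants lack g_sw.
- **Air profiles** (per plant×treatment): AR(1) fluctuation (coefficient
  0.9, innovation sd 0.3 °C — chosen to resemble smooth canopy profiles)
  around a canopy mean of 23.2 °C (benign) or 35.7 °C (high; canopy level
  runs below the room setpoints), plus episodic cooler dips: start
  probability 0.02 min⁻¹, geometric duration (mean 5 min), depth
  ~N(9, 1) °C. This occupancy×depth combination is calibrated so ≈10 % of
  minutes fall below the treatment's trim threshold, matching the reported
  fraction of data removed by trimming.
- **Leaf channel**: t_leaf = pivot + δ + β_g·(t_air − pivot) + ε,
  ε ~ N(0, 0.3² °C). The pivot is the mean of the *protocol-retained* air
  minutes, so the generating δ is exactly the thermal offset the pipeline
  estimates and β_g exactly the generating slope — estimator bias from
  trimming is removed by construction rather than left as a confound.
- **Offsets**: the six biome×treatment presets (temperate 1.99 ± 1.30 /
  0.60 ± 0.91, alpine 0.63 ± 1.01 / −1.25 ± 0.77, desert 0.50 ± 1.05 /
  −1.66 ± 0.92 °C for benign/high) are treated as *observed cohort
  statistics*: per-plant δ are Normal draws standardized so each 25-plant
  cohort has exactly the preset mean and sd. The generator reproduces the
  observed study rather than resampling a superpopulation; between-plant
  spread, plant ranks, series noise and trimming remain stochastic. The
  printed ± values are interpreted as between-plant sd; if they were CI
  half-widths the cohort means — the quantities the pipeline asserts —
  would be unchanged.
- **Slopes**: per-plant β_g ~ N(0.85, 0.1) in benign cohorts (limited
  homeothermy) and N(1.1, 0.1) temperate / N(1.0, 0.1) alpine and desert
  at high temperature — directions follow the observed qualitative
  pattern; the numbers are generator defaults, not estimates.
- **Traits**: log-normal biome clusters (alpine thick/less dense/wet/high
  g_sw; temperate thin/dense/dry/low g_sw with a wide size range; desert
  small and narrow), with masses derived self-consistently from density ×
  volume and LWC. Numeric cluster parameters are invented defaults chosen
  to be physiologically plausible; species labels are design bookkeeping
  (variation is drawn at plant level).

What passing tests on synthetic data do **not** show: recovery under
non-linear leaf–air coupling, radiation-driven microclimate structure,
stomatal dynamics, or measurement error structure of real thermocouples.
The generator is a linear-coupling emulator, and pipeline validation on it
demonstrates estimator correctness, not field realism.

## Problem sizes and determinism

Default analyses run the full 75-plant × 2-treatment design (180-min
series), which completes in seconds; Monte-Carlo test suites use 60–200
replicate series and 2000 bootstrap-coverage simulations. Everything
stochastic flows from a single integer seed through spawned numpy
Generators; identical seeds give byte-identical generated CSVs and result
tables. Series are written rounded to 0.001 °C (below any physical signal,
keeping files compact and round-trips exact).

## Known limitations

- Which channel the original trimming rule used is not documented in the
  protocol this package follows; the air-channel decision is recorded
  above and configurable in effect via the thresholds.
- β aggregation (window mean vs pooled regression) is a documented choice;
  both are implemented.
- The fixed-effects ANOVA is not a substitute inference for designs with
  strong clustering by species or family.
- Absolute τ values depend on the unknown true h(width, wind) formulation;
  only relative comparisons are meaningful.
- The alpine climate preset's printed temperature range is internally
  inconsistent by 1.0 °C with its MaxT − MinT; `validate_t_range` flags it
  and leaves the printed values untouched.
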