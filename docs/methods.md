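# Methods

## The model

The response is minute ventilation normalized by forced vital capacity,
V̇E/FVC (units min⁻¹, since V̇E is L·min⁻¹ and FVC is L). For repeated
measurements *j* on subject *i*,

    y_ij = x_ij' β + b_i + ε_ij,    b_i ~ N(0, τ²),  ε_ij ~ N(0, σ²),

a general linear mixed model with a subject random intercept — the
variance-components covariance structure. The candidate fixed effects are
HR, f_B, ACT (accelerometry magnitude in g), the warm-up/cool-down flag,
age, sex (0 male / 1 female), BMI, FEV1/FVC and height. Normalizing by FVC
is the device that makes a population-level equation possible: FVC carries
most of the between-person size variation, so the remaining subject effect
b_i is small and a new person can be predicted with fixed effects alone.

### REML estimation

Estimation profiles the variance ratio λ = τ²/σ². For fixed λ the GLS
estimate of β and the REML estimate of σ² are closed-form; by the Woodbury
identity all whitened cross-products reduce to per-subject sums, so a
dataset is summarized once into per-subject sufficient statistics
(X'X, X'y, column sums, y-sums, counts per subject) and any predictor
subset on any subject subset refits in microseconds. That speed is what
makes 511 subsets × 5 folds × replicate cohorts tractable on one CPU.

The profiled criterion −2ℓ_R(λ) is minimized over a 57-point log grid on
[10⁻⁸, 10⁶] plus λ = 0, followed by bounded scalar refinement. Every fit
is audited against 64 fixed pseudo-random λ probes; a probe that
beats the optimum triggers re-refinement and, if the audit still fails, an
error. τ̂² = 0 (the boundary) is reported as-is. With σ = 0 data the
profiled criterion degenerates; the quadratic form is floored at 1e-300 so
the fit still returns the exact least-squares solution.

### Inference and AIC

Wald t-intervals and two-sided p-values use residual (containment-style)
degrees of freedom n − rank(X) − (m − 1) for m subjects. With ~300
observations this is close to any of the common df approximations for
within-subject predictors; for between-subject predictors (sex, height,
age, BMI) it is anticonservative, a known property that the model-selection
rule has to live with (see below).

AIC = −2·logLik_REML + 2q with q = 2, counting only the covariance
parameters (τ², σ²) — the REML convention of the mixed-model software this
field predominantly uses. q stays 2 at the τ² = 0 boundary. The
count-all-parameters convention is available (`aic_of(fit, "all")`).
REML log-likelihoods are not strictly comparable across different
fixed-effect sets; the AIC column follows the field convention regardless,
and the selection rule never relies on AIC alone.

## Cross-validation and model selection

Folds partition subjects, never observations: `grouped_kfold` shuffles the
sorted subject ids with a seeded generator and deals them into k maximally
equal folds. Each fold's model is fit on the training subjects only;
held-out observations are predicted with fixed effects only, and the
percent errors 100·(pred − obs)/obs are pooled over observations across
folds (mean and SD reported, SD with ddof = 1). Train/validation
disjointness is asserted on every fold of every run. The same fold split is
reused across all 511 subsets within one evaluation so percent errors are
comparable between models; the split seed is a required, logged input. A
subset whose training fold makes a between-subject predictor constant
(e.g. an all-male training set for `sex`) keeps its full-data fit but gets
NaN percent error, logged; NaN never wins a criterion.

The best model of a given size is chosen by a three-criteria cascade:

1. a model that minimizes both |mean percent error| and AIC wins outright;
2. otherwise the percent-error winner and the AIC winner are compared on
   the confidence of their estimates: the candidate whose *worst*
   coefficient p-value (intercept included) is smaller wins;
3. any remaining tie goes to the smaller |mean percent error|.

Step 2 is deliberate: with 15 subjects, the mean percent error differences
among reasonable models are noise-level (tenths of a percentage point),
while a model carrying a genuinely irrelevant predictor almost always shows
a weak p-value somewhere. Breaking disagreements by worst-case p rather
than by raw percent error makes the choice reproducible across fold seeds;
every selection emits a machine-readable report naming the deciding
criterion.

## Preprocessing conventions

- Breath events attach to the 1-second row containing the exhalation start
  (floor); two breaths flooring to the same second sum on that row; total
  attached volume is conserved exactly.
- Fixed windows (60/30/15 s) align to the session start. Window V̇E is
  mean V_T × mean f_B — the mean volumetric flow rate, not the literal
  volume in one minute; a total-volume/duration variant exists behind
  `ve_mode="volume_rate"` for sensitivity checks. Windows containing no
  breath have undefined V̇E and are dropped with a log line.
- The individual-breath dataset emits one record per breath after the
  first, averaging the 1-second rows since the previous breath's row
  (exclusive) through the breath's own row (inclusive).
- `warm` is 0 up to and including the last maximum of the 15-second
  centered rolling mean of HR, 1 after — a single-peak protocol assumption;
  sample-to-sample differencing would flip the flag on HR noise. A constant
  series is all 0. Per fixed window the flag is the majority value.

## The synthetic-data generator

The generator stands in for the raw study data, so its defaults are the
study conditions and every statistical claim the package makes is tested
against its known truth.

**Cohort** (n = 15 by default): age ~ N(17.3, 1.3²) truncated to [15, 18];
height ~ N(175, 10²) cm; 40% female; race sampled over the three reference
categories (0.73/0.07/0.20); BMI ~ N(20.6, 2.9²); measured FVC =
NHANES-predicted FVC × N(0.92, 0.10²); FEV1/FVC ~ N(0.88, 0.051²). The
implied cohort means (percent-predicted FVC ≈ 92%, FEV1 ≈ 94%) reproduce
the adolescent-athlete morphology the package targets.

**Treadmill protocol**: ~60 s rest at HR ~N(70, 8²), ~60 s walking near
100 bpm, a 240–300 s linear ramp to a peak drawn U(160, 180), and a
180–240 s cool-down toward baseline + 20, with AR(1) measurement noise
(SD 2 bpm, 10 s correlation).

**Breathing rate**: f_B = max(8, 1.71681 + 0.18363·HR + u). The link line
is not free: it is the unique line that makes the two-predictor truth
(−4.247, 0.0595, 0.226) project exactly onto the HR-only equation
(−3.859, 0.101) under omitted-variable algebra. The deviation u is a slow
AR(1) (stationary SD 4.5, 75 s correlation time) representing
breathing-pattern drift independent of heart rate; its SD is likewise
pinned by the f_B-only projection (slope ≈ 0.44 given the protocol's HR
variance) and matches the scale of the f_B coefficient's standard error
that a 15-subject study of this design produces.

**Tidal volumes**: breaths are spaced 60/f_B seconds (clipped to [1, 10]).
Each breath's V_T is set so that the mean V̇E/FVC over the 1-second rows of
its interval equals β₀ + β_H·H̄R + β_f·f̄_B + b_i + e exactly — the same
row convention the individual-breath preprocessing uses, which is why the
zero-noise pipeline recovers the truth to machine precision rather than
approximately. V_T is hard-capped at `vt_cap_frac`·FVC (default 0.65, a
physiologic guard rail); where the *fixed-effect* demand would push V_T
past 90% of the cap, f_B is raised in one pass so realized V_T sits at 90%
of the cap instead. Using only the deterministic demand for that decision
keeps the recorded f_B independent of the residual noise and of the random
intercept — an f_B raise driven by the realized (noisy) demand would leak
residual into a predictor and bias the fitted coefficients, which is a
generative artifact, not a property of the estimator.

**Residual noise**: e is piecewise-constant on the generator's 30-second
reference window, scaled by σ × (HR-implied demand)/9.5 (floored at 0.5/9.5).
Three properties motivate this over per-breath white noise: (i) the stated
σ is then *exactly* the residual SD of the primary 30-second analysis
dataset; (ii) window residuals are independent, so the mixed model the
package fits is correctly specified at the analysis scale and its
confidence intervals are calibrated (95% intervals cover each generative
coefficient ~95% of the time over replicate cohorts); (iii) breath-level
noise stays at window amplitude, so the V_T cap and the positivity floor
(V̇E/FVC ≥ 0.1) bind for well under 1% of breaths and introduce no
measurable truncation bias. The amplitude is tied to the HR-implied demand
rather than the realized response so the noise scale is independent of the
f_B deviations and the subject intercept. Defaults τ = 0.5 and σ = 1.75
give a between-subject spread of roughly 5% and pooled cross-validated
percent-error SDs in the 20–30% range at the 30-second time base, the
regime reported for adolescent treadmill data of this design; τ much above
0.5 would push some subjects' rest-level ventilation implausibly close to
zero under an additive intercept.

**What the generator does not emulate** — and what passing tests therefore
do not show about real data: breath-scale ventilation noise (shallow breath
followed by a compensating large one) is homogenized within 30-second
blocks, so relative noise across the 15-s and individual-breath time bases
is flatter than in reality; ACT levels are plausible placeholders excluded
from quantitative claims; HR/f_B dynamics carry no oxygen-uptake kinetics
or dead-space physiology; and the residual truly is exchangeable at the
analysis window, which real wearable data will not be. Real-data percent
errors should be expected somewhat worse than the synthetic ones.

**Field sessions**: rest/activity bouts of 3–8 minutes alternate between
HR levels ~75 and U(120, 170), smoothed over 30 s. PM2.5 is a stationary
AR(1) at 1-minute resolution with the requested mean, SD = 0.25·mean,
lag-1 correlation 0.8, floored at zero (a mean of 0 yields an identically
zero trace).

All randomness flows from one seed; per-subject and per-session substreams
are spawned deterministically (`SeedSequence`), so every artifact is
reproducible bit for bit from the top-level seed.

## Dose integration

Per 1-minute concentration interval, V̇E is the mean of per-second
predictions within that minute; volume = V̇E × covered-minutes / 1000 (m³),
exposure = C × covered-minutes (µg·min·m⁻³), dose = C × volume (µg), all
summed by the rectangle rule with no interpolation; partial leading or
trailing minutes are weighted by their coverage fraction. Predicted
ventilation is floored at zero — the linear equations go negative below
HR ≈ 38 under the HR-only model, and negative ventilation is unphysical;
the floor's effect is confined to rest-level extrapolation. Gaps in
concentration coverage and negative concentrations are errors, not
warnings. The unit chain (L·min⁻¹ ventilation, µg·m⁻³ concentration, m³
volume, µg dose) is covered by exact closed-form tests.

## Numerical and degenerate-input conventions

- Percent error requires strictly positive observations; a nonpositive
  held-out response is an error (the ratio is undefined).
- Constant HR series: the warm flag is all zero (tie broken toward
  "still warming").
- Rank-deficient designs name the collinear columns; a single subject, or
  a subject with one observation, is rejected (the random intercept is
  unidentifiable).
- `enumerate_subsets` orders subsets by size then lexicographically and
  refuses more than 20 candidates (2²⁰ models is past the tool's remit).
- Fold assignment depends only on the sorted set of subject ids and the
  seed, so cross-validation is invariant to dataset row order.

## Known limitations

- The reference-equation module covers the three NHANES III race
  categories; other categories must be mapped explicitly by the caller —
  the package refuses to guess. Lower-limit-of-normal values are secondary
  outputs and less thoroughly validated than predicted values.
- Containment-style degrees of freedom overstate precision for
  between-subject predictors with 15 subjects; the selection cascade is
  designed so this cannot promote a spurious between-subject predictor,
  but reported p-values for such predictors should be read with care.
- Only the random-intercept (variance-components) covariance structure is
  implemented; random slopes, non-identity links and small-sample df
  corrections (Satterthwaite, Kenward-Roger) are out of scope.
- REML-based AIC comparisons across fixed-effect sets inherit the field
  convention's caveat noted above.
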