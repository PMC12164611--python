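# Methods

## The problem

A day is a closed budget: 1440 minutes split between sleep, sedentary
time (SED) and light-, moderate- and vigorous-intensity physical
activity (LPA, MPA, VPA). Because the five durations must sum to a
constant, they carry only *relative* information, and entering raw
minutes into ordinary regressions induces spurious collinearity: adding
time to one behaviour necessarily removes it from others. `coda24`
treats the daily budget as a five-part composition in the Aitchison
geometry and analyses its association with cardiometabolic risk (CMR)
factors — BMI, BMI z-score, fasting glucose, insulin, HDL-C, LDL-C,
triglycerides, systolic/diastolic blood pressure and waist
circumference — in children and adolescents.

## Compositional machinery

**Closure.** A positive vector x is closed as C(x) = x · (1440 / Σx).
Closure is idempotent; the tolerance on the closure invariant is 1e-6
relative. All logarithms are natural.

**Zero replacement.** Zero VPA days are certain in accelerometer data
and log-ratios need strict positivity. Two strategies are provided:
`fixed_floor` (zeros become a floor, default 0.5 min, then re-close)
and `multiplicative` (zeros become the floor; the non-zero parts shrink
so the original total is preserved). The fixed floor is the default
because it perturbs non-zero parts only through the final closure.

**CLR / ILR.** clr(x)_i = ln x_i − mean_j ln x_j maps a composition to
a zero-sum vector; an ILR basis is a (D−1)×D matrix V of orthonormal
zero-sum contrasts, and ilr(x) = V clr(x) gives D−1 unconstrained
coordinates suitable for ordinary least squares. We use *pivot*
(sequential-binary-partition) bases: the first coordinate of the basis
led by part b is

    z1 = sqrt((D−1)/D) · ln( x_b / gm(x_rest) ),

the balance of b against the geometric mean of the other four parts.
With D = 5 the lead weight is sqrt(4/5) ≈ 0.894 and each remaining part
gets −sqrt(1/20). The first coordinate is invariant to the ordering of
the remaining parts; coordinates in any two valid bases differ by an
orthogonal rotation, so distances, fitted values, R² and joint tests
are basis-invariant. No extra rescaling is applied to the reported
first-pivot coefficient.

**Compositional centre.** The geometric-mean composition (part-wise
geometric means, re-closed) equals the ILR-inverse of the mean ILR
vector in any basis; this identity is used as a test oracle. The
variation matrix reports var(ln(x_i/x_j)) with the n−1 denominator; it
is symmetric with non-negative off-diagonal entries by construction.
(Published variation matrices occasionally print negative entries,
which is impossible under this definition and suggests a different
centred statistic; this package implements only the standard one and
makes no attempt to match such tables.)

## Cohort assembly

Daily records carry accelerometer-derived SED/LPA/MPA/VPA minutes,
self-reported sleep, wear time and the monitoring month. A day is valid
when wear time ≥ 600 min (10 h) and sleep lies in [240, 960] min; a
participant is retained with ≥ 3 valid days. These thresholds stand in
for study-specific criteria that are not published in full and are
fully configurable. Exclusions are logged with reason codes
(`malformed`, `wear_time`, `sleep_bounds`, `too_few_days`,
`missing_outcome`), and retained + excluded always equals the input
count.

Within a participant, behaviour minutes are averaged across valid days
*before* closure. Because mean wear plus sleep rarely fills 24 h, the
four waking behaviours are rescaled proportionally to 1440 − mean
sleep — the least-informative reconciliation consistent with a closed
day — then zero-replaced and closed. The monitoring month is the modal
month over valid days, ties resolved to the earliest. Missing outcomes
are handled by listwise deletion per outcome model (each outcome's
model uses exactly the participants who have that outcome); there is no
cross-outcome imputation.

## Regression model

For each outcome y (natural-log-transformed for BMI, glucose, insulin,
HDL-C, LDL-C, triglycerides and waist circumference; identity for BMI
z-score and the blood pressures):

    T(y) = β0 + β' ilr(x) + γ' covariates + ε,

with covariates age (years), sex (reference male), ethnicity (White /
Black / Asian / NotReported, reference White) and monitoring month
(dummy-coded, reference January). The model p value is the joint F test
of the four ILR coordinates against the covariate-only model. The
reported R² is the *increment* over the covariate-only model — the
share of variance attributable to the composition itself — with a
switch for total model R². Refitting with each behaviour in the pivot
position yields one coefficient per behaviour (its balance against the
remaining four), with two-sided t tests and 95% CIs, no multiplicity
adjustment. The five pivot coefficients are projections of a single
zero-sum CLR vector (pivot_b = sqrt(D/(D−1)) · clr_b), which the tests
verify numerically.

The core is exposed as scikit-learn-style estimators
(`IlrTransformer`, `CompositionalRegression`) so the transform and
model compose with sklearn pipelines; module-level functions
(`fit_compositional_model`, `summarize_models`) wrap them.

## Isotemporal substitution

A reallocation moves δ minutes (default 10) from a donor behaviour to a
receiver at a reference composition — the sex-specific geometric-mean
composition, from sex-stratified fits by default (a pooled-fit option
exists; the underlying reports are ambiguous on this point). The
predicted model-scale change is Δŷ = β'(ilr(x') − ilr(x)); covariate
terms cancel exactly, which is verified by predicting at two covariate
profiles. Percent change around the sample mean is 100·Δŷ/ȳ for
identity outcomes and the exact 100·(exp(Δŷ)−1) for log outcomes (a
first-order switch is available). Cells whose donor cannot spare δ
minutes are reported missing, never fabricated.

Two asymmetry facts are deliberate and tested: (i) a reallocation and
its *undo* (moving the minutes back from the reallocated composition)
negate exactly in model space; (ii) swapping donor and receiver *from
the same reference* gives opposite signs but unequal magnitudes,
because ln((a−δ)/a) ≠ −ln((a+δ)/a) — most visibly when the donor is a
small part such as VPA. Published change matrices show exactly this
pattern.

**Smallest worthwhile change.** SWC = 0.2 × group SD (n−1), per sex and
outcome, also expressed as a percent of the group mean; a cell is
flagged when its absolute predicted change exceeds the SWC. When an
outcome's mean is near zero (BMI z-scores average ≈ 0), percent-of-mean
changes explode while remaining numerically valid; matrices then carry
an `extreme_percent_warning` and an absolute-units table rather than
suppressing the cells.

## Synthetic cohorts

Real cohort data of this kind are third-party and not redistributable,
so the generator produces cohorts with the statistical structure the
analysis assumes, plus ground-truth bookkeeping:

- **Compositions** are logistic-normal: Gaussian ILR coordinates around
  sex-specific centres (defaults: boys (342.1, 350.7, 40.5, 14.0,
  692.7) and girls (365.8, 348.5, 30.2, 11.5, 681.1) minutes, the
  published cohort centres), mapped back to the simplex. The default
  ILR covariance derives from per-part log SDs (0.25, 0.20, 0.45, 0.70,
  0.09): relative spread largest for VPA, smallest for sleep, giving
  plausible minute-scale spread (e.g. VPA ≈ 14 × e^±0.7). Logistic
  normality makes linear-on-ILR regression exactly correctly specified,
  so recovery tests are sharp.
- **Days**: 3–7 monitored days per participant (mean 5.8, SD 1.2);
  day-level log-normal jitter (SD 0.15 waking, 0.04 sleep) around the
  participant mean; 2% of days have VPA exactly zero to exercise
  zero replacement; wear time is the waking-minute sum. Planted invalid
  days and planted exclusions are recorded exactly, which is what makes
  the participant-flow test exact.
- **Outcomes** are linear in the ILR coordinates of the *assembled*
  composition (the one the ingest step reconstructs), plus age and sex
  effects and Gaussian noise. Coefficient vectors use published
  per-behaviour sign patterns, rescaled so the compositional increment
  R² hits a stated target given a plausible outcome SD — published
  coefficient magnitudes and variance shares cannot both be taken at
  face value without the source data, so the share is treated as
  primary. Noise SDs are solved from the target R² via the population
  variance decomposition (within-sex compositional variance / total).
  Missingness rates mirror the per-outcome availability of the emulated
  cohort.

What the generator does **not** emulate: accelerometer count time
series and cut-point classification, inter-cohort heterogeneity,
seasonal structure in behaviour (month is a pure noise covariate),
outcome-outcome correlations, and non-Gaussian outcome tails. Passing
recovery tests therefore demonstrates correctness of the *pipeline
under its own model assumptions*, not robustness to real-data
violations of them. A small known artifact: zero-VPA measurement days
pull the assembled VPA centre ~2% below the drawn centre; the drawn
compositions themselves are unbiased.

## Validation studies

- **Coefficient recovery** (default n = 2000/sex, 200 replicates): full
  pipeline per replicate; 95% CI coverage pooled over the five
  behaviours sits in [93%, 97%], and per-behaviour relative bias is
  well under 2%. The validation config is designed from a precision
  analysis rather than realism: an isotropic ILR covariance (0.35² I)
  identifies every pivot balance equally, and the balanced zero-sum CLR
  vector (1, 1, −2/3, −2/3, −2/3) with increment R² 0.30 puts the
  Monte-Carlo noise of each per-coefficient bias estimate near 0.5%,
  far below the 2% bound being checked — under a movement-like
  covariance the sleep balance is so weakly identified that the noise
  floor of the bias *measurement* at 200 replicates would be
  comparable to the bound itself.
- **Change-matrix consistency**: the maximum absolute gap between
  pipeline and analytic (planted-coefficient) percent matrices, averaged
  over 8 replicates per size, shrinks over n ∈ {500, 2000, 8000}.
- **Type-I calibration**: with a zero planted CLR vector, the joint F
  test rejects at 5% within the binomial interval over 1000 simulations
  (n = 250 participants each).

These sizes keep the default validation suite around one to two
minutes on a single core while leaving Monte-Carlo error far inside
the acceptance bands.

## Numerical and design choices

- Canonical part order SED, LPA, MPA, VPA, Sleep everywhere.
- Sample variances and SDs use n−1 throughout.
- Cohen's d uses the n−1-weighted pooled SD and the standard normal
  approximation for its CI. Effect bands close the printed threshold
  gaps with half-open intervals on |d| rounded to 2 dp: <0.205 trivial,
  <0.605 moderate, <0.805 large, else very large. d is reported both
  raw and covariate-adjusted (ANCOVA difference / residual SD), since
  adjusted and raw versions can differ materially and published tables
  do not always say which they print.
- ANCOVA adjusted means are least-squares means at sample-average
  covariate values; the F for the group factor equals the squared t of
  its dummy, verified against an explicit nested-model F.
- Rank deficiency raises an error naming the first collinear column
  (QR diagnostic).
- Degenerate inputs: all-zero part vectors, non-positive closure
  totals, singular designs, n ≤ p fits, zero pooled SDs and infeasible
  reallocations all raise typed errors rather than producing numbers.

## Known limitations

- The generator's covariance and covariate effects are plausible
  choices, not fits to the emulated cohort; only centres, availability
  rates and variance shares are matched to published values.
- Pooled vs sex-stratified change matrices answer slightly different
  questions; both are supported, stratified is the default.
- The increment-R² definition differs from total model R²; headline
  variance-explained ranges depend on that choice and both are stored
  on every fit.
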