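# Methods

This note documents the statistical models implemented in `circannual`, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the numerical details a user
re-analyzing real data should know.

## Time coordinate

All models work in decimal months since a user-supplied study origin, with one
month fixed at 365.25/12 = 30.4375 days so that a period of τ = 12 months is
exactly one tropical year. Timestamps are treated as UTC throughout. The
origin is configuration, not data: acrophases are only interpretable relative
to it.

## Seasonal reporter index

For gene *g* with polarity *p₉* ∈ {−1, +1}, fish *i* in standardization batch
*b*: z₉ᵢ = (log₁₀ REᵢ₉ − mean_b)/sd_b with the sample (n−1) SD, and
SRI*ᵢ* = Σ₉ *p₉* z₉ᵢ. Batches default to site × study-year because assay
calibration makes expression comparable only within a study iteration; the
batch key is configurable (including a single global batch for laboratory
data). Zero-variance genes raise an error rather than being dropped —
silently omitting a gene would change the index definition. Consequences
worth knowing: within every batch the SRI sums to zero, the index is
invariant to positive rescaling of any RE column, and any effect expressed on
the SRI scale is realized only up to the per-gene standardization SDs (see
*Generator calibration* below).

## Cosinor regression

The linearized model Y = M + β·cos(ωt) + γ·sin(ωt) + covariates + e
(ω = 2π/τ) is fitted by OLS. Conventions and details:

* **Acrophase**: ϕ = atan2(−γ, β), wrapped to (−π, π]; the fitted curve peaks
  at t\* = (−ϕτ)/(2π) mod τ. This reproduces the identities β = A cos ϕ,
  γ = −A sin ϕ.
* **Standard errors**: delta method from the (β, γ) covariance —
  se_A² = (β²V_ββ + 2βγV_βγ + γ²V_γγ)/A², se_ϕ² = (γ²V_ββ − 2βγV_βγ + β²V_γγ)/A⁴.
  Validated against a nonparametric bootstrap (B = 1000): agreement within
  15% at n ≈ 117 and A/σ ≈ 1.2. Both SEs degrade as A/se_A → small; the
  acrophase SE is meaningless for a non-significant sinusoid.
* **Significance and effect size**: joint F-test of {β, γ}; classical
  η² = SS_effect/SS_total with Type II (covariate-adjusted, order-independent)
  sums of squares, because the SS type behind "classical η²" is ambiguous and
  Type II is the covariate-adjusted reading.
* **Box–Cox**: λ maximizing the profile log-likelihood on a grid
  λ ∈ [−2, 2] step 0.05; applied to individual-gene responses only, never to
  the SRI (a signed z-score sum can be negative).
* **Assay plate**: primary linear models omit the plate term so that η² keeps
  its familiar meaning; the penalized-spline route (below) offers the
  ridge-penalized plate intercept as the sensitivity check.
* The fit warns when the sampled time span is below one period (amplitude and
  acrophase weakly identified) and errors below half a period.

Oracle: on any dataset the linearized fit equals the direct nonlinear
least-squares minimizer (dense ϕ grid at 10⁻⁴ rad with profiled M, A, plus
local refinement) to 10⁻⁶ relative error — checked on 50 random datasets in
the test suite.

## Penalized-spline trend model

Y = Xβ + f(t) + Zb + ε with Gaussian errors. f is a rank-k (default k = 10)
thin-plate regression spline: the radial basis |t − tⱼ|³ on the distinct time
points, eigen-truncated to k columns, with the {1, t} polynomial constraint
absorbed and the constant removed by centering. The resulting smoother block
has k−1 columns and a positive semi-definite (k−1)×(k−1) penalty whose null
space is the linear-in-t direction — so as λ → ∞ the smoother degenerates to
a straight line (≈1 effective df), not to zero; this is inherent to
cubic-energy penalties.

* **Smoothing selection**: restricted maximum likelihood (REML) on a 61-point
  log-spaced λ grid. GCV (with the standard df-cost inflation γ = 1.4) is
  available as an option, but GCV's more data-adaptive selection measurably
  inflates the approximate smoother test (type-I 0.084 vs 0.067 for REML at
  n = 120 under the null in our calibration runs), so REML is the default.
* **Plate random intercept**: a full dummy block with identity (ridge)
  penalty and its own λ on a 17-point grid, selected jointly.
* **edf**: trace of (X'X + λS)⁻¹X'X over the smoother columns.
* **ΔDev(%)**: 100·(RSS_ref − RSS)/RSS_ref where the reference model drops
  only the smoother columns (plate block kept at its selected ridge penalty).
  This reads "deviance explained by the temporal trend beyond the parametric
  terms"; other definitions of a ΔDev share exist, and this one is this
  package's reading.
* **p_smooth**: F-type test of the smoother against the reference model using
  the bias-corrected df edf₁ = 2tr(F) − tr(FF) (F the influence-ratio matrix)
  as numerator df. This is an approximation: calibration at n = 120, k = 10
  under the null gives ≈0.067 rejection at nominal 0.05 (the validation suite
  allows ≤0.08). Treat p-values near the threshold with caution.
* **Curve uncertainty**: pointwise bands use the Bayesian covariance
  σ²(X'X + λS)⁻¹; smoothing-parameter uncertainty is not propagated.

### Group-specific smoother difference

For a two-level factor (e.g. photoperiod regimen) the joint model has shared
parametric terms (including the group main effect) and one smoother per group
with its own REML-selected λ. The difference d(t) = Δ_group + f₁(t) − f₂(t)
*includes* the group main-effect coefficient — a pure centered-smoother
difference cannot represent a constant offset between groups. Significance is
declared when the pointwise 95% CI excludes zero anywhere on the overlap grid
(100 points). This anywhere-exclusion screen is **anti-conservative**: with
no multiplicity control across the grid its null rate is well above 5% (≈0.21
in our 500-replicate lab-design calibration). It is a screen for "is there any
evidence of a group difference anywhere", not a calibrated test; a
Bonferroni-style simultaneous band (over the basis dimension) is available via
`simultaneous=True`, and the rule used is recorded in every result.

## Thermal effect and prediction

The per-°C effect is the heated-vs-unheated coefficient from a cosinor model
on the mesocosm SRI (sex + length + ration + heating + year + sinusoid +
sinusoid×year, both study years in one model) divided by the *achieved*
logger temperature difference (mean heated-tank minus mean unheated-tank
temperature), not the nominal +2 °C — the SE is scaled by the same divisor.
Using a treatment contrast rather than a regression on continuous tank
temperature avoids collinearity between temperature and the seasonal
sinusoid. Whether mesor terms should also interact with year is ambiguous;
this model fits a year main effect plus year×sinusoid interactions only.

Prediction: for sampling instants t, predicted(t) = mesor + slope·(T̄wk(t) −
mean over the sampled instants of T̄wk), with T̄wk the mean temperature over
the half-open week [t − 7 d, t). The centering makes the series vary around
the mesor by construction. The prior-week mean is the only temperature lag
used anywhere in the package. Observed-vs-predicted comparison: Pearson r on
the (monthly) sampling grid, and the predicted amplitude from a cosinor refit
to the predicted series (not (max−min)/2, so non-sinusoidal temperature
traces still yield a well-defined amplitude percentage).

## Laboratory model set

Null: sex + length + temperature group. Model 1: + cos(ωt) + sin(ωt)
(photoperiod-independent endogenous trend). Model 2: + PP group main effect +
PP×cos + PP×sin (3 added df; this nests model 1 and represents changed
amplitude/phase or loss of oscillation in the accelerated group). F-tests for
both nested comparisons; AIC from the Gaussian log-likelihood with σ² counted
as a parameter. The verdict rule tests photoperiod first: a significant
model-2 improvement is `pp_effect` regardless of the endogenous test, then a
significant model-1 improvement is `endogenous_trend`, else
`no_temporal_effect`. Per-response tests use unadjusted α = 0.05; a
Benjamini–Hochberg helper is provided for gene batches but is off by default.

## Circular summaries

Acrophases across site×year fits are summarized by the weighted vector mean:
direction atan2(Σw sin ϕ, Σw cos ϕ), resultant length R̄ = |Σw e^{iϕ}|/Σw.
Weights default to the fits' η² (mirroring effect-size-scaled acrophase
plots); the unweighted mean is always reported alongside. Antipodal/zero-
resultant configurations return an explicit undefined-direction flag rather
than an arbitrary angle.

## Synthetic-data generator

The generator reproduces the three sampling schemes exactly:

* **wild** — monthly samples, 10 fish/month/site, two sites, two annual
  cycles (n = 120/site/year), with one temperature series per habitat;
* **mesocosm** — 20 fish/month from 12 tanks with per-tank loggers; per
  quarter each tank contributes exactly 2 + 2 + 1 = 5 fish (the single-fish
  set rotating over the quarter's months); tanks carry a 2×2 heating
  (+2 °C) × ration layout; two annual cycles (n = 480);
* **lab** — 30 weekly samples × 4 treatment combinations (7/15 °C × natural/
  ×2-accelerated photoperiod), one fish per combination per week alternating
  between two replicate tanks (n = 120). Day length (as % of 24 h) is
  generated as a covariate but has zero effect by default, matching the
  finding the designs were built to test and enabling power studies when
  switched on; a `pp_doubles_frequency` switch doubles the accelerated
  group's oscillation frequency for power analyses.

Temperature: T(t) = mean + A_T·cos(2πt/12 + ϕ_T) + A_d·cos(2π·hour/24) +
AR(1) noise, hourly by default (10 °C mean, 6 °C annual and 0.5 °C diurnal
amplitude, AR(1) coefficient 0.9 with 0.3 °C innovations — a mid-latitude
freshwater profile); heated tanks add a constant offset. Expression: effects
are additive on log₁₀ RE (multiplicative on RE), with Gaussian gene residuals
(a Student-t₅ option exists for robustness checks), shared per-plate
intercepts, per-tank effects, Bernoulli(½) sex and Gaussian length (45 ± 6 mm
with optional growth drift).

### Generator calibration

Systematic effects are specified on the **SRI scale** (amplitude, acrophase,
thermal slope per °C, sex/length/ration effects) and injected into each gene
as polarity-signed signal/12. Because the SRI z-scores each gene, the
realized SRI-scale effect equals the nominal target times
(1/12)·Σ₉ 1/sd₉ — an exact identity given a generated table, computed by
`effective_sri_truth` (the factor is ≈1.01 at default settings). Recovery and
coverage tests compare estimates against this realized truth.
`residual_sd_for_eta2(A, η²)` converts a target sinusoid effect size into a
residual SD via η² = (A²/2)/(A²/2 + σ²); the default wild configuration uses
A = 3.95, ϕ = −0.61, σ = 3.35 (η² ≈ 0.41), the field-realistic
strong-seasonality regime, and the default mesocosm configuration uses a
0.249/°C thermal slope with a 1.0 extra seasonal amplitude and σ = 3.3.

What the generator does **not** emulate: non-Gaussian heavy-tailed expression
outliers (beyond the optional t₅ residuals), gene–gene residual correlation
beyond the shared drivers, age/cohort structure, serial correlation of fish
sampled from the same tank in successive months, and measurement error in the
loggers. Passing tests therefore demonstrate correctness of the estimators
under the designs' statistical structure, not robustness to every field
artifact.

## Validation protocol and problem sizes

The validation suite (`tests/test_acceptance.py`) uses: 50 datasets for the
cosinor/grid-search oracle; 500 replicates for amplitude/acrophase coverage
(n = 117 per replicate) and for thermal-slope coverage (n = 480); 1000–1500
replicates for type-I calibration of the exact F-tests and the approximate
smoother test; 500 replicates for the smoother-difference null rate; 200
replicates for each end-to-end thermal-prediction scenario. The pure-thermal
prediction scenario uses a low-noise configuration (SRI residual SD 0.5) so
that the ±30% amplitude criterion measures pipeline bias rather than sampling
noise; at field-realistic noise the slope's own SE (≈0.15 on 0.25) dominates
the amplitude ratio, exactly as the wide uncertainty on the real manipulation
suggests.

## Known limitations

* Single-harmonic cosinor only; asymmetric seasonal waveforms are the
  smoother's job.
* No full REML mixed-model machinery (random slopes, nested random effects);
  random structure is limited to the penalized plate-intercept block.
* The smoother p-value and the difference screen are approximations (see
  above); simulation-calibrated thresholds are recommended for borderline
  decisions.
* Gaussian response models throughout; heavy-tailed expression should be
  Box–Cox transformed or analyzed with caution.
* `estimate_thermal_effect` assumes the heating offset is constant in time;
  thermostat failures that vary ΔT seasonally would bias the per-°C rate.
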