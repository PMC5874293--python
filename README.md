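# circannual

Rhythmometry of seasonal immune allocation in fish, built around gene-expression
reporters. The package implements the statistical pipeline used to ask *what
drives circannual variation in immune gene expression* — endogenous timing,
photoperiod, or temperature — in three-spined stickleback sampled monthly from
wild habitats, from outdoor mesocosms under a +2 °C heating manipulation, and
from a 30-week laboratory photoperiod × temperature experiment.

It is written for quantitative ecologists and ecoimmunologists who have
per-fish relative expression (RE) tables (ΔΔCT-normalized qPCR values) and
habitat temperature-logger series, and who want tested, scriptable versions of
the analyses rather than one-off R sessions.

## What it computes

**Seasonal reporter index (SRI).** Each gene's RE is log₁₀-transformed and
z-scored within a standardization batch (site × study year by default), then
summed with polarity weights: winter-biased genes −1, summer-biased genes +1.
High SRI = summer-like immune expression profile.

**Cosinor regression.** Seasonality is modelled as
*Y*(*t*) = *M* + *A* cos(2π*t*/τ + ϕ) + *e*(*t*) with τ = 12 months, fitted by
OLS via the linearization *Y* = *M* + β·cos(2π*t*/τ) + γ·sin(2π*t*/τ) with
β = *A* cos ϕ, γ = −*A* sin ϕ, plus fixed effects for sex and body length (and
treatments where applicable). Amplitude *A* = √(β²+γ²) and acrophase
ϕ = atan2(−γ, β) get delta-method standard errors; the sinusoid is tested by a
joint F-test and summarized by classical η² (Type II sums of squares). Gene
responses can be Box–Cox transformed (profile-likelihood λ on a grid).

**Penalized-spline trend detection.** A Gaussian additive model
*Y* = *X*β + *f*(*t*) + *Zb* + ε with a rank-k thin-plate regression spline
*f*, an optional ridge-penalized assay-plate intercept block, REML-selected
smoothing, ΔDev(%) for the smoother, and an approximate F-test. Group-specific
smoothers can be compared via the difference curve *d*(*t*) with a pointwise
95% band (photoperiod-treatment test).

**Thermal calibration and prediction.** The heated-vs-unheated mesocosm
contrast divided by the achieved logger ΔT yields a per-°C effect; applied to
prior-week mean temperatures from habitat loggers it predicts a thermally
driven seasonal series, compared against the observed cosinor sinusoid by
Pearson *r* and an amplitude percentage.

**Photoperiod model comparison.** For the laboratory experiment, three nested
models — null (sex + length + temperature), +sinusoid (endogenous trend),
+photoperiod × sinusoid — are compared by F-tests and AIC, with a
PP-first verdict rule.

**Synthetic studies.** `simulate_design` generates all three designs with
known ground truth (wild: 10 fish/month/site over two annual cycles; mesocosm:
20 fish/month from 12 tanks, quarter-balanced, ±2 °C × 2 rations; lab:
30 weeks × 4 treatment combinations, n = 120), including per-habitat/tank
temperature series (annual sinusoid + diurnal cycle + AR(1) noise).

## Worked example

```python
import circannual as ca
from circannual.pipeline import attach_sri, run_field_analysis

cfg = ca.GeneratorConfig.wild(seed=4)          # 2 sites x 2 years, 480 fish
study = ca.simulate_design(cfg)
table, _ = attach_sri(study.table, study.polarity)
print(run_field_analysis(table).to_string(index=False))
```

```
site year   n  delta_dev_pct     p_smooth      edf  acrophase  se_acrophase  amplitude  se_amplitude   p_sinusoid  eta2_pct
 FRN   Y1 120      54.410689 5.159105e-16 5.406747  -0.445042      0.093146   4.484154      0.415142 3.232104e-18 49.467946
 FRN   Y2 120      51.198860 7.656582e-15 5.416891  -0.701524      0.095077   4.317196      0.415807 3.037586e-17 45.787614
 RHD   Y1 120      42.406401 3.156768e-11 5.427528  -0.754021      0.122297   3.360537      0.415923 5.924851e-12 36.029012
 RHD   Y2 120      31.443226 3.197995e-08 4.015956  -0.688100      0.134930   3.387055      0.464084 3.128411e-10 31.386709
```

Each row is one site × year: the smoother's deviance share and significance
first (the cosinor is only reported where the temporal smoother is
significant), then the acrophase ϕ (radians; peak at *t*\* = −ϕτ/2π months
after the study origin), amplitude *A* (SRI units, half the seasonal
peak-to-trough swing), and the sinusoid's η². Here the generated seasonality
(A ≈ 4, ϕ ≈ −0.6, peak in early November for an October origin) is recovered
at every site and year.

The same steps are scriptable from the shell:

```sh
circannual simulate --design mesocosm --seed 6 --out meso/
circannual thermal-effect --meso meso/expression.csv --polarity meso/polarity.csv \
    --tank-temps meso/ --out effect.json
# -> slope=0.260±0.157/degC (achieved dT=2.00)
```

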