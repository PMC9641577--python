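# Methods

This note documents the statistical machinery implemented in `crisk`, the
assumptions it rests on, the defaults and why they were chosen, and what
the simulation-based tests do and do not demonstrate about real data.

## The competing-risks prediction model

The target of estimation is the cumulative incidence of a primary event
(cause 1, "serious fall") in the presence of a competing event (cause 2,
"death from other causes"). The model is the Fine-Gray subdistribution
hazard model: covariates act multiplicatively on the hazard of the
subdistribution, in which subjects who experience the competing event
remain formally at risk. Predicted risk takes the form

    F1(t | x) = 1 − (1 − CIF0(t))^exp(x'β),

where CIF0 is the baseline cumulative incidence at the covariate centring
point (sample means of the design columns) and exp(β) are subdistribution
hazard ratios. Modelling the subdistribution rather than the
cause-specific hazard keeps predicted probabilities from overstating risk
in subjects likely to die of other causes first.

### Estimation

`fit_finegray` maximises the IPCW-weighted partial likelihood. A subject
with a competing event at time s contributes to risk sets at t > s with
weight w(t) = Ĝ(t⁻)/Ĝ(s⁻), where Ĝ is the Kaplan-Meier estimate of the
censoring survival function; Ĝ is evaluated at left limits so an event at
t is not weighted by its own censoring information. The weight factorises
as Ĝ(t⁻) × [1/Ĝ(s⁻)], so all risk-set sums are maintained by cumulative
sums over the time-sorted data and each Newton iteration costs O(n·p²).
Optimisation is damped Newton with step-halving from β = 0; iteration
stops when the score norm falls below 10⁻⁹ or the likelihood reaches its
floating-point plateau (in practice the score norm ends below 10⁻⁶ even at
n = 20 000, and at machine precision for small problems). Ties among
cause-1 event times use the Breslow approximation, consistent with the
Breslow-type baseline estimator H0(t) = Σ d_j / S0(t_j),
CIF0 = 1 − exp(−H0). Standard errors are model-based, from the inverse
observed information.

Degenerate inputs are rejected explicitly: non-positive follow-up times,
zero cause-1 events, and collinear design columns (reported by name).
With no competing events the estimator reduces exactly to Cox partial
likelihood; the test suite verifies β agreement with an established Cox
implementation to 10⁻⁶ and Breslow-baseline agreement to 10⁻⁸.

### Functional form and diagnostics

Continuous predictors may enter through fractional polynomials with
powers from {−2, −1, −½, 0, ½, 1, 2, 3} (0 = ln; a repeated power p adds
x^p·ln x). Because a higher-order FP always attains lower deviance,
selection uses the closed-test procedure: the best FP2 must beat the
linear term by a χ²(3) deviance drop at the 5% level before any
non-linearity is kept, and must beat the best FP1 by χ²(2) to be
preferred over it. Across imputed copies the per-copy winners are
combined by majority vote, ties resolved toward lower order and then
toward linearity. Predictors with negligible association are removed via
an explicit, user-supplied exclusion list — never by automated stepwise
selection.

Proportionality on the subdistribution scale is checked by weighted
Schoenfeld-type residuals (observed minus risk-set-weighted mean
covariate at each cause-1 event) correlated with event-time rank. A
caution established while validating this diagnostic: data whose
cause-specific hazards are proportional are generally *not* proportional
on the subdistribution scale, so null-calibration simulations must draw
from the subdistribution model itself (the generator's indirect method);
against the wrong null the diagnostic appears wildly anti-conservative.

## Pseudo-values

Observed outcome probabilities under right censoring are represented by
jack-knife pseudo-values of the Aalen-Johansen estimator,
θ_i = n·F̂1(t) − (n−1)·F̂1^(−i)(t). Subjects sharing (time, event) have
identical leave-one-out estimates, so the implementation recomputes once
per unique pair; this equals the naive per-subject brute force exactly
(tested to 10⁻¹² on random instances) while costing O(u·m) instead of
O(n·m). Pseudo-values are computed within groups of the linear predictor
(default 50 equal-count groups, stable ties; undersized groups merged
with a neighbour) and never clipped to [0, 1]. Equal-count rather than
equal-width grouping was chosen because it guarantees every group
supports its own Aalen-Johansen estimate. A horizon beyond a group's last
observed time falls back to the last attainable time with a warning.

## Recalibration

When calibration plots show systematic miscalibration at a horizon, the
linear predictor is mapped to recalibrated risk through
r* = expit(γ0 + Σ γ_k fp_k(LP)); individual predictor coefficients are
never re-estimated. Because pseudo-value responses may lie outside
[0, 1], the fit solves logit-link estimating equations with a constant
working variance — equivalently, nonlinear least squares of θ on
expit(·) — with sandwich covariance. The FP search over LP terms is off
by default (identity term only); LP is shifted positive before any power
transform and the shift is stored with the model. Recalibration is
per-horizon and skippable, since a horizon with good apparent calibration
is best left untouched.

## Validation metrics

All "observed" quantities are pseudo-value based, keeping the metrics
consistent under censoring and competing risks.

* **O:E** — mean pseudo-value over mean predicted risk. SE of ln(O/E) is
  sd(θ)/(O√n), treating E as fixed.
* **Harrell's C** — concordance between θ and predicted risk over pairs
  with distinct pseudo-values, prediction ties scoring ½, computed in
  O(n log n) with a Fenwick tree and locked to an exhaustive-enumeration
  oracle. SE is the DeLong-type U-statistic estimate 2·sd(c_i)/√n from
  per-subject mean concordance contributions. **Limitation:** under heavy
  censoring most usable pairs involve censored subjects whose θ values
  differ only through censoring noise — and within LP groups that noise
  anti-correlates with the group incidence — so this C is strongly
  diluted toward (sometimes below) 0.5 and does not reproduce the
  magnitude of a time-to-event concordance index. It retains the locked
  identities (perfect ranking of θ → 1, independent predictions → 0.5).
* **Royston's D** — slope of the pseudo-value logit regression on scaled
  rankits Φ⁻¹((rank(LP)−3/8)/(n+¼))/κ with κ = √(8/π);
  R²_D = (D²/κ²)/(π²/6 + D²/κ²).
* **Calibration curves** — equal-count groups of predicted risk (means of
  prediction and θ) plus a lowess smooth (local linear, span 0.75 by
  default) with a pointwise 95% band from binned standard errors.

Per-practice metrics require ≥ 20 patients and ≥ 2 cause-1 events;
excluded practices are reported with reasons.

## Meta-analysis across practices

Per-practice estimates are pooled by random-effects meta-analysis with
REML estimation of τ², on the scale where each metric's sampling
distribution is closest to normal: ln O:E, logit C with delta-method SE
SE(C)/(C(1−C)), and D unchanged. τ̂² maximises the restricted
log-likelihood over a bounded interval (snapped to 0 when the likelihood
is flat toward the boundary, i.e. whenever observed dispersion does not
exceed sampling dispersion); its CI is profile-likelihood. The 95%
prediction interval is pooled ± t_{k−2,0.975}·√(τ² + SE²)
(Higgins-Thompson convention); the Knapp-Hartung adjustment is not
applied by default. Practices whose transform is undefined (O ≤ 0,
C ∈ {0,1}) are excluded and counted; k is the post-exclusion count.
A practical note from the worked example: with only a few events per
practice, back-transformed pooled log-scale estimates sit visibly above
the cohort-level ratio — small-practice noise is skewed on the ratio
scale.

## Decision curves

Net benefit at threshold p_t is (TP − FP·p_t/(1−p_t))/n with treated =
predicted risk ≥ p_t and the event probability among the treated
estimated by their mean pseudo-value (competing-risks-consistent, unlike
a naive Kaplan-Meier complement). Comparators are treat-all
(NB = F̂ − (1−F̂)p_t/(1−p_t), crossing 0 at the prevalence) and treat-none
(NB ≡ 0). The default grid is 0.5% steps over (0, 0.5] with the 10%
threshold highlighted in outputs; the curve report includes, per model
variant, the lowest grid threshold from which the model dominates both
comparators for the rest of the grid. CVD risks for the
cross-classification are exogenous inputs.

## Multiple imputation

Missingness is expected only in cholesterol, ethnicity, deprivation,
smoking and alcohol; absent diagnosis/prescription flags mean absence and
are never imputed. The chained-equations engine (10 cycles by default;
m = 10 copies) imputes continuous variables by stochastic linear
regression with Bayesian parameter draws (σ² from its scaled inverse-χ²,
β | σ² normal; predictive-mean matching available per variable, e.g. for
cholesterol to avoid implausible negatives) and categorical variables by
ridge-stabilised multinomial logistic draws. Every imputation model
includes the other predictors plus the Nelson-Aalen cumulative
cause-specific hazards for both events evaluated at the subject's own
follow-up time and the two event indicators. Scalar estimates pool by
Rubin's rules (T = W + (1+1/m)B, df = (m−1)(1 + W/((1+1/m)B))²);
quantities without an approximately normal posterior are summarised by
median and IQR. Performance metrics pool on transformed scales (log O:E,
logit C, raw D), matching the meta-analysis scales.

## The synthetic cohort generator

The generator emulates a large primary-care cohort of patients with an
indication for antihypertensive treatment; its defaults are the reference
study conditions for all tests.

* **Structure.** Patients cluster in practices with log-normal size
  dispersion (σ = 0.8 on the log scale); a normal practice effect
  (SD 0.10) on the linear predictor provides modest real clustering.
* **Predictors.** Age ~ Normal(58, 14.5) truncated at 40 (mean ≈ 59–60,
  SD ≈ 13); 52% women; SBP ~ Normal(143.5, 11.9) confined to 130–179
  mm Hg (the eligibility window); cholesterol ~ Normal(5.3, 1.1) mmol/L;
  frailty ~ Beta(0.9, 16) (right-skewed, median ≈ 0.03); categorical
  margins and binary-flag prevalences (previous falls 6%, ACE inhibitors
  12%, opioids 31%, ...) set to the development-cohort descriptive table.
  Predictors are drawn independently given practice; the generator
  documents this choice rather than claiming fidelity to any real
  database, whose joint dependence is unpublished.
* **Event process.** Indirect subdistribution simulation: cause 1 with
  probability 1 − (1−p)^exp(η), event time from the conditional
  subdistribution of F1(t|x) = 1 − (1 − p(1 − e^(−ρt)))^exp(η) with
  ρ = 0.25/year; cause-2 times exponential with a log-linear age effect
  (0.9 per SD of age). Defaults p = 0.017855 and baseline death rate
  0.008773/year were obtained by numerically inverting the marginal
  10-year incidences to 3.5% (falls) and 10% (deaths) over a fixed-seed
  probe of the covariate distribution; the default true log-SHRs mirror
  the published effect directions (women +0.22, previous falls +0.28,
  heavy drinking +0.45, ... with age the dominant predictor at 1.0/SD).
* **Censoring.** Exponential dropout at rate 0.09/year plus an
  administrative cut at 10 years, giving a median follow-up of ≈ 6.5
  years (IQR ≈ 2.4–10).
* **Missingness.** MAR: the missingness logit depends on observed age
  (+0.4/SD) and sex (+0.3 for women), with the intercept solved by
  bisection so realised marginal rates match the configured ones
  (cholesterol 48%, ethnicity 55%, smoking 5%, alcohol 15%). MAR rather
  than MCAR so that imputation is non-trivially testable.
* **Eligibility filter.** Age ≥ 40, at least one systolic reading in
  130–179 mm Hg, no reading above 180; entry at the first qualifying
  reading, index date 12 months later. The filter is idempotent and
  order-independent.

**Parameter-recovery configuration.** The Table-1-like defaults produce
~500 falls at n = 20 000 — far too few to pin log-SHRs to ±0.05. Recovery
studies therefore use a dedicated event-rich configuration
(`parameter_recovery_config`): four well-dispersed covariates, cause-1
mass calibrated to a 35% 10-year incidence, ~10% competing deaths, light
dropout (~23% censored before the horizon) and no practice effect. Both
configurations were fixed before the recovery experiments and are not
tuned per run.

**What the simulations do not show.** The generator draws from the same
model family the estimator assumes, so recovery and calibration results
demonstrate internal correctness, not robustness to model misspecification,
informative censoring, measurement error, or the unknown real-world
dependence among predictors. Scale is also reduced (tens of thousands of
patients, ~100 practices) relative to the millions of patients and
hundreds of practices of the motivating setting, so simulation SEs are
correspondingly larger.

## Problem sizes used in the shipped studies

Parameter recovery and calibration repair run at n = 20 000 patients;
generator-marginal checks at n = 50 000; oracle equivalences on 100
random instances of n ≤ 80; meta-analysis recovery on 200 practices × 30
replicates. These sizes give Monte-Carlo SEs comfortably inside the
asserted tolerances while keeping the full suite to a few minutes.

## Numerical choices

* Newton tolerance 10⁻⁹ on the score norm with a float64-plateau stop;
  step-halving (up to 40 halvings) guards ascent.
* η = x'β clipped at ±200 inside exp() for overflow safety only.
* Estimating-equation fits use `scipy.optimize.least_squares`
  (Levenberg-Marquardt) with 10⁻¹² tolerances; failure to reduce the
  score below 10⁻⁴ of the response scale raises.
* REML uses bounded scalar minimisation (xatol 10⁻¹²) with an explicit
  τ² = 0 boundary check.
* Rounding of reported percentages is half-up at one decimal, matching
  printed-table convention.
* Ties: stable sorts throughout; quantile grouping breaks LP ties by
  input order; concordance handles tied predictions by ½-credit and tied
  pseudo-values by pair exclusion.

## Known limitations

* No time-varying covariates or treatment changes during follow-up; the
  model predicts from a single moment under current-care assumptions.
* No multilevel imputation by practice; no imputation of outcomes.
* The pseudo-value concordance definition (see above) is one of several
  defensible readings of "C applied to pseudo-values"; it is documented
  and oracle-locked rather than claimed identical to any other software.
* The smooth calibration band is a binned-SE approximation, not a full
  bootstrap band.
* No cause-2 prediction model beyond what the censoring weights require.
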