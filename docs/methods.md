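# Methods

This note documents the statistical model behind `ineqshift`, the design of
the synthetic cohort that serves as its test bed, the numerical choices, and
the limits of what the tests demonstrate.

## Estimands and identification

The outcome Y is gestational age in weeks at the first antenatal visit; the
exposure A is early pregnancy recognition, defined as recognition within 6
weeks of the first day of the last menstrual period (boundary inclusive; a
companion dichotomisation flags initiation within 14 weeks, also inclusive —
both cut-offs are configurable). Thirteen categorical predictors L span
individual factors (age group, migration background, relationship status,
pregnancy intention, mental illness, language skills, parity) and
socio-economic ones (education, employment, household income, housing,
neighbourhood deprivation, cognitive functioning).

Three quantities are reported per predictor level:

1. **Inequality without intervention** — the OLS contrast of Y on the
   predictor's level indicators. These are deliberately *unadjusted*
   one-predictor-at-a-time associations: the design asks how large each gap
   is, not which causal path produces it, and explicitly avoids
   mediation-style decomposition. (A config switch fits mutually adjusted
   variants.) The reference level is the level with the earliest mean
   initiation, so inequalities are non-negative; it is chosen once on the
   observed data and frozen for the counterfactual scenario, with ties
   broken by the level dictionary's order and empty levels excluded with a
   warning.
2. **Inequality with intervention** — the same regression run on
   counterfactual outcomes under do(A = 1).
3. **Reduction** — with minus without.

Counterfactuals use the adjusted linear exposure model
Y = β_A·A + γᵀL + ε. Under this main-effects model, prediction-based
g-computation and the residual-preserving shift
Y* = Y + β̂_A(1 − A) coincide, and the shift keeps "with-intervention"
regressions well defined row-wise; the shift is therefore the default, with
the prediction-based variant available (`analysis.counterfactual: predict`)
for models with exposure–covariate interactions. Two exact identities follow
and are enforced in tests: consistency (Y* = Y whenever A = 1) and the
closed form reduction_ℓ = β̂_A(Ā_ref − Ā_ℓ).

Identification rests on exchangeability (no unmeasured confounding given
the thirteen predictors), positivity (every covariate stratum can be
exposed — diagnosed by the minimum fitted propensity from a logistic model
of A on all predictors, computed on complete cases of the non-imputed data,
with a configurable warning floor of 0.01), and consistency of the
intervention (most plausible for people with a regular 28 ± 4-day cycle,
hence the sensitivity rerun on that subset).

An exhaustive-standardisation oracle (substituting, for every unexposed
row, the observed mean outcome of exposed rows in the same covariate
stratum) provides an independent check: on small tables where the outcome
model is saturated in stratum × exposure, g-computation must agree with it
to numerical precision, and the test suite verifies this on hundreds of
randomised tables.

## Missing data

Chained-equation multiple imputation:

* visit order ascending by missing fraction, ties alphabetical;
* continuous variables by predictive mean matching, type-1 matching with
  k = 5 donors (the conventional default), Bayesian draws of the regression
  parameters (χ² draw for σ², normal draw for β with a 1e-8 ridge on X'X
  for near-collinear indicator sets);
* categorical/binary variables by multinomial-logistic
  posterior-predictive draws (unpenalised scikit-learn fits; any fit
  failure falls back to a logged marginal draw);
* three auxiliaries (BMI at intake, gestational age at intake, 5-minute
  Apgar) enter every conditional model but no analysis model;
* the exposure flag is *passively* imputed — recomputed as
  1{recognition ≤ 6} after every update of recognition timing — so the
  definitional invariant holds in every completed dataset (imputing the
  flag directly could contradict the imputed timing);
* initial fill by random draws from each variable's observed marginal;
  m independent chains seeded from one seed.

Estimates are pooled by Rubin's rules (total variance
W + (1 + 1/m)B; t-interval with classical large-sample degrees of freedom,
or Barnard–Rubin when a complete-data df is supplied). The reference
configuration is m = 50 imputations with 100 iterations; the analysis
drivers, tests and the acceptance script use m = 5–10 with 2–10 iterations,
sizes chosen so the full pipeline runs in minutes on one core. With a single
incomplete variable the chain's conditional distribution is available after
one sweep, so few iterations suffice there by construction.

## Uncertainty

Percentile bootstrap, B = 1000 by default (B = 200 in the drivers and
acceptance run). Ordering: imputation happens once; each replicate draws one
row resample of size n and applies it identically across all m completed
datasets, runs the full estimator on each, and pools within the replicate;
intervals are (α/2, 1 − α/2) linear-interpolation quantiles over the B
pooled replicates, and point estimates come from the unresampled data.
Resampling after imputation reuses the expensive imputation once and keeps
within-person correlation intact; imputing inside every bootstrap replicate
(m × B chains) is the main alternative and is computationally out of reach
at reference scale. Reduction intervals are computed on the reduction draws
themselves, never by differencing endpoint pairs. Replicates in which a
parameter is inestimable (a level vanished from the resample) are recorded
absent; a parameter with more than 1% absent draws is flagged.

## The synthetic cohort

No participant-level data are distributable, so the generator emulates the
analytical sample's *structure*, calibrated to the published marginals at
n = 4196:

* **Predictors** are drawn independently with the published marginal
  prevalences (the joint distribution was never published; independence is
  the documented copula choice). Parity marginals were also not published:
  0.56/0.30/0.09/0.05 with 1.1% missingness are package choices typical of
  an urban birth cohort.
* **Exposure**: logistic model on education, income, age group and
  pregnancy intention — the strongest published gradients — with modest
  logit coefficients (−0.10 to −0.45) and an intercept solved exactly so
  the marginal prevalence is 0.817. Stratum propensities span roughly
  0.59–0.88: confounded enough that adjustment matters, far from the 0/1
  boundaries (positivity by construction).
* **Recognition timing**: Uniform[2, 6] weeks among early recognisers; 6 +
  Gamma (clipped at 30) among late ones, with the late mean placed so the
  overall mean is 5.4 weeks. With 81.7% early and early support [2, 6],
  the implied overall SD is ≈ 3.5 weeks — the published 2.3 cannot be
  reproduced jointly with the mean under this mixture, and the mean is the
  calibrated moment.
* **Outcome**: linear in all predictor indicators (coefficients follow the
  published per-predictor contrasts) plus β_A = −0.6 weeks for early
  recognition and Gaussian noise; intercept and noise SD are solved exactly
  so the untruncated outcome has mean 12.9 and SD 3.7 weeks. Outcomes are
  clipped below at 4 weeks (a first visit earlier is biologically
  implausible; ~0.7% of draws are affected, so moment calibration is
  checked against the untruncated model).
* **Missingness**: init_weeks is never missing (the inclusion criterion).
  Predictors are MCAR at their published rates (1.1%–36.2%). Recognition
  timing is MAR at 25.5% with weights driven by education, migration
  background and pregnancy intention (lower education, first-generation
  migration and unplanned pregnancy make the recognition question more
  likely to go unanswered — a recall/reporting pattern), normalised so the
  marginal rate is preserved. Because two of these drivers also drive the
  exposure, complete-case analysis overestimates early-recognition
  prevalence by ≈ 0.8 percentage points (computed by exact enumeration),
  which is the bias the imputation tests must remove.

What the generator does **not** emulate: the cohort's recruitment process,
sibling/geographic clustering, predictor–predictor dependence, and the
right skew of the real initiation-time distribution. The last point matters
for one descriptive quantity: a symmetric outcome with mean 12.9 and SD 3.7
puts only ~61% of first visits within 14 weeks, whereas the real, right-
skewed distribution put 81.4% there. Passing tests therefore demonstrate
the *methods* (calibration of margins, bias removal, interval coverage,
algebraic identities), not distributional fidelity of the outcome's shape.

## Numerical choices and degenerate inputs

* OLS via statsmodels' pseudo-inverse solver (rank-revealing); empty or
  constant indicator columns are dropped with a logged warning and recorded
  in the fit's metadata.
* Exposure-model intercept by Brent root-finding to 1e-12; outcome
  intercept/noise by exact moment enumeration over the joint distribution
  of the exposure drivers.
* Separation in the propensity model is detected up front (a predictor
  level observed with only one exposure value) and raises an error naming
  the covariate; in the orchestrated pipeline a failed diagnostic is
  recorded in the run's diagnostics instead of aborting the analysis. On
  synthetic cohorts at n = 4196 the complete-case subsample is small
  (~300–600 rows), so rare levels separate in a few percent of cohorts —
  an honest feature of complete-case diagnostics.
* Percentile quantiles use the linear-interpolation rule
  h = (n − 1)p + 1; degenerate (constant) draw vectors yield point
  intervals.
* One master seed derives all stage seeds (CRC-based, < 2^31); identical
  configs reproduce every output byte for byte apart from timestamps.
* Human-readable tables round to one decimal; machine outputs keep full
  precision.

## Known limitations

* Single-level data: no clustering by neighbourhood or midwifery practice.
* The inequality regressions are unadjusted by design; reductions therefore
  quantify prevalence-gap closure, not causal decomposition.
* PMM imputation of a continuous variable whose dichotomisation is the
  analysis exposure is mildly uncongenial; at reference scale the pooled
  exposure effect is recovered to well within its sampling error (verified
  over 100 replications), but small systematic attenuation (~0.03 weeks)
  is visible in that experiment.
* Bootstrap-within-imputation treats the imputation model as fixed across
  replicates; intervals ignore imputation-model refitting variability.
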