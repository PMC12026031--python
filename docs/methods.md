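# Methods

This note documents the statistical procedures implemented in
`csfrisk`, the assumptions behind them, and the design choices made
where the underlying conventions are genuinely open.

## Marker classification and the Erlangen Score

Each CSF analyte is judged against an assay-specific decision limit
(`AssayPanel`): Aβ1-42 is pathological when **low**, pTau181 and tTau
when **high**, the Aβ1-42/Aβ1-40 ratio when **low** (cut-off 0.05 for
manual immunoassays, 0.06 for the automated-platform dialect). Because
values near a decision limit are analytically uncertain, a symmetric
borderline band of ±10 % of the cut-off (configurable per panel)
separates three zones: clearly normal (score 0), borderline (1), and
clearly pathological (2, deviation > 10 % past the cut-off).

Two conventions had to be fixed:

* **Band sidedness.** The borderline band is symmetric around the
  cut-off. A one-sided reading (borderline only below the Aβ1-42
  cut-off) cannot produce the observed score patterns in which a
  marker that is *binary-normal* still contributes a borderline point
  (e.g. an amyloid-ratio-positive profile with borderline-normal
  Aβ1-42 reaching the maximum total), nor those in which a
  *binary-pathological* value contributes only one point.
* **Ties.** The binary pathological status is strict (pathological only
  strictly past the cut-off; a value exactly at the cut-off is normal),
  and values exactly at a band edge are borderline. This makes every
  boundary deterministic; it is a choice, since tie behaviour at exact
  cut-off values is not standardized anywhere we know of.

The Erlangen Score adds the Aβ1-42 zone score to the higher of the two
tau zone scores (max rule), then adjusts by the amyloid ratio: +1 if
pathological, −1 if normal, with the result clamped into [0, 4]. An
alternative published phrasing gates the −1 adjustment on the sum being
"less than one"; applied literally it produces totals of −1, so the
add-then-clamp formulation is implemented. Totals above 1 are high
risk. When Aβ1-40 was not measured the unadjusted sum is read on a
three-level scale; the level boundaries (low 0–1, medium 2, high 3–4)
keep "pathological = above one" intact with a single intermediate
level — the exact mapping of the no-ratio scale is not spelled out in
the sources defining the score, so this is a documented choice.

## Youden calibration of the pTau/Aβ1-42 cut-off

Candidate thresholds are midpoints between consecutive distinct pooled
values plus ±∞ sentinels; sensitivity counts cases strictly above the
threshold, specificity controls at or below it. The calibration returns
the candidate maximizing J = sensitivity + specificity − 1, breaking
ties toward higher specificity and then toward the smaller cut-off (a
deterministic policy; Youden's index itself defines none). Calibration
cases are "neurochemically definite AD" profiles — all four markers
clearly (>10 %) pathological — and controls are profiles with all four
markers clearly normal. Calibration is exposed as a separate step so a
cut-off table derived from any larger eligible pool can be supplied
instead. Empirical calibration only; no smoothed or parametric ROC.

## Trajectory mixed model

zMMSE_it = β0 + β1·t + β2'·group_i + β3'·(group_i × t) + u0_i + u1_i·t + e_it,

with (u0, u1) ~ N(0, G) and within-subject residuals e_i ~
N(0, σ²·C(ρ)), C an AR(1) correlation matrix. Estimation is exact
maximum likelihood on the marginal Gaussian likelihood; the fixed
effects are profiled out by generalized least squares and the
covariance parameters are optimized by L-BFGS-B on an unconstrained
scale (log variances, Fisher-z for ρ). Initialization is deterministic
(OLS for β, a between/within split of the OLS residual variance for the
variance components, ρ = 0), so fits are bit-reproducible. Subjects
sharing a visit schedule share one Cholesky factorization per
likelihood evaluation, which keeps a 259-subject fit around 0.2 s.

Choices and conventions:

* **Time unit: years.** Reported slopes are per year of follow-up.
  Fitting in months and rescaling the two time slopes by 12 reproduces
  the fit in years (tested), so the unit is a labelling convention, not
  a modelling one.
* **AR(1) over visit order** (lag = difference in visit rank) is the
  default, matching the repeated-effects convention of the mainstream
  commercial mixed-model implementations; a continuous-time variant
  ρ^|Δt| is available via `LmmSpec(residual_correlation="continuous")`.
* **Diagonal G by default** (no intercept–slope covariance), giving
  four covariance parameters: var(u0), var(u1), ρ, σ². This matches the
  default variance-components structure of the same implementations; a
  free-covariance option (Cholesky-parameterized) exists.
* **Information criteria.** AIC = −2ℓ + 2k, BIC = −2ℓ + k·ln N with
  k = fixed effects + covariance parameters and N = total observation
  count. BIC's N convention varies across software; total observations
  is used consistently here, so criteria are comparable *within* this
  package but not necessarily across packages.
* **Standard errors** come from the GLS information matrix
  (Σ XᵀV⁻¹X)⁻¹ with normal-approximation t and p values; no
  Satterthwaite/Kenward-Roger small-sample correction (groups here have
  ≥ 50 subjects).
* **RMSE.** Marginal RMSE uses fixed-effect predictions; conditional
  RMSE adds empirical-Bayes (BLUP) random intercepts/slopes,
  b_i = G Z_iᵀ V_i⁻¹ (y_i − X_i β̂). Residual AR(1) structure is not
  used for prediction.
* Restricted ML is deliberately not offered (the comparison design uses
  ML so AIC/BIC are comparable across fixed-effect structures), and no
  missing-visit imputation is performed.

## Conversion risk

Follow-up varies between one and thirteen years, so raw scores are
first turned into horizon conversion probabilities via a Cox
proportional hazards model (one covariate, Breslow tie handling,
Breslow baseline cumulative hazard; fitted by scikit-survival with the
information-matrix standard error computed directly):
P(convert by h | x) = 1 − exp(−Λ₀(h)·e^{βx}) with h = 10 years by
default. Whenever β > 0 this transform is strictly increasing in the
score, so the ROC/AUC of the probabilities equals that of the raw
score — the Cox step calibrates probabilities but does not re-rank, and
the AUC comparison is therefore a comparison of the scores themselves.
Covariate coding: the ordinal scores enter as numeric 0–4 (yielding the
characteristic 5-point ROC), the pTau/Aβ1-42 ratio as continuous.
Monotone separation (all events on one side) is flagged on the fit
rather than silently returned.

AUC is the empirical Mann–Whitney statistic with half-credit for ties.
Correlated AUCs on the same subjects are compared with the
structural-components estimator of DeLong et al.:
z = (AUC_A − AUC_B)/√(v_A + v_B − 2c_AB), two-sided normal p; a
near-zero variance of the difference is reported as a degenerate
comparison instead of a z score. Diagnostic 2×2 tables report
sensitivity, specificity, LR±, and the diagnostic odds ratio with a
Woolf logit 95 % CI, applying the Haldane–Anscombe 0.5 correction (and
a flag) when a cell is empty. Competing risks and time-varying
covariates are out of scope.

## Synthetic cohort generator

The generator produces cohorts with the structure the analysis assumes;
its defaults are the study conditions, not tuning knobs.

* **Constellations.** 13 ATN(R) constellations with weights equal to
  the reference cross-tab column totals
  (87, 1, 5, 5, 3, 2, 2, 3, 58, 30, 9, 18, 36 of 259). Analytes are
  drawn log-uniformly inside the requested zone, staying > 10 % clear
  of the cut-off unless a borderline draw (probability
  `borderline_probability`, default 0) places the value inside the
  band — always on the requested binary side, so the generated
  constellation is reproduced by construction. Aβ1-40 is derived from
  the drawn Aβ1-42 and a target ratio on the requested R side.
  Concentration scales (Aβ1-42 cut-off 600 pg/mL, pTau181 60 pg/mL,
  tTau 400 pg/mL, ratio 0.05) are plausible round numbers for the
  synthetic panel; real assay cut-offs are user configuration.
* **Deterministic fixture.** `table1_fixture()` places the exact
  constellation counts at fixed clear values; a variant flag moves one
  R+A−T+N+ subject's Aβ1-42 into the borderline-normal band,
  reproducing the single cross-tab cell that requires a borderline
  score.
* **Trajectories.** Simulated from the mixed model above with default
  truth β = (−1.30, −0.07, −0.40, −0.40) (binary grouping),
  var(u0) = 1.0, var(u1) = 0.02, ρ = 0.3, σ² = 0.25; annual visits at
  0, 1, 2, … years truncated at the follow-up end. Annual scheduling is
  an assumption — real visit spacing is irregular.
* **Follow-up.** A two-component uniform mixture
  0.498·U(1, 3.761) + 0.502·U(1, 13) years, solved in closed form so the
  population median is 3.25 y and the IQR 4.9 y (the two published
  summaries), with support matching the 12–156-month eligibility
  window.
* **Outcomes.** Exponential conversion times with rate
  0.0535·e^{1.1·g} per year (g = 1 for the high-risk group), censored
  at the follow-up end. The baseline rate was solved numerically so the
  expected conversion fraction with a 156/103 group split is ≈ 31 %
  (81 of 259).

What the generator does **not** emulate: assay measurement error and
inter-laboratory variation, correlations between analytes within a
zone, non-exponential hazards, informative censoring, practice effects
in repeated MMSE testing, and the real (irregular) visit process.
Passing recovery tests therefore show that the estimators recover the
parameters of their assumed data-generating process at realistic sizes
and noise levels — not that the models are correctly specified for any
particular clinic's data.

## Verification strategy and problem sizes

The published cohort-level estimates (AUCs, DeLong p values, odds
ratios, information criteria) depend on unavailable patient-level data
and are not reproduction targets. Correctness is instead established
against independent oracles: a brute-force verbal-rule scorer for the
Erlangen Score (10 000 random profiles), exhaustive threshold scans for
the Youden calibration, all-pairs counting for the AUC, direct
enumeration for the DeLong components plus a permutation-null
uniformity check, grid search of the Cox partial likelihood on small
instances, and dense multivariate-normal evaluation of the mixed-model
likelihood on ≤ 10 subjects. Simulation-based checks use 100 replicates
of 259-subject cohorts for fixed-effect recovery (mean interaction
within ±0.05 of truth) and for null coverage (estimates within 2 SE of
zero in ≥ 93/100 replicates); these sizes give Monte-Carlo standard
errors comfortably below the tolerances while keeping the whole suite
at a few minutes on one CPU.

## Known limitations

* The no-ratio three-level mapping and the exact-tie conventions are
  reasoned choices (see above), not published prescriptions.
* BIC's sample-size convention makes cross-software comparisons of
  absolute criterion values unreliable.
* The Cox step assumes proportional hazards across score levels; the
  package does not test that assumption.
* Single-covariate Cox models only; no adjustment for age, sex, or
  education (the MMSE z-scores consumed here are already
  demographically adjusted upstream).
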