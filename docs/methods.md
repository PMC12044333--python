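# Methods

## Free-ligand equilibrium

The equilibrium module solves the two-component 1:1 binding system for a
cytokine (IL-18, 18.4 kDa) and its binding protein (IL-18BP) under the law
of mass action. All concentrations are molar (pmol/l); ELISA mass readings
(pg/ml) can be converted by `mass_to_molar` (pg/ml ÷ kDa = pmol/l). The
dissociation constant defaults to 400 pmol/l (0.4 nM), the literature value
for the IL-18·IL-18BP complex, and is exposed as a parameter so sensitivity
analyses over the plausible Kd range are possible.

Numerics. In serum, IL-18BP is typically 30–100× molar excess over IL-18,
so the textbook root `(-b + sqrt(b² + 4·Kd·T))/2` with `b = BP − T + Kd`
subtracts two nearly equal large numbers. For `b ≥ 0` the algebraically
identical conjugate form `2·Kd·T / (b + sqrt(b² + 4·Kd·T))` is used, which
is cancellation-free; for `b < 0` the original form is already stable. The
full species solve computes free binding protein by the role-symmetric
closed form and the complex from the Kd identity, so both conservation
identities hold to machine precision even when one species nearly vanishes
(computing the complex as `T − free` instead loses ~7 digits when
`T ≫ BP`). An independent bisection solver on the complex concentration
(bracket `[0, min(T, BP)]`, iterated to bracket collapse) serves as a
verification oracle in the tests; agreement with the closed form is checked
at 1e-9 relative tolerance over a randomized grid of 10⁵ points with
T, BP ∈ [0, 10⁴] pmol/l and Kd ∈ [10⁻³, 10⁴] pmol/l.

Zero concentrations are valid boundary inputs; negative or non-finite
inputs raise a validation error naming the offending field rather than
being clamped, since silent clamping could mask assay problems.

## Cutoff selection and group comparisons

The ROC curve enumerates every distinct observed marker value plus a
saturating sentinel as candidate thresholds. Because the exposure of
interest is *low* free IL-18, the default orientation scores a subject
test-positive iff `marker < threshold` — strictly, matching the
`< 6.0` / `≥ 6.0` group convention of the motivating analysis. AUC is the
trapezoid rule over the curve, which equals the midrank Mann–Whitney
statistic divided by `n₁·n₀` (verified as a cross-check identity in the
tests). The Youden-optimal threshold maximizes J = sens + spec − 1; ties
are broken toward the highest sensitivity, then the smallest threshold — a
deterministic rule chosen here because published analyses report a single
cutoff without stating one, and favoring sensitivity means favoring not
missing infections. Thresholds are observed marker values, not midpoints;
under strict `<` any value in the gap below the chosen threshold yields the
identical classification, so recovery experiments score the midpoint of
that gap.

The chi-square test for 2×2 tables is uncorrected Pearson by default with
an optional Yates flag (the SPSS variant behind each published table row is
not knowable). The Mann–Whitney U test uses midranks for ties and the
tie-corrected normal approximation with continuity correction; U counts
pairs with `x > y` (+½ per tie), so a first sample entirely below the
second gives U = 0. Exact enumeration is used as a brute-force oracle in
the tests at small n.

## Survival analysis

Kaplan–Meier estimation follows the standard product-limit conventions:
subjects censored at an event time are counted at risk at that time;
standard errors are Greenwood's. The two-group log-rank test sums
observed-minus-expected events over distinct event times with the
hypergeometric variance (including the `(n−d)/(n−1)` tie factor) and refers
the statistic to chi-square(1).

Cox proportional hazards regression maximizes the Breslow partial
likelihood by Newton–Raphson from a zero coefficient vector with
step-halving (the log-likelihood is concave, so accepted steps never
decrease it). Breslow tie handling is the default because it is the SPSS
Cox default, matching the reporting style this pipeline mirrors; Efron is
available behind `ties="efron"` and is what `lifelines` uses, providing an
independent oracle in the tests. Convergence is declared when
max |score| < 1e-9 or the relative log-likelihood change falls below 1e-10,
within 50 iterations. Confidence intervals and p-values are Wald
(`exp(coef ± z·se)`), again matching the SPSS style. Rank-deficient designs
(constant or linearly dependent columns) raise a collinearity error before
fitting; variance inflation factors from auxiliary least-squares fits are
reported with the pipeline output and flagged above 10. Monotone
likelihoods (perfect separation) are detected by an implausibly large
scaled coefficient (|β|·sd(x) > 11, the heuristic lifelines also uses) and
flagged via `converged_ = False` plus a warning, never silently.

A note on an identity used in testing: the log-rank statistic equals the
Cox score test for a binary covariate under Breslow ties *exactly* only
when event times are untied — with ties, the log-rank hypergeometric
variance carries the `(n−d)/(n−1)` factor the score information lacks. The
identity checks therefore use continuous (tie-free) simulated times, which
is also what the cohort generator produces.

Deaths and non-infection hospitalizations are treated as independent
right-censoring for the infection endpoint. This is an assumption, not a
fact about the data-generating process: with ~14% two-year mortality a
competing-risks analysis (e.g. Fine–Gray) could give different absolute
incidence estimates. Competing risks are out of scope here.

## Synthetic cohort

No patient-level data are publicly available for the incident-dialysis
setting this pipeline targets, so a seeded generator emulates its
structure. Defaults (all overridable in `CohortConfig`):

| parameter | default | rationale |
|---|---|---|
| n_subjects | 295 | study sample size |
| analyte marginals | lognormal, moment-matched | total IL-18 29.9 ± 18.7, IL-18BP 1034.0 ± 468.2 pmol/l; positive, right-skewed |
| rho (log-scale correlation) | 0.35 | places derived free IL-18 at ≈ 8.8 ± 5.3 pmol/l, the reported 8.7 ± 5.3 |
| kd | 400 pmol/l | as above |
| true_cutoff | 6.0 pmol/l | the published prognostic threshold |
| baseline_hazard | 5.2224e-5 /day | solved so expected overall infection incidence = 6.8% over 730 days |
| hazard_ratio_low | 4.0 | ratio implied by the published 14.5% vs 3.8% group incidences |
| dropout_hazard | 2.0e-4 /day | ≈ 13.6% two-year attrition (the cohort's mortality), as independent censoring |
| admin_horizon | 730 days | two-year endpoint window; observed times floored at 1 day |

Event and dropout times are exponential (constant hazards) — the simplest
model consistent with the summary statistics being emulated. The hazard
effect acts through the *derived* free IL-18 (a threshold on the computed
value), not a latent label, so cutoff-recovery experiments genuinely test
the estimator. Covariates (age, eGFR, CRP, albumin, hemoglobin, corrected
calcium, phosphate, intact PTH) are drawn independently of the marker with
normal or lognormal marginals matched to the published baseline table;
right-skewed ones (eGFR, CRP, PTH) are lognormal. Independence reflects
the reported absence of marker–covariate correlation; it also means the
adjusted and unadjusted hazard ratios coincide in expectation, so the
generator exercises but cannot stress-test confounding adjustment.

What the generator does not emulate: the bivariate-lognormal marginals
with rho = 0.35 put ~34% of subjects below 6.0 pmol/l where the study
observed 28% — the published free-IL-18 mean/SD, the analyte marginals and
the low-group fraction cannot all be matched simultaneously under this
family, and the free-IL-18 distribution was prioritized. Also absent:
deaths as a competing risk, dialysis-modality effects, assay measurement
error, and any marker–covariate dependence. Passing tests on these cohorts
demonstrate correctness of the estimators under the stated model, not
robustness to real-data violations of it.

## Validation design

Every estimator has an independent oracle: bisection for the closed-form
solver; brute-force pair counting and scipy for Mann–Whitney; scipy for
chi-square; scikit-learn for AUC; lifelines for Kaplan–Meier, log-rank and
(Efron) Cox; a partial-likelihood grid search for the Breslow Cox; and
normal-equation least squares for the VIFs. Simulation-based checks use
these problem sizes, chosen to keep the default suite fast while leaving
sampling error well below the tolerances tested: Cox parameter recovery
with 100 replicates of n = 5000 at true hazard ratio 8 (mean log-HR within
5%, Wald coverage within [0.90, 0.98]); chi-square type-I calibration with
10⁴ null replicates at n = 295 and event probability 0.3 (chosen a priori
so expected cell counts exceed the usual ≥ 5 validity rule; the study's own
6.8% incidence would put the asymptotic test at the edge of its validity);
and Youden cutoff recovery with 100 replicates of n = 2000 at hazard
ratio 8.

## Pipeline and reporting

`run_pipeline` stages: free IL-18 derivation (skipped when precomputed —
the two paths are verified identical), ROC + cutoff (Youden or fixed),
strict-`<` dichotomization, group comparison table, KM + log-rank, adjusted
Cox. Fewer than one event halts the pipeline after stage 1 with an explicit
diagnostic. The default Cox adjustment set is the full published-model
covariate list (eGFR, CRP, age, albumin, hemoglobin, corrected calcium,
phosphate, intact PTH); the motivating text and its regression table
disagree on whether eGFR, CRP and hemoglobin were included, and the fuller
table list is followed. Missing covariate values are handled by
complete-case exclusion per model with the excluded count reported.
Hazard ratios are stored at full precision (a per-pg/ml PTH effect rounds
to 1.00 at display precision); display rounding (percentages 1 dp, AUC and
HR 2 dp) is applied only in the report's `display` fields. Reports are
deterministic given input and config; the provenance timestamp is the only
non-deterministic field and is excluded from `report_hash`. KM and ROC
curves export as CSV; figure rendering is deliberately out of scope.
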