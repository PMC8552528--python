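# Methods

This note records the models, numerical choices and limitations behind
`gestaflux`. Units: concentrations are pg/mL (CRP µg/mL, carried as
metadata, never converted); all logarithms are natural; gestational age (GA)
is in days with `w+d ≡ 7·w+d`.

## Synthetic study generator

The generator is a generative twin of the analysis assumptions, not a
re-simulation of any particular cohort's data.

**Cohort.** `n_women` participants are split into a term group (cohorts
1–4, 1–4 serum samples between days 45 and 280) and a late-term group
(cohort 5, exactly one sample at day 289 ± 2, discrete uniform). Default
marginal prevalences: 56% late term, 10% smokers, 46% nulliparous, 42%
female fetuses, BMI classes 64/26/10% (normal/overweight/obese, WHO cuts,
left-closed, eligibility restricted to [18.5, 40)). Sample counts for term
women follow probabilities (0.16, 0.28, 0.28, 0.28) for 1–4 visits (so 84%
contribute more than one sample), with trimester placement probabilities
(0.25, 0.49, 0.26). Joint covariate structure beyond these marginals is not
modelled.

**Trajectories.** Each analyte's population log-concentration is a cubic
B-spline on days [40, 290] with four interior knots, parameterized by knot
heights realizing four shapes: monotone increase, monotone decrease,
interior peak, interior dip. Defaults assign the canonical shape per analyte
(eotaxin and most chemokines decrease; G-CSF, IL-13, IL-4, GM-CSF, FGF-b
increase; CRP and IL-7 peak mid-pregnancy; IL-1β and IL-6 dip). Amplitudes
are free parameters (no published scale exists for them); the default is
0.8 log units, with a +0.5 log-unit late-term surge ramping over days
283–293 for every analyte except FGF-b. Subject random intercepts (SD 0.5
log) and residuals (SD 0.4 log) are added on top; covariate effects
(obesity, overweight, smoking, parity, fetal sex, birth-weight percentile
group) enter as log-scale shifts with piecewise trimester profiles, e.g.
parity contributes +0.25 in T1 and −0.25 in T3 on CRP and IL-6.

**Assay forward model.** FI = 5PL(conc)·exp(lot offset + plate offset) +
heteroscedastic noise with var(FI) = θ₀·mean^θ₁. Defaults: 3 lots × 4
plates, lot offsets ~ N(0, 0.2²) log units (reference lot 0), plate offsets
~ N(0, 0.1²), θ = (0.5, 1.4) (≈9% CV at mid-curve FI). Per plate: standards
in duplicate (8 four-fold dilution levels), blanks in duplicate, and a
pooled control in duplicate sharing one true concentration across all
plates. Eight bridge samples per non-reference lot are re-measured in the
reference lot.

**Labor outcomes.** Spontaneous labor follows the subdistribution
F₁(t; x) = 1 − (1 − p(1 − e^{−t/s}))^{exp(xβ)} with p = 0.45 and s = 4.8
days; clinically indicated induction is a competing event with
exponential(25 d) latent time; women reaching their scheduled induction
(uniform on days 8–13 after sampling) first are censored
(randomized-induction arm). Under the defaults this yields ≈39% spontaneous
labor with a mean sampling-to-delivery delay of ≈3.4 days, matching the
design target the generator is calibrated to.

Each sub-generator draws from its own seeded stream, so stages are
individually reproducible and fixed seeds give byte-identical tables.

## Preprocessing

Corrections act on log FI and apply to every well on the affected
lot/plate, standards included. Inter-lot first: per analyte,
`delta = mean log FI(bridge re-assay in reference lot) − mean log FI(bridge
in origin lot)` is added to the origin lot. Intra-lot second: per analyte
and lot, each plate is shifted so its anchor-well mean equals the lot-wide
anchor mean (exactly, to 1e-10; re-application is the identity). Pooled
control wells are the default anchors — they share a true concentration, so
the noiseless correction is exact; the API also accepts explicit anchor
sample ids (e.g. a same-GA cohort subset randomized across plates). With
corrections in this order, bridge-well plate offsets do not cancel exactly;
residual lot-level error is of order plate-SD/√8 and is part of what the
noisy integration tests exercise.

Calibration fits the 5PL by variance-weighted least squares, with θ
estimated by regressing log replicate variance on log replicate mean over
(lot, plate, level) duplicate groups; the small-sample bias of log sample
variances is removed with the digamma correction E[log s²] − log σ² =
ψ(ν/2) − log(ν/2). Weights are iteratively recomputed from the fitted mean
(three passes). LLOD is the concentration whose expected FI is blank mean
+ 3 model SD (zero when blanks sit at the lower asymptote); ULOD sits 3
model SD below the upper asymptote; LLOQ/ULOQ bracket the region where the
model CV of back-calculated concentration, sd(FI)/(|dFI/dx|·x), is ≤ 20%
(evaluated on a 2000-point log grid). The 3·SD and 20% constants are
configurable conventions; the variance model itself is the fixed choice.

Censoring: FI at/above the invertible upper range → conc = ULOD, status
`capped_ulod`. Below-LLOD values are imputed per analyte by a univariate
left-censored lognormal EM using full truncated-normal first and second
moments (plain first-moment substitution does not converge to the MLE);
convergence at |Δµ|+|Δσ| < 1e-6, cap 500 iterations; imputed value =
E[X | X < LLOD], strictly below the limit. EM refuses analytes with ≥80%
censoring or fewer than 3 quantified values. Analytes with more than 25% of
measurements outside [LLOQ, ULOQ] are excluded (strictly more — exactly 25%
is retained). Imputation is univariate for transparency; a compositional
multivariate variant would borrow strength across analytes at the cost of
auditability.

Missing GA at sampling is replaced by the mean observed GA of the same
(cohort, visit) group. The outlier screen is per cohort: PCA of the
autoscaled log panel, robust Mahalanobis distance (MinCovDet) on (PC1,
PC2), flag beyond the χ²(2) 0.999 quantile; flags are advisory and removal
requires an explicit configuration list, mirroring score-plot inspection.
Cohort accounting resolves overlapping exclusion reasons in the priority
order complications > BMI > missing samples and asserts
assessed = included + exclusions + outliers.

Normalization: `rmasca` scheme subtracts the per-analyte overall mean and
divides by the *unweighted mean of per-cohort SDs* (not the pooled SD);
`zscore` is plain standardization, used for the late-term regressions.

## Trajectories

Continuous curves: untransformed concentration ~ penalized cubic regression
spline over GA + cohort fixed effects + participant random intercept. The
P-spline is written in mixed-model form (second-difference penalty; the
linear null space joins the fixed effects, the penalized part becomes iid
random coefficients) and the two variance ratios (smoothness, subject) are
optimized by REML on precomputed cross-products — Nelder–Mead over the two
log-ratios, penalized solves via Cholesky with a 1e-10 ridge. Basis: 10
cubic B-spline functions, knots at GA quantiles (reduced automatically when
distinct GA values are scarce). Pointwise 95% bands use the standard
"Bayesian" covariance σ²C⁻¹ of (fixed, smooth) coefficients; they account
for curve uncertainty, not for smoothing-parameter uncertainty. Curves are
reported at the reference cohort over 100 equispaced points between the 1st
and 99th GA percentiles.

Reliability screen: 50 refits on stratified-by-cohort random 80% participant
subsets; Spearman ρ between each run's curve and the mean-of-runs on the
common grid; unreliable if mean ρ < 0.90; at least 80% of runs must
succeed. A caveat established during validation: under a pure-noise
response the screen flags only ~65–75% of datasets (confirmed with an
independent penalized-GAM implementation), because REML shrinks null fits
toward the linear null space and rank correlations between near-linear
curves saturate at ±1 whenever runs share a spurious trend; the screen's
power is against unstable curve *shapes*, not against absence of signal.

Trimester analysis: log concentration ~ trimester + cohort with participant
random intercept, Wald contrasts against T1, BH correction across the whole
analyte × contrast family. The random-intercept LMM is a fast profiled-REML
solver (one variance ratio, closed-form group algebra, boundary at zero
variance checked explicitly); it is numerically identical to statsmodels
MixedLM (cross-checked in the tests to 1e-8) and exists because the
resampling procedures refit thousands of models. Correlations: Spearman ρ
between log concentrations within each stratum (T1/T2/T3/late term), one
sample per participant per stratum (earliest kept), BH over all pairs
within the stratum, minimum 10 complete samples.

## RM-ASCA+

Step 1: per analyte, value ~ time (categorical T1/T2/T3) [* group] + cohort
with participant random intercept, on the `rmasca`-normalized panel. Step
2: fixed-effect contributions are assembled per design cell (time × group)
by reference-coded prediction differences — time matrix: pred(t, g_ref) −
pred(T1, g_ref); group matrix: pred(t, g) − pred(t, g_ref) — so time +
group matrices equal the full fixed-effect prediction minus intercept and
cohort terms by construction. Cohort never enters the effect matrices.
Columns are then centered with design-cell-count weights, and each
partition matrix is decomposed by SVD after weighting rows by √(cell
count) (unbalanced-data convention); scores are unweighted cell
projections, loadings are orthonormal, and the largest-magnitude loading of
each component is made positive. On a balanced complete design with no
random-effect variance this reproduces classical centered cell-mean ASCA
exactly.

Jackknife: 100 iterations; each draws a fresh 7-fold partition of
participants stratified by group (relative group sizes preserved), drops
one fold (cycling), refits, aligns components to the full-data loadings by
maximal absolute correlation with sign flip, and the 2.5th/97.5th
percentiles of the collected scores and loadings form the bands. At least
80% of iterations must succeed. Reference levels for group analyses follow
the clinical conventions: normal weight, non-smoking, nulliparous, male
fetus, 25th–75th birth-weight percentile, youngest age band.

## Late-term analyses

Term vs late term: two-sided Mann–Whitney U (tie-corrected asymptotic) on
log concentrations, term = sampling GA in [259, 283], late term > 283; the
sensitivity variant first removes women with any delivery within 4 days of
sampling ("within four days" means ≤ 4); BH across analytes.

Fine–Gray: per analyte (univariate, matching the per-analyte hazard-ratio
display), spontaneous labor is the event, clinically indicated induction
(and late-window cesarean) the competing event, randomized induction
without labor is censoring. The subdistribution partial likelihood keeps
prior competing-event subjects in the risk set with Kaplan–Meier
inverse-censoring weights G(s)/G(T_j); Breslow ties; Newton iterations to
gradient norm < 1e-8 with step halving; |β| > 50 is reported as monotone
likelihood. Standard errors are model-based (inverse information): exact
partial-likelihood SEs when no independent censoring is present (weights
all 1 — the regime of the calibration checks), approximate otherwise; a
robust sandwich variance is a known omission.

O-PLS-DA: predictors autoscaled; `n_orth` y-orthogonal components (default
1; the original count is not knowable) are removed by orthogonal
projection, then a single predictive component is extracted; classification
thresholds the predictive score at the cut maximizing training balanced
accuracy; VIP = √p·|w| with ‖w‖=1, so mean VIP² = 1 identically.
Evaluation: one stratified 90/10 split for error/sensitivity/specificity;
permutation test shuffles the outcome, redraws a split, refits (n_perm =
1000 by default) and reports p = (1 + #{perm error ≤ observed})/(n_perm+1),
floored at 1/(n_perm+1). Ties in the discrete holdout error make the null p
conservative (super-uniform), which is the validity direction.

Late-term regressions: per analyte, z-scored log concentration on
standardized age, BMI, parity and birth-weight z-score plus smoking and
fetal sex indicators (references: non-smoking, female); OLS, BH across the
analyte × covariate grid; condition-number warning above 1e4. Birth-weight
z-scores interpolate a sex × GA reference table linearly, clamping GA
outside the table with a warning; the bundled reference is synthetic
(linear growth 22 g/day around 3650 g at day 282, girls −130 g, SD 450 g)
and any population reference table with the same columns can be supplied.

## What the synthetic tests do and do not show

Passing tests demonstrate that each stage implements its stated estimator
correctly (oracle equivalences, parameter recovery, calibration of error
rates) under the generator's assumptions: lognormal analyte distributions,
multiplicative batch structure, correctly specified trajectory shapes and
proportional subdistribution hazards. They do not certify behavior under
model misspecification real serum panels can show — heavy-tailed analytes,
lot-by-analyte interactions beyond multiplicative offsets, informative
censoring, or assay drift within a plate.

## Problem sizes

Default test and acceptance runs use deliberately modest sizes chosen to
exercise every code path at stable Monte-Carlo tolerances: studies of
50–120 women for integration tests, n = 2000 for EM and Fine–Gray recovery,
2000 replicates at n = 200 for type-I calibration, 20-seed sweeps for
coverage and reliability properties, and 100–200 permutations per seed for
the classifier null. The full-scale defaults (50 robustness runs, 100
jackknife iterations, 1000 permutations) remain the configuration defaults.
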