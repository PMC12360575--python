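# Methods

## Problem setting

Risk prediction models for cardiovascular disease (CVD) and type-2
diabetes are usually validated on general populations, yet they are most
often applied to patients who already carry other diagnoses. `pcmrisk`
evaluates risk models *separately* in two baseline subgroups:

* **comorbid** — a mental disorder (depression or anxiety) co-occurring
  with the condition complementary to the prediction task (diabetes when
  predicting CVD; CVD when predicting diabetes);
* **non-comorbid** — everyone else.

The package asks three questions about a unified model trained on the
whole cohort: how well does it discriminate and calibrate in each
subgroup (AUC-ROC, Brier, decision curves); how much of each subgroup's
error is irreducible (Bayes-error bounds); and which variables drive
performance and predictions in each subgroup (single-variable AUC,
permutation importance, Shapley attribution, dual-group effect sizes) —
with particular attention to early-life factors (ELFs), long-horizon
exposures such as breastfeeding or childhood maltreatment.

## Data model

A `FeatureCatalog` declares every raw variable's category (ELF,
sociodemographic, blood assay, physical, lifestyle, psychosocial, family
history, medical history, mental health), type, categorical levels,
laboratory flag, and membership in the task's seven "core" predictors.
All variable subsets (core-7, non-laboratory, ELF) are derived from
these declarations. The default catalog is a synthetic reconstruction of
a UK-Biobank-like panel: 64 raw variables that one-hot encode (full
k-column encoding, no reference level dropped) into 83 feature columns,
8 of them ELFs. Core-7 sets follow the published scores' inputs:
Framingham-style for CVD (age, sex, smoking, systolic blood pressure,
total and HDL cholesterol, hypertension) and a Leicester-style set for
diabetes (age, sex, ethnicity, waist, BMI, hypertension, family
history). The published coefficient tables themselves are *not*
reproduced; external scores plug in through `ScoreSpec`, and a logistic
regression on the core-7 columns (fitted per training fold) serves as a
clearly-labelled stand-in benchmark.

Missing cells (empty strings in CSV input) are masked at load time.
Imputation defaults to iterative chained equations for continuous
variables (scikit-learn's `IterativeImputer`, 5 rounds, values clipped
to the observed range) and the mode for discrete ones; any variable
missing more than 25 % is rejected, mirroring the usual missingness
screen. When a cohort still carries missing values at fit time, the
imputer is fitted on each fold's training rows only, so no test
information leaks into training.

## Synthetic cohorts

Real psycho-cardio-metabolic cohorts are access-restricted, so a
generator produces cohorts with the statistical structure the analyses
assume, with every true effect known. The latent chain: independent
Bernoulli ELFs combine (protective exposures negatively) into an
adversity score; adversity raises depression/anxiety rates; a metabolic
latent factor drives anthropometry and blood assays; the complementary
baseline condition depends on the metabolic factor and mental health;
the outcome is logistic in standardized encoded features with three
special terms — an ELF main effect, an ELF×comorbid interaction, and a
piecewise marker coupling (zero below the HbA1c population mean, linear
above). Labels are then flipped with subgroup-specific noise rates.

Defaults are the study conditions: n = 20,000; outcome prevalence 0.10;
comorbid fraction 0.15; label noise 0.15 (comorbid) vs 0.03
(non-comorbid); ELF main effect 0 with comorbid interaction 2.0 per
adversity unit; marker coupling 0.8 per above-mean SD. Outcome and
complementary-condition intercepts are calibrated by bisection (0.1
percentage-point tolerance, ≤ 60 iterations) so realized prevalence and
comorbid fraction hit their targets by construction; an unreachable
target raises `DegenerateConfig`. The interaction scale was set, as part
of the generator design, at the smallest round value for which the
designed-in subgroup patterns (below) are reliably detectable at
n = 20,000 across seeds; weaker interactions leave the subgroup AUC-gain
ordering inside fold noise.

Designed-in recovery surface — these patterns exist in the generative
process and the pipeline is tested on recovering them: (i) ELFs are
nearly uninformative alone in the non-comorbid subgroup but informative
in the comorbid one; (ii) the comorbid subgroup carries more label
noise, so its Bayes-error bounds are higher; (iii) the marker carries
signal only above its mean, so marker-stratified comparisons show it
predictive only in the high-normal stratum.

What the generator does **not** emulate: realistic marginal
distributions or correlations of any real biobank, informative
missingness, time-to-event structure, and measurement error beyond
label flips. Passing recovery tests therefore shows the *pipeline*
recovers structure it is designed to detect — not that the same effects
exist in real cohorts.

## Risk models

The unified model is an XGBoost classifier (`tree_method="hist"`,
single-threaded for determinism) trained on each fold of a stratified
5-fold split; comorbid/non-comorbid membership is never a training
input and only used at evaluation. Hyperparameters come from a seeded
random search (depth 2–8, learning rate 0.01–0.3 log-uniform, 50–500
trees, subsample 0.5–1.0) scored by AUC on an inner 20 % split of the
training fold; trial 0 is a fixed default configuration (depth 4, rate
0.1, 150 trees, subsample 0.9), so a budget of one trial — the default
used by the test suite and the shipped analyses, chosen to keep full
runs cheap — fits that configuration directly. All seeds derive from
one master seed by a fixed integer hash.

## Evaluation

AUC-ROC uses the rank (Mann–Whitney) form with midranks; Brier is the
mean squared error of the predicted probability on raw (uncalibrated)
model outputs. Per-subgroup metrics are computed on each fold's test
rows restricted to the subgroup and reported as mean ± sd over folds; a
fold whose test subgroup has under two samples or one class is skipped
with a warning. Net benefit at threshold t is
`b(t) = TP/n − (FP/n)·t/(1−t)` with a positive call iff probability
strictly exceeds t; decision curves default to 99 thresholds
0.01…0.99, evaluated on the comorbid subgroup, with the closed-form
'all' reference `π − (1−π)·t/(1−t)` and the 'none' reference at zero.

## Bayes-error bounds

Three classical estimators, each per subgroup and per variable set
(core-7 and all variables):

* **Mahalanobis** (upper bound only): `E_up = 2p₁p₂/(1 + p₁p₂Δ)` with Δ
  the squared Mahalanobis distance between class means under the pooled
  covariance.
* **Bhattacharyya** (Gaussian class models): with
  `B = ⅛ dᵀΣ̄⁻¹d + ½ ln(|Σ̄|/√(|Σ₁||Σ₂|))`, `ρ = e^{−B}`:
  `E_up = √(p₁p₂)ρ`, `E_low = ½(1 − √(1 − 4p₁p₂ρ²))`.
* **k-NN**: the 5-fold cross-validated 5-nearest-neighbour error ε̂
  (features standardized with training-fold statistics, Euclidean
  metric) gives `E_up = ε̂` and, via the two-class Cover–Hart
  inversion, `E_low = ½(1 − √(1 − 2ε̂))`, with ε̂ clipped to [0, ½].
  The Cover–Hart asymptotic pair was chosen over k-specific
  (Devijver–Kittler) corrections; the inversion is isolated in one
  function and swappable.

Covariance singularity is detected by a condition-number threshold of
10¹² and reported as a status, not an exception: full one-hot blocks
make class covariances rank-deficient by construction, so the
parametric estimators are expectedly unavailable on all-variable sets
(a constant baseline-flag column has the same effect). Non-overlap of
the two subgroups' k-NN intervals is flagged per variable set.

## Driver analyses

*Performance drivers.* Single-variable models fit one small booster per
raw variable. Permutation importance is `loss(shuffled) − loss(original)`
(so informative features score positive; the sign convention is chosen
so the score agrees with the verbal definition "increase in error"),
averaged over 10 shuffles per test fold, with one-hot blocks shuffled
jointly; the loss defaults to instance-decomposable log-loss with
1−AUC selectable. A Spearman screen reports fully correlated pairs
(|ρ| = 1) as a warning — correlated features split PFI credit — but
never drops anything automatically.

*Prediction drivers.* Shapley attributions are computed on the margin
(log-odds) scale under the tree-conditional value function: a coalition
evaluates a tree by following splits on in-coalition features and
cover-weighting both children otherwise. Two backends: `exact` — own
float64 per-tree coalition enumeration (valid because out-of-tree
features are null players and Shapley values add across trees),
practical when individual trees use ≤ 16 distinct features, and exact to
~1e-12 against full 2^|F| enumeration; `fast` — xgboost's built-in
path-dependent TreeSHAP, used at pipeline scale, float32 and known to
deviate from the exact conditional value when a feature repeats along a
root-leaf path. Importance `I_j` is the mean |φ| per raw variable
(encoded columns summed per instance before the absolute value). The
dual-group effect size takes out-of-fold risks, forms high (`p > t`) and
low (`p ≤ 1−t`) groups at t = 0.5, and reports each feature's Cohen's D
with (n−1)-weighted pooled variance; zero pooled variance yields
"undefined" (NaN), never 0.

## Post-hoc analyses

The marker-stratified comparison splits the cohort at the whole-cohort
mean of a continuous marker (HbA1c by default; values at the mean go to
the high stratum) and compares core-7, marker-only, all-minus-marker and
all-variable models (plus the stand-in benchmark) on comorbid test rows
per stratum. The incremental curve starts from the core-7 + ELF set and
adds raw variables by descending PFI; the plateau is the first step
where three consecutive marginal gains fall below ε = 0.002 (an invented,
configurable rule reported alongside the raw curve). ELF contribution
shares are `100·Σ(ELF scores)/Σ(all scores)` per variant and metric,
with negative PFI clipped to zero before summation so shares stay in
[0, 100]; gains are reported against the all-variables baseline in
percentage points and percent. Of the three metrics, the SHAP-based
share is the most stable under this clipping rule and is the one the
recovery checks assert on.

## Numerical choices and edge cases

* Split thresholds live in float32 inside xgboost; the float64
  re-implementation quantizes inputs and thresholds through float32 so
  routing agrees with the booster exactly.
* Log-loss probabilities are clipped at 1e-12.
* Ties at a decision threshold count as negative calls.
* Prediction-risk ties at exactly t (risk grouping): high requires
  strict `>`.
* Stratification means are computed on the whole cohort, not per fold.
* The default tuning budget of 1 (fixed configuration) is used for all
  shipped analyses and tests; the search space above is exercised when a
  larger budget is requested.

## Known limitations

* The exact attribution backend is exponential in the number of
  distinct features per tree; deep trees require the fast backend.
* Bhattacharyya bounds assume Gaussian class-conditionals; on binary/
  one-hot data they are at best heuristic (and usually unavailable due
  to singular covariance).
* The stand-in benchmark is a synthetic placeholder for published
  scores, suitable for exercising the comparison machinery only.
* Accuracy-style thresholded metrics are deliberately not reported;
  the evaluation centres on AUC-ROC, Brier and net benefit.
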