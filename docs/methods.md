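# Methods

## The model

BMI is regressed on a standardized lipidome plus age and sex with a
penalized linear model. The estimator minimizes, in the glmnet-style 1/(2n)
convention,

    (1/2n) Σᵢ (yᵢ − β₀ − xᵢᵀβ)²  +  λ [ α‖β_P‖₁ + (1−α)/2 ‖β_P‖₂² ]

where the penalty set `P` contains the lipid features only: the intercept
and the declared covariates (age, sex) are unpenalized, so they are never
shrunk away even in the extreme-LASSO limit. A `shrink_covariates` switch
moves the covariates into `P` (internally z-scored); with it the model
collapses to the intercept alone at large λ, which is the limit in which the
metabolic BMI collapses onto measured BMI exactly (see below).

Unpenalized covariates are handled by exact profiling: for any fixed
penalized β the optimal unpenalized coefficients are an OLS solve, so the
penalized sub-problem is the same objective on covariate-residualized data
(Frisch–Waugh). Ridge solutions over the whole λ grid come from one SVD of
the residualized design; LASSO/elastic-net solutions from scikit-learn's
coordinate-descent path on the identical sub-problem. Correctness of the
LASSO solution is certified in the tests by its KKT subgradient conditions,
not by a second library fit.

The response is standardized to unit SD inside the estimator and
coefficients are returned in kg/m². This puts λ on the scale where the
120-point grid log₁₀λ ∈ [−4, 0.2] spans everything from effectively
unpenalized fits to the all-null LASSO model; no exact numeric
correspondence to any other implementation's λ is claimed. On the bundled
synthetic cohorts — where the lipidome's BMI information is concentrated in
one latent direction — the inner-CV MSE decreases out to the top of this
grid, so the "optimal" ridge λ sits at the grid edge; predictive R²
(squared Pearson correlation, which is invariant to the uniform shrinkage
this induces) varies by well under 0.05 across the entire grid.

Cross-validation is 10-fold by default: standardization parameters and the
inner-CV λ choice are computed inside each training fold only, and each
sample's pBMI comes from the one model that never saw it. The full-data
model used for external cohorts refits at the mean of the per-fold optimal
λs and serializes its coefficients, feature-scaling parameters, and
reference line as a single JSON record; applying it never refits anything.

## The score

The reference line is the OLS fit of pBMI (response) on BMI (regressor).
Then

    mBMI  = BMI + (pBMI − (a + b·BMI)),    mBMIΔ = mBMI − BMI.

This orientation is deliberate: it makes mBMIΔ an OLS residual, hence
exactly mean-zero and uncorrelated with BMI on the score-defining cohort —
the property every downstream "independent of BMI" claim rests on. The
reverse regression would not have it. On external cohorts scored with a
frozen line neither identity is promised. mBMIΔ is defined as mBMI − BMI
(positive = lipidome looks heavier than the person is), which is the sign
convention all downstream analyses use.

Quintiles are a rank-based partition with stable tie-breaking. When n is
not divisible by 5 the extra members are assigned outermost-first
(Q1, Q5, Q2, Q4, then Q3), so the deficit sits in the middle; 10,339 samples
split 2068/2068/2067/2068/2068.

In the full-shrinkage limit pBMI is constant, the line has slope 0, mBMIΔ is
identically 0 and mBMI = BMI, so R²(mBMI, BMI) = 1 exactly. The λ-sweep
reports this case through its closed form because the sample-correlation
formula is undefined at a constant predictor (and a naive evaluation is
ill-conditioned one ulp away from it).

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes, not
any real cohort's values:

- **Lipidome.** 575 species in 33 classes on log10 scale: species baseline
  ~N(1.0, 0.6); a within-class shared factor (SD 0.07); species noise
  (SD 0.12); multiplicative technical noise with CV 10% (log-normal, the
  closed form CV = √(exp σ² − 1) is used so the QC %CV checks are exact);
  per-batch median shifts (SD 0.03 log10) at one batch per ~485 samples,
  with pooled-plasma (PQC) and reference-material (NIST) replicate rows.
- **Latent structure.** Adiposity A ~ N(0,1) and dysregulation M ~ N(0,1)
  are independent. Species load on S = A + κM with κ = 0.6 and signed,
  class-structured loadings |N(0.12, 0.04)| (glycerolipids/ceramides
  positive, lyso- and ether-phospholipids negative). Because M loads
  *proportionally* on the adiposity direction, the two factors are not
  separable from the lipidome: the best lipid predictor of BMI is attenuated
  by 1/(1+κ²) and necessarily drags M along — which is exactly what makes
  mBMIΔ a readout of M.
- **Calibration.** BMI = 26.9 + 4.9·(w_age·age_z + w_sex·sex_z + w_A·A +
  w_e·ε) with age ~ U(25, 80), sex ~ Bernoulli(0.55). Age and sex contribute
  R² = 0.03 together; w_A is solved in closed form so the *population* R² of
  BMI on (lipidome, age, sex) equals `signal_r2`:
  w_A² = (signal_r2 − 0.03)(1 + κ²). Configurations where this exceeds the
  available variance are rejected by name.
- **Outcomes and traits.** Prevalent outcomes are logistic draws with
  log-odds `delta_effect`·M (+ a BMI term); incident outcomes are
  exponential event times truncated at the follow-up horizon (5 y for
  diabetes, 10 y for cardiovascular events). `delta_effect` defaults to 0.5,
  chosen from the variance algebra above so the Q5-vs-Q1 adjusted odds ratio
  lands in the 2–5 range. Cardiometabolic traits are log-normal with
  positive loadings on M and BMI (HDL-C negative); healthy lifestyle
  variables (fruit, fibre, physical activity) load negatively on M.
- **Seeding.** One child stream per component (species, lipids, phenotypes,
  outcomes, qc) from a single master seed: regenerating outcomes never
  perturbs the lipid matrix, and a fixed seed reproduces the cohort
  bit-for-bit.

**What the generator does not emulate** — and what passing tests therefore do
not establish about real data: missing species and imputation, non-linear
lipid–BMI relationships, chromatographic drift within batches, realistic
lipid-class covariance beyond one shared factor per class, population
stratification, and any cohort's actual effect sizes. Published
cohort-specific numbers (explained variance of 60.4%/52.1%, specific odds and
hazard ratios, AIC values) are order-of-magnitude anchors here, not
reproduction targets, since the original cohorts are access-restricted.

## Numerical conventions

- Standardization uses the sample SD (n−1) throughout, including the z-score
  helper; zero-SD species standardize to 0 and are flagged rather than
  dropped, keeping feature indices aligned across cohorts.
- Batch correction is multiplicative on the concentration scale (ratio of
  the global PQC median to the batch PQC median, applied to every sample in
  the batch); after the log10 transform it is an additive offset. It is
  idempotent and errors on batches without PQC rows or non-positive medians.
- R² is the squared Pearson correlation (sign-invariant, shrinkage-
  invariant); 1 − SSE/SST is available as an option.
- Association effects on lipids are per-unit slopes on log10 concentration;
  percent difference = (10^β − 1)·100. Fold differences for traits use
  natural-log modelling with exp back-transform. All CIs are Wald-type.
- BH correction is applied within one association family (one scan of the
  species panel), not across families.
- Cox models use age as the time scale with delayed entry at baseline age
  and Efron tie handling. Incident analyses exclude prevalent cases at
  baseline; the exclusion count is logged in the run manifest.
- AIC in the nested comparison uses k = number of parameters as specified
  (so an exactly collinear added term costs exactly 2); fits go through
  IRLS, which tolerates the collinear edge case.
- LASSO active sets are not theoretically monotone along the path; unit-size
  re-entries can occur and the path tests allow them.

## Problem sizes

The test suite exercises the full pipeline at n = 10,000 × 575 species for
the mirroring analysis, n = 5,000 for signal-recovery across generative R² ∈
{0.2, 0.4, 0.6}, 200 repetitions at n = 500 for null calibration of the BH
and LRT procedures, and smaller cohorts (n = 300–3,000, 30–120 species)
elsewhere; these sizes give sampling tolerances comfortably inside the
asserted bounds while keeping a full run to a few minutes on one CPU.
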