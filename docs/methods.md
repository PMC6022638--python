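# Methods

This note documents the statistical machinery, its defaults, the synthetic
data model, and the choices made where more than one reasonable design
existed. Nothing here asserts an empirical result the test suite does not
itself compute.

## The progression axis

All trajectories are functions of the CAG-Age Product, CAP = age × (CAG −
35.5), evaluated per visit with the age at that visit. For numerical
conditioning the models use CAP* = (CAP − M)/S with fixed constants M = 320
and S = 60; these are analysis constants, not re-estimated per sample, so
coefficients from different cohorts are directly comparable. The CAP metric
is undefined at or below the repeat-length offset; `compute_cap` raises
rather than extrapolating.

The "late" progression point, where the instantaneous slope of a fitted
polynomial is reported, defaults to the empirical 0.95 quantile of the
per-observation CAP values (linear interpolation between order statistics —
any consistent quantile rule would do; this one is documented and tested
against a sort-based oracle). It can be fixed to the canonical value 420
via `RunConfig(late_cap_rule="fixed")`.

## The mixed model and its estimation

For outcomes v = 1..V (V ≤ 3) with standardized scores Z_ij(v),

Z_ij(v) = α(v) + a_i(v) + Σ_k β_k(v) CAP*^k + γ(v)ᵀ x_i + e_ij(v),

where the a_i = (a_i(1),…,a_i(V)) are joint zero-mean normal with
unstructured covariance **D** and the residuals are independent, mean-zero
normal with per-outcome variance σ²(v). All cross-outcome dependence is
carried by D: cross-outcome residual correlation is fixed at zero, matching
the model statement that only the random effects correlate (within one
outcome, intercept and residual are independent). No random slopes and no
serial residual correlation are modelled.

Estimation is REML. Fixed effects are profiled out by generalized least
squares, and −2·restricted-log-likelihood

Σ_i log|V_i| + log|Σ_i X_iᵀV_i⁻¹X_i| + Σ_i r_iᵀV_i⁻¹r_i + (n−p)·log 2π

is minimized over the variance parameters, with V_i = Z_i D Z_iᵀ + R_i the
per-participant block. Implementation details that matter:

- **Parameterization.** D is optimized through the log-Cholesky factor
  (diagonal on the log scale, off-diagonals free) and residual variances on
  the log scale — unconstrained, positive-semidefinite by construction.
  Parameters are box-bounded at ±20 only so the exponentials stay finite.
- **Gradient.** Analytic: d(−2ℓ_R)/dθ = tr(P V̇) − rᵀV⁻¹V̇V⁻¹r, evaluated
  blockwise. Verified against finite differences in the tests.
- **Pattern grouping.** V_i depends only on a participant's pattern of
  observed (visit, outcome) pairs, not on their covariates, so participants
  are grouped by pattern and each pattern's covariance is factorized once
  per objective evaluation. This is what makes the Monte-Carlo suites
  affordable on one CPU.
- **Starts and restarts.** One moment-based start (each outcome's marginal
  variance split evenly between intercept and residual variance); dispersed
  restarts only if the first attempt fails the gradient criterion, keeping
  the best criterion value found. Convergence requires a max-gradient below
  1e-3 (or projected-gradient termination at an active bound with a sane
  norm); anything else is flagged `converged=False`, and the testing layer
  refuses unflagged use. Refitting a related model (the degree hierarchy,
  bootstrap resamples) warm-starts from the previous variance estimates.
- **Missing data.** Rows with a missing outcome value are simply omitted
  from that outcome's block; REML is unbiased when the missingness
  mechanism is ignorable, which the synthetic generator respects by
  construction.
- **Degenerate inputs.** Noise-free (exactly polynomial) data put the REML
  optimum on the boundary; fixed effects remain exact (GLS is exact for any
  positive-definite weight when the data lie in the design's span) but such
  fits are honestly flagged non-converged.

Wald tests use z = estimate/SE against the standard normal, with no
degrees-of-freedom correction — adequate at the ~100-participant scale the
package targets, and the null simulations in the acceptance suite confirm
the 5% level within binomial bounds at that scale.

REML criteria are not compared across different fixed-effects sets, so no
likelihood-ordering claim is made (or tested) between the linear, quadratic
and cubic fits; each polynomial degree is a separately fitted model whose
top coefficient carries its test.

## Three-step testing and FDR

Step 1 fits the univariate linear, quadratic and cubic models for X and
uses raw P-values at α = 0.05 (X is the only structural candidate, so there
is nothing to correct over). Condition 1 = negative significant linear term
AND non-significant quadratic and cubic terms. Failure halts the pipeline
with an explicit verdict. On success X is fixed to degree 1 everywhere.

Step 2 fits bivariate MLMMs (X linear + Y at degree 1, 2, 3). The
Benjamini–Hochberg step-up is applied within the group of Y variables,
separately per polynomial term (the group's eight quadratic p-values are
adjusted together, and so on) — matching a results table whose star columns
are per-term. Y survives iff its quadratic term is negative with q < 0.05;
only the quadratic significance is enforced, and survivors carry degree 2
forward. Non-survivors never reach step 3.

Step 3 fits trivariate MLMMs (X linear, Y quadratic, C at degree 1, 2, 3),
adjusting within the group of C variables that share the Y, per term.

Classification per (X, Y, C): a significant cubic C term takes precedence
(the delayed reading): negative cubic and negative late slope ⇒
`cubic_with_negative_late_slope` (overall partial compensation when
conditions 1–2 hold); any other significant cubic ⇒ `inconsistent`.
Otherwise a significant negative quadratic ⇒ `quadratic_concave_down`
(overall compensation); otherwise `none`. Tests are two-sided with the sign
checked afterwards. The Y-vs-C late-slope comparison is recorded but never
tested — the acceleration difference is deliberately not a condition, as
its test would be severely underpowered relative to the coefficient tests.

## Trajectories and bootstrap bands

Fitted curves evaluate the fixed effects at a population-averaged dummy
profile (each dummy at its sample mean), giving one cohort-level curve.
Bands resample participants with replacement — the participant, not the
observation, is the exchangeable unit under repeated measures — refit, and
take pointwise percentile intervals; the default is 1000 resamples at 95%.
Resampled duplicates are treated as distinct clusters. Non-converged
resamples are redrawn and counted; above 20% failures the procedure aborts.
Percentile bands at a few hundred resamples under-cover mildly (the
acceptance suite measures ≈0.93 at n=200 participants and 200 resamples,
within 3 Monte-Carlo SEs of nominal); raise `n_boot` for production
figures. Which model the bands bootstrap is the caller's choice; the
pipeline's convention is the trivariate fit.

## The synthetic cohort

The generator emulates a four-site premanifest cohort: 110 carriers by
default with a 89/15/6 mix of three/two/one annual visits, baseline age ~
U(30, 55) and integer CAG ~ U(40, 46) drawn independently (entry-age spread
is what lets between-participant information identify the trajectories),
sex ≈ 1:1, education 30/40/30 over three ISCED levels, uniform sites. This
yields baseline CAP ≈ 340 ± 100 — a slightly wider spread than the M = 320,
S = 60 of the cohort those constants come from, which only helps
identification and leaves the analysis constants untouched. Outcomes follow
the cubic MLMM equation generatively, with scenario presets encoding the
coefficient-sign templates: full compensation (X linear −1.0; Y −0.5 CAP*
−0.3 CAP*²; C −0.3 CAP*²), delayed compensation (C −0.25 CAP*³), linear-only
decline, flat null, and a positive-cubic anti-pattern (C +0.25 CAP*³, whose
positive late slope must be flagged inconsistent). Default random-intercept
variance 0.25 with pairwise correlation 0.5 and residual SD 0.5 were chosen
once as plausible for standardized longitudinal measures (no empirical
variance components were available to copy); effect sizes are "strong" so
classification power, not effect detectability, is what the simulations
measure.

Dropout is monotone: each post-baseline visit is missed with a logistic
hazard in observed covariates (site, standardized baseline age), after
which all later visits are missed. Both covariate coefficients default to
zero — the simplest ignorable mechanism, and the one with a closed-form
geometric retention expectation used as a test oracle; passing nonzero
coefficients gives covariate-dependent MAR. A site-by-visit availability
mask reproduces per-variable missingness such as task measures acquired at
only two sites at the third visit.

What a green simulation does **not** establish: the generator draws
perfectly normal intercepts and residuals, exact annual spacing,
covariate-independent trajectories and scalar compensators — real cohorts
have heavier tails, practice effects, scanner drift and site-by-variable
confounding the model does not represent. The simulations validate the
machinery (estimator, error calibration, classification logic), not the
biology.

## The disease-load composite

Four TIV-corrected volumes (grey matter, white matter, caudate, putamen),
all visits pooled, are z-scored per column and the first principal
component of their correlation matrix provides the weights — correlation
rather than covariance so no region dominates by scale. The sign is fixed
so the loadings are non-negative (volumes load together on a common atrophy
factor): larger composite = more volume = less disease. Rows with any
missing volume are dropped from the PCA (listwise) and get a missing score;
standardization elsewhere is pairwise. Degenerate (rank-0) input is an
error.

## Known limitations

- Cross-outcome residual correlation is fixed at zero; if real data carry
  visit-level shared shocks across outcomes, D absorbs what it can and the
  rest inflates residuals.
- Wald/normal inference, no small-sample df correction: below ~50
  participants the test is anticonservative; the calibration suite runs at
  n = 100.
- The bivariate/trivariate steps re-estimate X's (and Y's) curves jointly
  with C rather than conditioning on earlier point estimates; this is the
  natural joint-model reading, but a conditioning variant would differ
  slightly.
- Polynomials only — no splines; a cubic's tails are trusted only up to the
  observed CAP range, and curve evaluation outside it warns.
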