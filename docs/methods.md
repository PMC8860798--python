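# Methods

This note documents the models implemented in `twinsem`, the choices made
where the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## The biometric mediation model

Phenotypes are ordered [exposure X, mediators M_1..M_m, outcome Y]. The
path matrix B holds the free structural coefficients of the chosen
variant: forward paths a_j (X→M_j), b_j (M_j→Y), c (X→Y), and reverse
paths a_rev_j (Y→M_j), b_rev_j (M_j→X), c_rev (Y→X). The variant map is

| variant              | free paths                          |
|----------------------|-------------------------------------|
| saturated            | all forward and reverse paths       |
| biDir                | forward paths + c_rev               |
| uniDir               | forward paths only                  |
| uniDir_reversed      | reverse paths only                  |
| uniDir_no_mediation  | c only                              |

Each structural residual carries four variance components. Within-person
residual covariance is `Ψ = Ψ_A + Ψ_C + Ψ_E + Ψ_S`; between two cluster
members the A block is scaled by genetic relatedness r (1 MZ, 0.5 DZ and
full siblings — no dominance or assortative mating), the C block by the
family indicator and the S block by the site indicator. Contralateral ROI
pairs may carry free A/C/E correlations that enter Ψ's off-diagonals as
`r·sqrt(v_i v_j)`. The implied cluster covariance is
`(I−B)⁻¹ Ψ(·) (I−B)⁻ᵀ` per block; `(I−B)` singular (an explosive
reciprocal loop) raises an error naming the feedback.

### Parameterization

Variance components are estimated directly, not as squared loadings, so a
negative shared-environment estimate remains representable (it signals
non-additive genetic variance in twin data). E variances are
log-transformed (they absorb measurement error and must stay positive);
contralateral correlations are atanh-transformed; everything else is
unconstrained. Means are free per phenotype.

### FIML over families and sites

The deviance is the sum over families of the −2 log multivariate-normal
density evaluated on the observed entries only (pattern-wise
marginalization). Families are grouped by (relation pattern, missingness
pattern), so each distinct covariance matrix is factorized once per
evaluation and the per-family quadratic forms are vectorized.

The site factor couples all families within a site. Writing the site-level
covariance as `D + U Λ Uᵀ` — D block-diagonal over families, U a 0/1
selector onto the p phenotype site factors, `Λ = G Ψ_S Gᵀ` — the
determinant and inverse are computed with the matrix-determinant lemma and
Woodbury identity, so the per-site cost is a p×p solve instead of a dense
factorization of the full site block. The implementation is verified to
1e-14 against a dense per-site multivariate-normal oracle in the test
suite.

### Optimization

Quasi-Newton (L-BFGS-B) with finite-difference gradients from a
moment-based start (sample means/variances, OLS path estimates) plus
jittered restarts (default 5; simulations in this repository use 1–3,
which the warm starts make sufficient). Two robustness devices matter:

- **Non-PD continuation.** Where the implied covariance leaves the
  positive-definite cone, the likelihood is continued by clamping the
  spectrum at 1e-6 and adding a squared-negative-eigenvalue barrier
  (weight 1e6). The surface stays continuous across the boundary, so
  finite-difference gradients point back toward feasibility instead of
  hitting a flat penalty cliff (which empirically stalled L-BFGS-B).
  Evaluations in the continuation region are counted and reported.
- **Best-evaluated tracking + polish.** The optimizer's own report can be
  poisoned by a penalty-region line-search step; the fit keeps the best
  point actually evaluated and restarts the optimizer from it until the
  deviance stops improving (tolerance 1e-6, up to 4 rounds). The
  convergence flag reflects this criterion.

When several nested variants are fitted (pipeline `compare` stage), richer
variants are warm-started from the nested solution with the extra paths at
zero; this keeps the nesting inequality on −2lnL honest and roughly halves
the fitting time.

### Fit statistics, CIs, comparisons

`df = (observed data points) − (estimated parameters)` and
`AIC = −2lnL − 2·df`; both conventions are asserted as identities on every
result. Likelihood-ratio tests use `Δχ² = −2lnL(nested) − (−2lnL(base))`
with `Δdf = ep(base) − ep(nested)`. Model choice: among variants not
significantly worse than the best-fitting one at the chosen level, take
the smallest AIC, ties broken by fewer parameters.

Confidence intervals: profile likelihood at the χ²(1) 95% cutoff (3.841),
re-optimizing all other parameters at each fixed value and root-finding
the deviance rise; the delta method (numerical Hessian, transformed by the
parameterization Jacobian) is the fallback and the default for derived
quantities. Indirect effects are reported as a_j·b_j with first-order
delta CIs; the profile route for a product parameter would require a
reparameterized constrained fit and is not implemented — the CI method is
recorded in the output.

Variance proportions (VA/VC/VE/VS) divide each component by the component
sum; their delta CIs propagate the full component covariance through the
ratio gradient.

Saturated-model twin correlations are computed as sample product-moment
correlations of the stacked (twin-1, twin-2) vectors per zygosity group —
with complete pairs these are the saturated ML estimates — with Fisher-z
95% intervals, and formatted with MZ below / DZ above the diagonal.

## Item measurement

Single-factor logistic 2PL: `P(y=1|θ) = σ(disc·(θ − diff))` with
θ ~ N(0,1). Marginal ML by Bock–Aitkin EM over 49 Gauss–Hermite points
(configurable); the M-step is a per-item expected-count logistic Newton
with step damping. The marginal log-likelihood is asserted non-decreasing
every iteration; non-convergence raises, carrying the last iterate.
Convergence near a zero-discrimination boundary (null items) is slow, so
the iteration cap defaults to 3000.

Discrimination ↔ standardized loading conversion uses the logistic scaling
constant D = 1.702: `loading = (disc/D)/sqrt(1+(disc/D)²)` (round-trips to
1e-10; the link and constant are recorded choices — a probit variant would
differ negligibly at these scales). Variance explained is the mean squared
standardized loading.

Sum-score levels: exposure counts {0}→0, {1}→1, {≥2}→2; symptom counts
{≤1}→1, {2}→2, {3}→3, {≥4}→4 (the rule object is explicit and
swappable). Counts run over non-missing items; the symptom level is
missing when the exposure count is zero — a symptom report presupposes at
least one event — and when every item is missing.

## Preprocessing

Fixed, logged order: conditional symptom missingness → MRI-QC mask (ROI
cells missing where qc_score < 600, strict inequality; other measures
retained) → OLS residualization on age/sex/ancestry (plus scanner and the
matching total volume for ROI columns) with standardization to unit SD →
outlier mask (|z| > 4 strict, on the already-standardized column, SD not
recomputed — so re-application is a no-op). Rows are never dropped; only
cells become missing. Residualization fits on complete cases and predicts
for all rows with complete covariates; a rank-deficient design raises an
error naming the aliased column. Skewness/kurtosis of the processed scores
are logged with a warning beyond 2/7. A Blom rank-based inverse-normal
transform is available (off by default) for sensitivity fits.

Because standardization precedes the outlier mask, a column that contained
injected artifacts ends up with retained-cell SD slightly below 1 after
masking; this ordering ambiguity is resolved this way and logged.

## Elastic net

Objective `RSS + λ Σ_j[(1−α)/2 β_j² + α|β_j|]` — α = 1 is the LASSO,
α = 0 ridge. Cyclic coordinate descent in the Gram (covariance-update)
form with soft-thresholding, warm starts along a geometric λ path from
λ_max (the smallest λ zeroing every coefficient, computed at α∨0.001) down
three decades in 100 points. KKT subgradient conditions are asserted along
paths in the tests; α < 1 yields exactly equal coefficients on duplicated
columns (grouping); the independent cross-check against scikit-learn lives
in the test suite only.

Cross-validation: k = 10 folds assigned to whole families so relatives
never straddle the split; per α the rule reports λ_min (smallest mean CV
MSE) and λ_1se (largest λ within one SE); the preferred α minimizes the
MSE range over its [λ_min, λ_1se] window (ties → smaller minimum MSE).
Mediator selection takes predictors with nonzero coefficients anywhere in
the window, ranked by |coefficient| at λ_min; a `max_mse_increase` knob
(in SE units) caps the window, 0 restricting it to λ_min. Whether the CV
response should be the symptom score, the exposure, or both is not
determinable from the source analysis; the pipeline uses the symptom score
with [exposure + ROI columns] as predictors, and the function surface
accepts any response.

The penalized SEM fit applies the same penalty functional to the forward
a/b paths only (c and the variance components are unpenalized), scaled by
the number of persons, with |β| smoothed as sqrt(β²+1e-10) for the
quasi-Newton optimizer; λ = 0 reproduces the ML fit, large λ drives the
mediator paths to zero while retaining c.

## Effective number of tests

Li–Ji eigenvalue construction:
`Meff = Σ_i [ 1(λ_i ≥ 1) + (λ_i − ⌊λ_i⌋) ]` over the eigenvalues of the
ROI correlation matrix — p for identity, 1 under perfect correlation.
Eigenvalues are rounded at 1e-10 before the floor (the formula is
discontinuous at integers and eigensolvers return 5.9999… for exact 6).
The screening adjustment is applied as α/Meff and is configurable.

## Synthetic cohorts: what is and is not emulated

The generator draws families (MZ/DZ pairs at the twin-hub sites — 4 of 20
by default — siblings and singletons everywhere), site effects per
phenotype, correlated A/C/E component vectors across phenotypes (the
contralateral structure), applies the structural paths, and derives
residual variances so every phenotype has unit variance given the paths.
Defaults are the study conditions: exposure A/C/E/S = 0.23/0.62/0.15/0.01;
a strong direct path with weak mediation (c = 0.918, a = 0.014,
b = 0.027 in the acceptance simulations); zero-exposure rate calibrated to
61.95% by a common difficulty shift solved by root-finding on the realized
liability sample; QC failures 6.8% below the 600 threshold; outliers
injected beyond 4.5 SD. Age ≈ N(9.9, 0.62²), balanced sex, a 5-group
ancestry mix, 3 scanner types assigned per site; covariate effects are
linear/additive and removed again downstream.

Item difficulties: two common exposure "anchor" items plus 15 rare ones —
with the zero-rate pinned, this also reproduces a ~97% mass at counts 0–2;
symptom difficulties all above +1.8 SD, placed so ~95% of subjects report
≤3 symptoms and the ordinal level variable keeps usable spread (an extreme
placement of nearly all difficulties above +3.9 SD would push the top
level beyond the ±4 SD mask and is inconsistent with the processed-score
spread the analysis assumes).

Not emulated: image synthesis (ROI volumes are generated directly on the
standardized scale — real volumes in mm³ arrive via the residualization
step), item-level missingness mechanisms other than the structural ones,
age/sex effects on variance components, dominance, assortative mating,
zygosity misclassification, and site-by-phenotype interactions beyond the
additive site factor. Passing recovery tests therefore demonstrates
correctness of the estimator under the model's own assumptions, not
robustness to their violation.

## Problem sizes

The acceptance script uses 20 replicates of an 8,000-person cohort for the
univariate variance-proportion recovery and 10 replicates of a
6,000-person one-mediator cohort for the direct-path recovery; the test
suite uses smaller cohorts (hundreds of pairs) chosen so that Monte-Carlo
standard errors stay well inside the asserted tolerances. The LRT type-I
check runs at reduced replicate counts (12–30) with binomial-3-SE
acceptance bands.

## Known limitations

- Ordinal variables enter the SEM as residualized quasi-continuous scores;
  no ordinal-threshold FIML is provided.
- Indirect-effect CIs are delta-method, not profile.
- The reverse-direction and saturated variants can sit on ridges
  (near-unidentified c/c_rev trade-offs); condition diagnostics are the
  gradient norm, the start log and the delta-method SEs — interpretation
  is left to the user.
- The elastic-net CV response convention and the standardize-before-mask
  order are documented choices; alternatives are configurable but not the
  default.
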