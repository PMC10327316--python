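# Methods

## The synthetic cohort

The generator emulates a six-wave adult cardiometabolic cohort. Per
subject i and wave j (j = 1..6):

* Sex_i ~ Bernoulli(0.5), coded 1/0 (the 2.360 BMI and −3.434 DBP
  coefficients attach to the level coded 1);
* Age_i1 ~ N(39.34, 16.23²) truncated to [1, 84] (rejection sampling;
  ages stay continuous), and Age_ij = Age_i1 + 3(j−1) exactly;
* BMI_ij = 19.86 + 0.136·Age_ij + 2.360·Sex_i + u_i + e_ij, with
  u_i ~ N(0, 4.50²) and e_ij ~ N(0, 1.57²);
* DBP_ij = 55.03 + 0.098·Age_ij − 3.434·Sex_i + 0.707·BMI_ij + v_i + w_ij,
  with v_i ~ N(0, 6.35²) and w_ij ~ N(0, 6.88²).

**Scale calibration.** The source parameterization does not say whether
4.50, 1.57, 6.35, 6.88 are standard deviations or variances, so
`SimulationConfig.scale_interpretation` exposes both. We calibrated
against two reference quantities: the per-wave missing proportions
(matched under either reading, within ±0.012) and the post-trajectory-mean
LMM BMI coefficient, which separates them decisively (≈0.62 under the SD
reading vs ≈0.55 under the variance reading, against a reference of
0.6164). The default is therefore `"sd"`.

**MAR amputation.** Each BMI cell is independently deleted with
probability expit(β0j + 0.002·Age_ij + 0.02·DBP_ij), each DBP cell with
expit(φ0j + 0.002·Age_ij + 0.02·BMI_ij), using the wave-specific
intercepts β0 = (−2.646, −2.634, −3.047, −3.271, −2.872, −2.440) and
φ0 = (−1.701, −1.815, −2.091, −2.386, −2.104, −1.522). Both logits are
evaluated on complete, pre-deletion values, so BMI missingness may depend
on a DBP value that is itself subsequently deleted; the two indicators are
drawn independently cell by cell (only marginal mechanisms are specified).
Sex and age are never amputed. Missingness probabilities average ~0.15–0.33
per wave, giving realistic mixes of intermittent gaps and dropout-like
tails.

**Randomness.** All draws use `numpy` Generators keyed on
`(seed, stream)` seed sequences with separate substreams for generation
(0), amputation (1) and hot-deck imputation (2), so the same seed produces
the same cohort whether or not amputation or imputation follows, and
identical `(config, seed)` reproduce panels bit for bit.

**What the generator does not emulate:** MNAR/selection mechanisms,
unequal visit spacing, measurement error in age, secular time trends
(the generating time effect is zero), and within-subject residual
autocorrelation beyond the random intercept. Results on synthetic data
therefore speak to MAR missingness in a compound-symmetric world, not to
every feature of a real cohort.

## Missingness taxonomy

Per trajectory, each cell is classified `observed`, `internal` (observed
values exist both before and after — intermittent), `trailing` (all later
cells missing — dropout), or `leading` (all earlier cells missing). The
leading category extends the usual two-way monotone/intermittent split so
head gaps have a defined imputation rule; an all-missing trajectory is
classed all-trailing by convention.

## The sixteen single-imputation methods

Cross-sectional methods replace a missing cell from the values observed at
the same wave (mean / median / uniform hot-deck draw). Trajectory methods
use the subject's own observed values (mean / median / hot-deck), LOCF and
NOCB carry the nearest earlier/later observation (with mutual fallback at
the head/tail, so one observed value always suffices). Interpolation fills
internal gaps by the line through the nearest observed neighbours,
`y_ia + (k−a)(y_ib − y_ia)/(b−a)`, and extends into head/tail gaps by one
of four strategies: flat carrying (`locf`), the line through the first and
last observed values (`global`), the line through the two boundary
observed values (`local`), or the angle bisector of the global and local
lines anchored at the boundary point (`bisector`). Copy-mean methods take
the matching initial completion and add the wave-level average variation
`AV_k` = (mean of originally observed values at wave k) − (mean of the
step-1 completed values at wave k).

Numerical conventions: interpolation is linear in the wave index (waves
are equally spaced, so any affine time scale gives identical values);
bisector slopes are computed from summed unit direction vectors (atan2),
which is stable for steep lines; medians of even counts use the midpoint
of the middle two; hot-deck draws are uniform with replacement and
per-cell independent, seeded. The population mean trajectory in copy-mean
uses originally observed values only — the complete trajectory is
unavailable by definition.

**Degenerate trajectories.** A trajectory with no observed value (or fewer
than two for the line-based variants) cannot be imputed from within. The
operators raise a named error by default. The replication harness instead
runs with `on_degenerate="skip"`: unimputable cells stay missing and rows
still incomplete after imputation are dropped before model fitting. Under
the default MAR design this affects ~0.2 subjects per 1000 per variable,
but ~28% of replicates contain at least one such subject, so an erroring
policy would make large Monte-Carlo runs impossible while the dropped rows
change coefficient means by well under one Monte-Carlo SE. In skip mode,
line-based interpolation on a single-observation trajectory falls back to
constant extension.

## The analysis models

**Random-intercept LMM.** `dbp ~ 1 + age + sex + bmi + time + (1|subject)`
with time the numeric wave index 1..6. The implementation profiles the
likelihood over the variance ratio λ = σ²_b/σ²_ε: given λ, the GLS
estimates and σ̂²_ε are closed-form (group-wise quasi-demeaning), leaving a
one-dimensional bounded optimization over log λ ∈ [−14, 14]. Coefficients
and SEs are reported from REML; deviance = −2·(ML log-likelihood) and
AIC = deviance + 2k with k = fixed effects + 2 variance components. The
REML criterion follows the statsmodels MixedLM convention (determinant
term on the scale-free weighted cross-product); the test suite checks
agreement with statsmodels to numerical precision and SEs against a dense
GLS computation. A relative floor of 1e−12 on the residual sum of squares
guards the perfect-fit limit. Note the source tables print AIC < deviance,
which no standard definition reproduces; we use the standard definitions.

**REEM tree.** Starting from b̂_i = 0, alternate: (1) fit a
variance-reduction CART to y_it − b̂_i on (age, sex, bmi, time); (2) fit
the random-intercept mixed model on the terminal-node indicator design,
updating b̂_i, the node effects μ_p and the variance components. Stop when
the REML log-likelihood changes by less than `tol` (default 0.001), cap at
100 iterations (warning, not error). The loop is not guaranteed monotone —
a tree refit can lower the mixed-model likelihood — so decreases beyond
10·tol raise a warning. After convergence the leaf predictions are
replaced by μ̂_p; predictions add b̂_i for training subjects and 0
otherwise.

The tree itself is deterministic: candidate thresholds are midpoints
between consecutive distinct sorted covariate values, a split must reduce
total SSE by at least `cp` × root SSE (and be strictly positive), children
keep at least `min_leaf` = 7 rows, nodes split only with `min_split` = 20
rows, no depth cap; ties break toward the lowest feature index, then the
lowest threshold. The cp/min-split/min-leaf defaults follow the
conventions of the classical recursive-partitioning implementations; the
source analysis does not state its settings, so tree-level comparisons are
property-based rather than value-targeted.

## Evaluation

Metrics are computed on conditional residuals r_it = y_it − fit − b̂_i
standardized by the fitted residual SD: MSE = mean(s²), RMSE = √MSE,
MAD = median|s|. The standardization is a deliberate reading: the
reference tables report MSE ≈ 0.85–0.98 for DBP measured in mmHg, which is
impossible for raw residuals (σ̂_ε ≈ 6.9 mmHg) and consistent with
SD-standardized ones; metric comparisons are therefore treated as ordering
checks rather than strict targets. AIC is reported for the LMM only,
matching the reference layout. Rubin's rules (q̄, W, B, T = W + (1+1/m)B)
pool externally produced multiply-imputed fits; the MCMC imputers
themselves are out of scope.

The replication harness runs R replicates with seed base+r, applies every
requested method to the same amputed data within a replicate, and reports
per-cell across-replicate means with Monte-Carlo SEs (sd/√R). Metrics are
averaged per replicate, not pooled across residuals. The packaged
reproduction (`scripts/acceptance.py`, and the acceptance tests) uses 100
replicates of n = 1000 — a tenth of the original 1000 replicates, enough
for Monte-Carlo SEs of ~0.004 on the BMI coefficient means.

## Known limitations

* Only random intercepts (no random slopes) in both models.
* The copy-mean correction is the additive AV_k form; some reference
  implementations scale the correction in certain variants.
* Cross hot-deck samples unrestricted from the wave's observed values (no
  covariate matching).
* REEM comparisons are property-based because the original tree settings
  are unstated.
* The harness's >5% failed-replicate abort is the only failure-tolerance
  mechanism; individual replicate failures are logged, not retried.
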