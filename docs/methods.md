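# Methods

This note documents the models, estimators, defaults and numerical choices
behind `rsmeta`, and what its synthetic-data tests do and do not establish
about real extracted data.

## Data model

The unit of analysis is one response-shift *effect*: a single test result
for one PROM domain / response-shift method / sample combination.  Effects
are nested in *samples* (unique participant groups).  Sample — not study —
is the clustering key: dependence arises when effects are computed on the
same participants, and a few samples are analyzed in more than one study
(e.g. a secondary analysis with a different method), while one study may
contribute several independent samples.  Study identity is carried only for
reporting.  When a study analyzed a subsample of a participant group whose
overall sample is also in the data, the subsample's effects are excluded
(chains of subsample links are followed; cyclic links are rejected; a
subsample whose parent contributes no effects is retained as the best
available representation of the group).

Categorical covariates are reference-coded (k−1 dummies); missing values
map to an explicit `other_unknown` category rather than being dropped.
Per-sample participant counts may be binned into quartiles with cutpoints
(57, 254, 410) — boundary values fall in the lower bin — or recomputed from
the data.

## Detection arm: 2-level random-intercept logistic model

logit P(y_ij = 1 | u_j) = x_ij′β + u_j, u_j ~ N(0, τ²).

* **Estimation.**  Marginal maximum likelihood with the random intercept
  integrated out by *adaptive* Gauss–Hermite quadrature: per cluster, the
  integrand's mode is found by a damped Newton search (warm-started across
  likelihood evaluations) and nodes are recentred/rescaled by the posterior
  curvature.  15 nodes by default; on fixed toys the 21-node result is
  within 1e−6 of 101 nodes, and the whole likelihood is oracle-tested
  against dense-grid numeric integration.  The optimizer works on
  (β, s = √τ²) with s ≥ 0; at s = 0 the likelihood is evaluated as ordinary
  logistic regression, so the boundary fit reduces to a plain logistic fit
  exactly.  Standard errors come from the finite-difference observed
  information (the s row/column is dropped at the boundary; the τ² SE uses
  the delta method).
* **Latent-scale variance accounting.**  On the latent-response view
  y* = x′β + u + e with e standard logistic, var(e) = π²/3.  The fixed
  predictor x′β̂ is split into between-cluster means and within-cluster
  deviations (var_B + var_W).  Reported quantities:
  total R² = var(x′β̂)/(var(x′β̂)+τ̂²+π²/3);
  effect-level R² = var_W/(var_W+π²/3);
  sample-level R² = (var_B + τ²_null − τ²_full)/τ²_null (may be negative
  under suppression/reshuffling; undefined when τ²_null = 0).  The split is
  one of several defensible latent-scale decompositions; it is isolated in
  `latent_r2` and deliberately swappable.
* **Standardized solution and Pratt index.**  Standardized coefficients
  rescale by sd(x_j)/sd(y*) with sd(y*) = √(var(x′β̂)+τ̂²+π²/3); latent
  predictor–response correlations are cov(x_j, x′β̂)/(sd(x_j)·sd(y*)).
  Pratt share of dummy j = std β̂_j·r_j/R², summed over a variable's
  dummies.  By construction the shares sum to exactly 1 on an exact fit;
  negative shares are reported as-is (possible suppression).
* **Marginal standardization.**  A category's adjusted probability sets the
  variable to that category for *every* effect, keeps all other covariates
  at observed values, and averages predictions.  Predictions are
  population-averaged by default — expit is integrated over N(0, τ̂²) with
  31-node Gauss–Hermite — with cluster-conditional (u = 0) predictions
  available via a flag.  Population-averaging is the default because the
  synthesis targets population-level probabilities; the two conventions are
  both implemented since either could be meant by an "adjusted
  probability".

## Magnitude arm: 3-level random-effects meta-regression

d_ij = x_ij′γ + v_j + e_ij + ε_ij with v_j ~ N(0, τ²₃) (sample level),
e_ij ~ N(0, τ²₂) (effect level) and known ε_ij ~ N(0, σ²_ij) (participant
sampling variance, treated as fixed — the standard meta-analytic
convention).

* **Estimation.**  REML by default (ML available).  γ is profiled out by
  GLS and the profile (restricted) likelihood is maximized over
  (τ²₂, τ²₃) ≥ 0 by bounded quasi-Newton from three starts.  The
  block-compound-symmetric covariance is handled by Sherman–Morrison per
  cluster, so cost is linear in the number of effects.  The optimum is
  oracle-tested against dense (τ²₂, τ²₃) grid search and cross-checked
  against `metafor::rma.mv`; pinning τ²₃ = 0 reproduces an ordinary 2-level
  random-effects meta-analysis (checked against an independent dense REML
  implementation and `metafor::rma`).
* **Variance decomposition.**  From the intercept-only model: total =
  typical σ² + τ²₂ + τ²₃, where the level-1 summary is the
  Higgins–Thompson "typical" within-study variance
  s² = (k−1)Σw_i/((Σw_i)² − Σw_i²), w_i = 1/σ²_i.  Shares are components
  over the total.
* **Level-wise R².**  Proportional reduction in heterogeneity,
  R²_ℓ = max(0, 1 − τ²_ℓ(model)/τ²_ℓ(null)); undefined (reported as None)
  when the null variance at that level is zero.
* **Marginal mean effect sizes** use the same standardization as the
  detection arm; the mean function is linear, so they are adjusted means.

## Effect-size construction

Cohen's d = |X̄₁ − X̄₂|/SD with the SD hierarchy: SD of the difference ≻
pooled SD of the two timepoints ≻ baseline SD.  The pooled SD uses the
equal-weight form √((s₁²+s₂²)/2) when group sizes are equal or unknown
(always true of within-person then-test contrasts) and the df-weighted form
otherwise.  When no SD is directly available: median/IQR summaries convert
via the Wan et al. estimators — mean ≈ (q1+median+q3)/3, SD ≈ (q3−q1)/η(n)
with η(n) = 2Φ⁻¹((0.75n−0.125)/(n+0.25)) — chosen as the most widely
validated variant and isolated so it can be swapped; CIs invert the t-based
half-width (SD = √n·width/(2t_{(1+level)/2,n−1})); paired t statistics give
SD = |mean|√n/|t|.  A reported effect size is the last resort; effects with
no usable inputs raise an "inestimable" error and are excluded upstream.
All effect sizes are absolute values: outcome directions are not comparable
across heterogeneous studies.  No Hedges small-sample correction is
applied.

## Purposeful selection

Both arms share one engine, generic over a `fit_fn(variables)` returning
joint Wald p-values per variable block and coefficients per dummy.

1. Univariate screen at α = 0.25 (deliberately liberal).
2. Iterative backward pruning of the multivariable model: the candidate
   with the worst p ≥ 0.10 is removed unless removal changes any remaining
   coefficient by more than 20% relative to the fuller model (confounding),
   in which case it is kept; repeat until every variable is significant or
   a confounder.  The relative change uses the fuller-model coefficient as
   denominator; a zero denominator falls back to the absolute change.
3. Screened-out variables are re-tested one at a time in the step-2 model
   and re-enter if p < 0.10.

Quality-control variables are appended afterwards without selection
(detection arm: the four quality flags; magnitude arm: also the
response-shift method, retained for theoretical interest).  Multi-category
variables move as whole blocks (joint Wald test).  Wald p-values are used
throughout (an LRT variant would be straightforward; the choice matters
little at these sample sizes).  The procedure is deterministic given data
and candidate order; removal ties break toward the largest p.

## Cluster bootstrap

Percentile CIs from resampling sample ids with replacement; a sample drawn
r times contributes all its effects r times under distinct relabeled
cluster ids.  B defaults to 1000 and a seed is always required (no silent
seeding).  Percentile rather than BCa intervals: the simplest method
consistent with clustered resampling, and coverage for the overall marginal
probability is verified by simulation (95% CI coverage within [91%, 98%]
over 200 known-truth replications).  In that coverage study the statistic
is the pooled (intercept-only, τ² = 0) marginal-standardized probability —
identically the observed detection proportion — which estimates the same
population quantity as the GLMM-based marginal at a small fraction of the
cost; bootstrap CIs for model-based marginals in the pipeline refit the
final model on every replicate (warm-started from the full-data fit).

## Synthetic-data generator

The generator emulates the corpus structure the models assume: a
configurable number of samples and effects per sample (reference defaults:
5–50 for the detection corpus, 2–12 for the sparser magnitude corpus), a
small fraction
(default 4.4%) of samples analyzed in two studies, sample-level covariates
constant within samples, effect-level covariates varying freely, and the
two outcome models above.  Reference conditions:

* detection: intercept ≈ logit(0.2)+0.45 (so the average detection rate is
  ≈15% once the covariate contrasts are applied), τ² = 1, log-odds
  contrasts at the magnitudes implied by observed category-wise detection
  probabilities (then-test vs latent-variable ≈ −1.0, regression ≈ +0.85,
  recalibration vs reprioritization/reconceptualization ≈ −0.95, ...), and
  a deliberately null sex variable for the selection step to screen out;
* magnitude: μ = 0.30, τ²₃ = 0.029, τ²₂ = 0.019, participant counts
  Uniform(57, 410) giving a typical Cohen's-d sampling variance ≈ 0.005 and
  hence the characteristic ≈(55%, 37%, 8%) sample/effect/participant
  variance split.

σ²_ij is computed from the one-group (within-person) form
σ² = 1/n + μ_ij²/(2n) at the fixed-part expected effect μ_ij, making it a
deterministic function of configuration and covariates, as known sampling
variances are in a meta-analysis.  Covariates are generated independently
across variables (the models contain main effects only).  Generated effect
sizes are draws from the 3-level normal model itself; by default they are
*not* folded to absolute values — under the reference conditions the model
mass is almost entirely positive, and folding would bias μ upward by ≈7%
and defeat parameter-recovery testing.  A `fold_negative` flag exists for
stress-testing the absolute-value convention.

What the generator does **not** emulate, hence what passing tests do not
show about real data: correlated covariates (real design and method
characteristics co-occur), non-normal heterogeneity, selective reporting or
publication bias, measurement error in extracted statistics, informative
cluster sizes, and the SEM-derived effect sizes whose σ² a real analysis
must obtain from reported model output.  Recovery results certify the
estimators under their own assumptions, not robustness to violations.

## Problem sizes and reproducibility

Identical seed and configuration reproduce datasets, fits, bootstrap draws
and report files byte-for-byte.  The test suite exercises oracle toys
(2–10 clusters), single-dataset recovery at 60–300 samples, and simulation
studies of 100–200 replicates (GLMM recovery at 300 samples × 20 effects;
meta-regression recovery at 200 × 5; bootstrap coverage at 60 samples with
B = 500).  `scripts/acceptance.py` runs both arms at a demonstration scale
of 120 samples (detection, ≈1300 effects) and 116 samples (magnitude,
≈800 effects) with B = 200 bootstrap replicates — sizes chosen as the
package's reference demonstration of the full stack.

## Known limitations

* No crossed random effects, random slopes, or 3-level logistic model for
  detection; no robust (sandwich/CR2) variance estimation or
  Knapp–Hartung adjustment; no publication-bias diagnostics.
* No interaction terms in either arm and none searched during selection.
* Wald-based selection p-values only (LRT not wired into the engine).
* The latent-scale R² level split and the population-averaged marginal
  default are documented conventions among several defensible variants;
  both are isolated behind small functions for substitution.
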