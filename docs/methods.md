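# Methods

## The model

`jointlogit` analyses three correlated binary outcomes collected in a
three-level survey design: individuals (level 1) nested in households
(level 2) nested in clusters / enumeration areas (level 3).  The motivating
setting is a national HIV survey in which each adult contributes a blood
test result, awareness of HIV/AIDS, and awareness of an HIV/AIDS campaign.

### Separate per-outcome model

For one outcome, the three-level random-intercept logistic model is

    logit P(Y_ihc = 1 | u_c, u_hc) = x_ihc' beta + u_c + u_hc
    u_c  ~ N(0, sigma2_c)    (cluster intercept)
    u_hc ~ N(0, sigma2_h)    (household intercept)

with the two random effects independent (zero cross-level covariance).
Households capture between-household heterogeneity not explained by
covariates; clusters capture between-cluster heterogeneity.

### Simultaneous (joint) model

The three outcomes share one likelihood.  Outcome q has its own coefficient
vector beta_q; the stacked random effects

    u = (u_c^1, u_c^2, u_c^3, u_hc^1, u_hc^2, u_hc^3)

are jointly normal with block covariance: a free 3x3 block Sigma_C at
cluster level (diagonal d1^q, off-diagonals d1^qp), a free 3x3 block
Sigma_H at household level (d2^q, d2^qp), and structural zeros across
levels.  When all six cross-outcome covariances
(d1^12, d2^12, d1^13, d2^13, d1^23, d2^23) are zero, the joint likelihood
factorizes into the three separate models — this identity is exact under
our quadrature construction and is verified to < 1e-8 in the test-suite.
The decision between joint and separate modelling is therefore a 6-df
likelihood-ratio test of those six covariances.  The tested parameters are
covariances, interior points of the parameter space given positive
variances, so the chi-square(6) reference needs no boundary correction.

### Latent-scale intraclass correlation

ICCs use the latent-threshold convention: the level-1 residual is logistic
with variance pi^2/3, entered as the literal 3.29 by default to follow the
convention as usually printed (`LEVEL1_VARIANCE_EXACT` = 3.2899 is available;
the difference moves ICCs in the third decimal at most):

    ICC_cluster             = sigma2_c / (sigma2_c + sigma2_h + 3.29)
    ICC_cluster+household   = (sigma2_c + sigma2_h) / (sigma2_c + sigma2_h + 3.29)

## Estimation

All fits maximize the marginal likelihood — the Bernoulli product with both
random-effect vectors integrated out — approximated by nested adaptive
Gauss-Hermite quadrature (AGHQ):

1. Per cluster, the joint posterior mode of (u_c, {u_hc}) is found by a
   damped Newton sweep; the Hessian's arrow structure (households coupled
   only through the cluster) is solved with a Schur complement, vectorized
   across all clusters.
2. Inner household integrals use tensor Gauss-Hermite nodes centred at the
   modal u_hc, scaled by the Cholesky factor of the inverse conditional
   curvature; the outer cluster integral is centred at the modal u_c with
   the Schur-complement (marginal) curvature.
3. Everything is accumulated in log space (log-sum-exp).

Defaults: 7 nodes per dimension for the separate (1-dim) integrals, 3 per
dimension for the joint model (27-point inner x 27-point outer grids).  On
the bundled test fixtures the 3-node joint value is within ~5e-4 of the
5-node value in log-likelihood units per cluster; the node count is exposed
everywhere (`quad_nodes`) and the factorization identity is constructed so
that restricted-vs-full comparisons always use matching node counts.

The optimizer is L-BFGS-B over (beta, log-Cholesky factors of Sigma_C and
Sigma_H); the restricted model parameterizes only the log-SDs.  The score
is computed analytically via Fisher's identity — the posterior-expected
complete-data score under the quadrature weights — which estimates the true
marginal score directly; its residual error is of the order of the
quadrature error of a posterior expectation and is compared against finite
differences in the tests.

Starting values: a plain logistic regression (statsmodels GLM) for beta
with both variances at 0.1 for separate fits.  The restricted joint fit is
assembled from the three separate fits (the factorization makes their
optima the restricted optimum), and the full joint fit warm-starts there —
which also guarantees a nonnegative LRT statistic.

### Boundary handling

The optimizer keeps log-SDs at or above log(0.1) (a variance floor of 0.01
on the latent scale, ~0.3% of an ICC) and off-diagonal Cholesky entries in
[-2.5, 2.5].  Beyond those bounds the covariance blocks approach degenerate
corners — near-zero variance with near-unit correlation — where a 3-node
grid cannot resolve the integrand and estimation becomes erratic.  A fit
whose SD lands at the floor is flagged (`boundary_cluster` /
`boundary_household`) and reports the floored variance, so every serialized
log-likelihood is reproducible from its serialized parameters.  Wald
standard errors are derived from the observed information — central second
differences of the quadrature log-likelihood — inverted over the interior
(non-boundary) parameters; parameters pinned at a bound carry zero sampling
variance.  Variance-component p-values are one-sided Wald on the variance
scale; near the boundary they should be read as descriptive (the usual
mixture-distribution caveat applies).

## Synthetic-data generator

The generator draws from exactly the model above: trivariate normal cluster
effects (i.i.d. across clusters), trivariate normal household effects
(i.i.d. across households, independent of cluster effects), Bernoulli
outcomes through the logit link.  One seeded NumPy generator is used with a
fixed draw order (cluster effects and cluster covariates, then household
counts/effects/covariates, then individual counts/covariates, then
outcomes, then the missingness mask), so a config plus seed reproduces a
dataset byte for byte.

Missing outcomes are simulated as whole triples missing completely at
random (`missing_rate`), mirroring "don't know"-style exclusions, and all
fits and tabulations apply listwise deletion with a logged exclusion count.

The default emulation config (`default_config()`, 50 clusters x 6
households x 3 individuals) carries survey-like ingredients: age
(continuous, individual, 31 +/- 12.5), education years (3 +/- 3.69), sex
(binary), a 5-level household wealth index and household electricity, with
cluster/household variance components at the magnitudes reported for this
kind of survey (0.394/0.696/0.851 at cluster level; 0.385/0.039/0.067 at
household level) and generic moderate covariate effects.  Intercepts are
placed by the logistic-normal attenuation approximation
(beta_0 = logit(p) * sqrt(1 + 0.346 * total RE variance) - mean covariate
shift) so marginal prevalences land near (0.134, 0.772, 0.549); covariate
variance is ignored in that placement, so prevalences are approximate to a
few percentage points.  A `paper_scale_config()` preset (270 clusters, 23
households each, 1 + Poisson(0.5) sampled adults per household) is provided
for larger experiments.

What the generator does **not** emulate: survey weights, stratification,
informative missingness, within-household covariate correlation, or any
calibration of covariate effect sizes to the real survey.  Passing tests
demonstrate correctness of the estimation machinery under the assumed
model, not robustness to real-data violations of it.

## Verification experiments

All experiment seeds derive from a base seed plus the replicate index.

* **Oracle agreement.**  A plain Monte-Carlo estimator of the marginal
  likelihood (joint normal draws per cluster, delta-method SE of the log)
  is implemented independently of the quadrature path; AGHQ values agree
  within 3 MC standard errors on small fixtures, and the diagonal-case
  factorization identity holds to < 1e-8.
* **Parameter recovery.**  50 replicates of 200 clusters x 6 households x 3
  persons (3600 records) with exchangeable cluster correlation 0.5,
  household correlation 0.3, and one standardized continuous
  household-level covariate.  Acceptance: median absolute error < 0.1 for
  every fixed effect and < 0.15 for every variance/covariance entry.
* **LRT calibration.**  Size: 200 replicates at 100 clusters x 4 households
  x 2 persons under zero cross-covariance; the empirical rejection rate at
  nominal 5% must fall in [0.02, 0.09] (observed: ~0.03 — the test runs
  slightly conservative at this scale).  Power: 100 replicates at 300
  clusters x 2 x 2 with cluster-level cross-correlation 0.8; rejection rate
  must exceed 0.9 (observed: 1.0).  These replicate sizes are the package's
  desk-scale defaults for its own verification suite.
* **Determinism.**  The demo pipeline run twice with one seed produces
  byte-identical pattern tables and log-likelihoods equal to 1e-8.

## Numerical choices and edge cases

* Covariance blocks are validated symmetric PSD; Cholesky factorization
  adds a jitter of 1e-10 x trace-scale, so exactly-zero variances are
  handled (the quadrature then collapses onto the fixed-effect likelihood;
  the degenerate-case identities hold to ~1e-9).
* Records sharing a household and an identical covariate row are collapsed
  to binomial sufficient statistics, so designs whose covariates vary at
  household/cluster level cost O(households) per likelihood evaluation.
* Convergence is declared on the optimizer's own criteria or a projected
  gradient below 1e-4 x (1 + |loglik|); anything else returns a flagged
  fit plus a warning rather than an exception.
* LRT comparability is enforced by fingerprinting the complete-case
  analysis set (IDs, all three outcomes, design matrix) and the node count;
  statistics in [-1e-6, 0) from floating-point noise clamp to 0.
* Pattern-table percentages are rounded to 2 dp, marginal percentages to
  1 dp; comparison tables print coefficients to 3 dp and p-values to 4 dp,
  with full precision kept in the JSON artifacts.

## Known limitations

* The joint model is fixed at Q = 3 outcomes at the API surface (the engine
  is Q-generic).
* Quadrature with 3 nodes per dimension trades a small likelihood bias for
  tractability; raise `quad_nodes` to 5 for final inference on small
  datasets if runtime permits.
* Wald p-values for variance components near zero are conservative; no
  mixture correction is applied.
* No survey weights, no random slopes, no crossed random effects, no
  missing-covariate handling beyond listwise deletion.
* An EM-type estimator is sometimes described for models of this family;
  this package uses direct quasi-Newton maximization of the quadrature
  likelihood, which targets the same maximum-likelihood estimates.
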