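# Methods

## Model

`tweediemix` fits a three-level multiplicative mixed model for semicontinuous
responses — nonnegative outcomes with a point mass at exactly zero and a
right-skewed continuous part, such as repeated symptom-severity scores of
adolescents (sub-clusters) nested in families (clusters).  Writing
Y_ijk for observation k of sub-cluster j in cluster i:

- **Cluster layer.**  U_i ~ Gamma(mean μ_i, dispersion σ²), independent
  across clusters, with μ_i = exp(z_i'β⁽¹⁾) a log-linear function of
  cluster-level covariates.
- **Sub-cluster layer.**  V_ij | U_i ~ Gamma(mean μ_ij U_i, dispersion
  τ²/U_i), conditionally independent, with μ_ij = exp(z_ij'β⁽²⁾).
- **Response layer.**  Y_ijk | V_ij ~ Tw_p(mean μ_ijk V_ij, dispersion
  ρ² V_ij^{1−p}), a Tweedie compound Poisson distribution with index
  p ∈ (1, 2) and μ_ijk = exp(z_ijk'β⁽³⁾).

Throughout, Gamma(mean m, dispersion φ) means shape 1/φ and scale φm, so the
variance is φm².  This is the convention under which the cluster layer has
Var(U_i) = σ²μ_i² and the sub-cluster layer has Var(V_ij | U_i) = τ²μ_ij²U_i,
the moment structure every formula below relies on.  The Tweedie layer has
conditional variance ρ²μ_ijk^p V_ij; for 1 < p < 2 it is a Poisson-count sum
of iid gammas, hence P(Y = 0 | V) = exp(−λ) > 0 with
λ = (μV)^{2−p} / (ρ²V^{1−p}(2−p)).

The point of covariate-dependent random effects is that group-level
covariates act on the mean of their own level's random effect rather than
being attached to individual observations — the latter invites ecological
fallacy in the interpretation of cluster-level effects.  The marginal mean
stays log-linear in the stacked design: E[Y_ijk] = μ_i μ_ij μ_ijk =
exp(X_ijk'β) with X_ijk = (z_i', z_ij', z_ijk')'.  Setting Z1 and Z2 empty
(all covariates at observation level) recovers the conventional
covariate-independent Tweedie mixed model as an exact special case.

## Prediction: orthodox BLUP

Random effects are predicted by the orthodox best linear unbiased predictor
Ŵ = E(W) + Cov(W, Y) Var(Y)⁻¹ (Y − E Y), which needs only the first two
joint moments.  Both predictors have closed forms; with
w_ij = 1 / (ρ² + τ²μ_ij Σ_k μ_ijk^{2−p}),

    Û_i  = [μ_i + σ²μ_i Σ_jk w_ij μ_ijk^{1−p} Y_ijk]
           / [1 + σ²μ_i Σ_jk w_ij μ_ij μ_ijk^{2−p}]
    V̂_ij = ρ²w_ij μ_ij Û_i + τ²μ_ij w_ij Σ_k μ_ijk^{1−p} Y_ijk

with prediction mean squared errors

    d(i)  = σ²μ_i² / [1 + σ²μ_i Σ_jk w_ij μ_ij μ_ijk^{2−p}]
    d(ij) = ρ²w_ij τ²μ_i μ_ij² + (ρ²w_ij)² μ_ij² d(i).

The grouping of the second d(ij) term (the square on ρ²w_ij) is the one
fixed by exact agreement with the dense matrix form
Var(W) − Cov(W, Y)Var(Y)⁻¹Cov(Y, W); it is also the natural one, since
ρ²w_ij μ_ij is the coefficient of Û_i inside V̂_ij, so the cluster-level
prediction error propagates quadratically.  The package carries both routes:
the closed forms are the production path (O(N) per evaluation), the dense
per-cluster matrix route is retained as an oracle and exercised by the test
suite on randomized sweeps at 1e−8 relative tolerance.

## Estimation

Regression blocks solve the estimating equation ψ(β) = 0 built by
substituting the BLUPs into the joint score of the data and random effects:

    ψ⁽¹⁾ = Σ_i   z_i   μ_i⁻¹   σ⁻² (Û_i − μ_i)
    ψ⁽²⁾ = Σ_ij  z_ij  μ_ij⁻¹  τ⁻² (V̂_ij − Û_i μ_ij)
    ψ⁽³⁾ = Σ_ijk z_ijk μ_ijk^{1−p} ρ⁻² (Y_ijk − V̂_ij μ_ijk)

Because the BLUPs are linear projections onto Y, the stacked score equals
X' diag(EY) Var(Y)⁻¹ (Y − EY) exactly, the sensitivity matrix is
S = −X' D Var(Y)⁻¹ D X (D = diag EY), and sensitivity, variability and
Godambe information coincide up to sign: J = V = −S.  The equation is
optimal among estimating functions linear in Y, and model-based standard
errors are sqrt diag(−S⁻¹).  Reported p-values are two-sided Wald normal
(the reference presentation does not state the convention; this is the
natural one for an asymptotically normal estimating-equation estimator).

Dispersions are estimated by adjusted Pearson moment estimators: averages
of squared BLUP residuals plus additive bias corrections built from d(i),
d(ij) (each estimator is exactly unbiased at the true parameters, which the
test suite verifies by Monte Carlo).

### Algorithm

The outer loop iterates, per the estimating-theory recipe: (1) one Newton
scoring step β* = β − S⁻¹ψ for all regression blocks jointly, with step
halving (up to 10) if the linear predictor overflows; (2) BLUP prediction at
the updated β; (3) dispersion update.  Convergence requires both the
maximum relative parameter change < 1e−8 and ‖ψ‖∞ < 1e−6, with max_iter =
200 (tolerances are the package's own choice).

Two numerical decisions matter here:

- **Dispersion solve.**  The plain "one adjusted-Pearson sweep per outer
  iteration" map is a contraction with rates observed around 0.95–0.98 at
  the reference design size, far too slow for the tolerance above.  Step (3)
  therefore solves the sweep map to its fixed point at the current β: 25
  plain warm-up sweeps (to pass the nonlinear transient), then a quasi-Newton
  root solve of log F(exp x) − x = 0 (positivity is automatic in log space),
  verified against the plain map and falling back to plain sweeps when the
  root finder fails or strays.  The solution is exactly the stationary point
  of the one-sweep map; only the route to it is accelerated.  Naive
  componentwise Aitken extrapolation was rejected: on some replicates it
  jumped into a spurious τ² ≈ 0 basin that the plain iteration never enters.
- **Boundary estimates.**  On some datasets a dispersion genuinely wants to
  sit on the zero boundary (e.g. a replicate whose between-cluster variation
  is absorbed elsewhere); the update then decays geometrically with no
  interior fixed point and no convergence by relative change.  A free
  dispersion that is monotone decreasing below 1e−3, losing at least 25%
  over 10 consecutive outer iterations, is pinned at the floor 1e−10 with a
  warning.  Nonpositive single updates are floored the same way; repeated
  flooring is a misspecification signal.

Initialization: β⁽³⁾ from a log-link Tweedie quasi-likelihood GLM on the
observation-level block ignoring clustering (statsmodels), β⁽¹⁾ = β⁽²⁾ = 0,
σ² = τ² = 0.1, ρ² from the Pearson statistic of that GLM.  Cheap,
scale-aware, and inside the basin of attraction in all tested designs.

The index p is fixed during fitting; estimate it externally (e.g. by Tweedie
profile likelihood) if unknown.  `p` enters every weight as μ^{2−p} and the
variance as μ^p, so misspecifying it mainly distorts the dispersion
estimates, not the regression point estimates.

## Simulator

`simulate_tmcdre` draws the hierarchy exactly: gamma layers in the
mean/dispersion convention above, and the Tweedie layer through its compound
Poisson representation (N ~ Poisson(λ), then a single Gamma(Nα, γ) draw),
which is exact for 1 < p < 2 including the point mass at zero.  Draw order
is fixed (structure, covariates by level, then U, V, Y), so datasets are
bit-reproducible under a seed.  Gamma draws that underflow to exactly zero
at extreme dispersions are clipped to 1e−300 so the conditional Tweedie
mean stays positive; the resulting response is zero almost surely either
way.

The reference designs mirror a family study of adolescent mental-health
scores: 269 clusters (parents), 1–5 sub-clusters (adolescents) per cluster,
1–17 repeated observations per adolescent, with the published fitted
parameters (p = 1.55; covariate-dependent: σ² = 0.1050, τ² = 0.3844,
ρ² = 0.6794) as generating truth.  The covariate generators are a
reconstruction, not the study's empirical covariates (which the published
description leaves unstated): binary covariates (treatment, genders,
ethnicity, seasons) are Bernoulli(0.5), adolescent baseline age is uniform
on 12–18 years, parent age uniform on 30–55 years, months-in-study uniform
integer 0–60.  Consequences worth knowing:

- Simulated covariates are mutually independent and balanced; real study
  covariates are correlated within families and unbalanced, and real visit
  times are serially structured.  Passing recovery tests therefore
  demonstrate correctness of the estimator under the model, not robustness
  to real-data covariate structure.
- Replication summaries (biases, SE calibration) under these generators are
  comparable in order of magnitude to the published simulation tables but
  not expected to reproduce them line by line.

## Problem sizes in the test suite

The randomized oracle sweeps use 1000 small instances (I ≤ 5–6, J_i ≤ 4,
n_ij ≤ 5, dispersions log-uniform on [0.01, 5], p ∈ {1.1, 1.5, 1.9},
responses including exact zeros).  The replication experiment runs 100
datasets at the full reference size I = 269 (≈ 7000 observations each);
Monte Carlo moment checks use 10⁵–10⁶ draws.  These sizes were chosen so a
single-core run of the whole suite completes comfortably while keeping MC
standard errors small relative to the tolerances tested.

## Degenerate and edge inputs

- σ² = 0: Û_i = μ_i exactly, d(i) = 0 (no pooling at the cluster level);
  τ² = 0: V̂_ij = μ_ij Û_i (full pooling within cluster).  Both fixed
  dispersions are supported through `fix_sigma2` / `fix_tau2`, and with
  both at zero and no group covariates the fit coincides with a Tweedie
  quasi-likelihood GLM (verified to 1e−6 against an independent IRLS).
- Exact zero responses need no special casing anywhere: μ^{1−p}·0 = 0.
- Singleton clusters and sub-clusters are legal; per-cluster matrices are
  1×1 and the closed forms reduce to scalar shrinkage.
- Linear predictors beyond |η| = 700 raise an explicit error (suggesting
  covariate rescaling) rather than silently overflowing.
- Exactly one intercept is allowed and must sit in the observation-level
  block: with a log link the three-level mean is a product, so constants at
  other levels are not identifiable; validation enforces this, and the full
  column rank of the stacked design is checked up front.

## Known limitations

- p is not estimated; no profile-likelihood machinery is included.
- Inference is model-based (J = V = −S); no robust/sandwich standard errors.
- Exactly three levels; no missing-data or dropout mechanisms.
- Dispersion estimates at the boundary are reported as the floor value with
  a warning rather than as a formal boundary test.
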