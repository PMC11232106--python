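# Methods

## Model

`linkshrink` fits the Gaussian linear model with every two-way interaction,

    Y_i = α + Σ_j β_j x_ij + Σ_{j<k} β_jk x_ij x_ik + ε_i,  ε_i ~ N(0, σ²),

under a hierarchical shrinkage prior that *links* each interaction
coefficient to the local scales of its two parent main effects:

    α ~ N(0, 10²)
    β_j  ~ N(0, σ² τ_j²),           τ_j   ~ C⁺(0, 1)
    β_jk ~ N(0, σ² τ_j τ_k τ_int),  τ_int ~ U(0.01, 1)
    σ² ~ IG(1, 0.001)

`N(0, v)` denotes a normal with *variance* v throughout, and IG follows the
Stan shape–scale convention (density ∝ (σ²)^{−(shape+1)} exp(−scale/σ²)).
The half-Cauchy local scales give flexible, differential shrinkage: a large
β_j drags τ_j up, which in turn loosens the prior on every β_jk involving j —
a soft heredity principle. Conversely the interactions inform τ_j ("reverse
borrowing"). τ_int is a global factor shared by all interactions that lets
them be weaker on average than main effects; its lower bound 0.01 prevents
the interaction block from collapsing entirely in sparse problems.

Variants (selected via `PriorSpec.variant`):

* **bay0int** — main effects get fixed wide priors N(0, 10²); τ_j are then
  informed only through the interactions. Useful when shrinking main effects
  toward 0 is not logical (e.g. a general quadratic form).
* **bayintadd** — the linking factor τ_j τ_k is replaced by (τ_j² + τ_k²)/2,
  so a single strong parent already implies little shrinkage of the
  interaction. The additive form is implemented as a prior *variance* factor,
  dimensionally consistent with τ_j τ_k being a product of two variance-like
  scales; this rendering is a documented package convention.
* **bayint_star** — pins τ_int = 1; more power to detect strong interactions
  at some cost in predictive accuracy.

### Assumptions

Gaussian homoscedastic errors; covariates observed without missingness;
effects linear on the encoded scale (no splines/transformations); interaction
order two. Binary/survival likelihoods and higher-order interactions are out
of scope.

## Covariate encoding

* continuous: standardized, (x − mean)/sd with the ddof=1 sample sd;
* binary: contrast-coded to {−1, +1} (sorted raw values map to (−1, +1)),
  standardized in the balanced case and symmetric in interpretation;
* categorical with L levels: L−1 sum-to-zero contrast columns in {−1, 0, 1};
  column l is +1 for level l, −1 for the reference (the last level in schema
  order). The value set {−1, 0, 1} is fixed; the specific contrast matrix is
  a package convention.

Interactions are exact elementwise products of encoded columns, one per
unordered pair (j, k), j<k, in lexicographic order, excluding pairs inside
one categorical covariate (its dummies are not independently manipulable).
Hence q = C(p_enc, 2) − Σ_c C(d_c, 2). Centering the continuous covariates
largely removes the collinearity between main effects and their interactions.
Training-set centers/scales are frozen in `TransformStats` and re-applied to
any new data; unknown levels raise.

Moment statistics are frozen at fit time with denominator n: per-column means
E[x_j] and per-pair second moments E[x_j x_k]. (Standardization uses ddof=1,
so a column's moment with itself is (n−1)/n, not 1; tests account for this.)

## Posterior computation

The sampler is a **blocked Gibbs sampler** written for this model — the
conditional structure makes gradient-based samplers unnecessary:

1. (α, β) | τ, τ_int, σ² is multivariate normal with precision
   A = WᵀW/σ² + P⁻¹ (W the full design with intercept, P the diagonal prior
   covariance). Drawn exactly via Cholesky; WᵀW is precomputed once.
2. σ² | β, τ is inverse-gamma — conjugate because the β priors scale with σ²
   (for bay0int the main-effect block drops out of the conditional).
3. Each τ_j | rest is updated by univariate slice sampling (Neal 2003,
   stepping-out + shrinkage) on u = log τ_j; the conditional combines the
   half-Cauchy kernel, the β_j term (unless bay0int) and all interaction
   terms involving j.
4. τ_int | rest ∝ τ_int^{−q/2} exp(−s/τ_int) on [0.01, 1], slice-sampled on
   its bounded support.

All conditionals are exact, so there is no step-size tuning, divergence
handling or mass-matrix adaptation. Each Gibbs block is exposed as a pure
function and the test suite verifies it against differences of the joint log
density, which itself is checked against an independently assembled
textbook-density oracle. Multiple chains use independently spawned seed
sequences; a fixed seed gives bit-identical draws. Split R-hat and bulk ESS
(ArviZ) are computed for every scalar parameter; R-hat > 1.05 or ESS < 100
triggers a warning, never a silent pass.

Defaults: 4 chains × (1,000 warmup + 5,250 kept) ≈ 25,000 total draws.
Tests and examples use reduced budgets (e.g. 4 × (500 + 1,000)); a sim1-sized
fit (n=200, 56 coefficients) takes ~10 s on one CPU.

### Summaries and selection

The point estimate is the posterior mean. Equal-tailed credible intervals use
empirical quantiles. A coefficient is *selected* at level ℓ iff its interval
excludes 0; the per-coefficient selection score is the largest level at which
it would still be selected, computed as 1 − 2·min(P(β<0), P(β>0)) under the
empirical posterior — thresholding the score reproduces interval selection at
any level and is the handle used by FDR sweeps.

## Interventional Shapley values

The coalition value v(S) fixes the "players" in S at the individual's values
and marginalizes non-players *ignoring their dependence on the players*
(interventional convention), which for a quadratic predictor needs only the
frozen first and second moments:

    v(S) = α + Σ_{j∈S} β_j x*_j + Σ_{j∉S} β_j E[x_j]
         + Σ_{j<k, both∈S} β_jk x*_j x*_k
         + Σ_{j∈S, k∉S} β_jk x*_j E[x_k]
         + Σ_{j<k, both∉S} β_jk E[x_j x_k]

Because v is linear in the coefficients, each term is a one- or two-player
subgame and the Shapley value has a closed form. A main term contributes
β_j (x*_j − E[x_j]) to its player; an interaction β_jk between distinct
players g ∋ j and h ∋ k contributes to g

    ½ β_jk [ x*_j (E[x_k] + x*_k) − E[x_j x_k] − E[x_j] x*_k ]

and symmetrically to h. With centered columns this reduces to the familiar
φ_ij = β_j x*_ij + ½ Σ_{k≠j} β_jk (x*_ij x*_ik − E[x_ij x_ik]); the ½
multiplies both the product and the moment term — the coalition-enumeration
oracle in the test suite is the arbiter of this form (closed form ≡ brute
force to 1e-9 on 100 random instances), and the general non-centered/grouped
expression is derived from the coalition value rather than transcribed.
Efficiency, dummy, symmetry and linearity hold exactly per draw, and averaged
over the training sample the attributions are exactly zero by construction.

A categorical covariate is one grouped player: all its contrast columns enter
or leave coalitions together. Applying the formula to every posterior draw
yields credible intervals for φ_ij; φ = φ^main + φ^int splits off the
β_j (x*_j − E[x_j]) part. Global importances are I_j = (1/n) Σ_i |φ̄_ij| of
the posterior-mean attributions, likewise per component; I_j ≠ I_j^main +
I_j^int in general because of sign cancellation.

The brute-force enumerator is exponential and refuses more than 15 players;
it exists as the validation oracle.

## Conditional-effect tools

Personalized unit-change effects E_ij = β_j + Σ_{k≠j} β_jk x_ik are computed
per draw (affine in x_i, so superposition is exact); at the covariate center
E_ij = β_j, the conditional main effect. Range-of-significance bands evaluate
β_j + β_jk x_k on a grid (default 41 equally spaced points over the observed
range of x_k) and flag where the interval excludes zero.

## Evaluation machinery

Over B replicate training sets with known truth β:

* rMSE(β) = sqrt((1/B) Σ_b (β̂^(b) − β)²), per coefficient;
* MSEp^(b) = ‖X_test β̂^(b) − X_test β‖², per replicate — a noise-free
  comparison of fitted and true linear predictors;
* sensitivity at fixed empirical FDR: coefficients are ranked by selection
  score (ties by index), the selection grown one at a time, FDR = FP/(FP+TP)
  and sensitivity = TP/#positives computed over labelled coefficients only
  (indeterminate labels excluded from numerator and denominator), and the
  sensitivity of the largest selection with FDR ≤ the requested level is
  reported. The FDR here is the realized false-discovery proportion against
  known truth — no multiple-testing correction is applied inside selection;
  the sweep over the credible-level score is the package's convention for
  hitting prescribed FDR targets.

The unshrunken reference is OLS on the full interaction design (statsmodels
behind the package surface), which rejects rank-deficient or underdetermined
problems instead of pseudo-inverting.

## Synthetic study designs

* **sim1**: n=200, p=10 continuous covariates, multivariate normal with
  exchangeable correlation ρ=0.3 ("moderately collinear"), q=45. Truth: five
  non-zero mains {1.0, 0.75, 0.5, 0.3, 0.15} and 13 non-zero interactions —
  six between two non-zero mains (0.10–0.30), four between a non-zero and an
  absent main (0.10–0.25), three "surprising" ones between absent mains
  (0.15–0.30), two of which share covariate 7 — 18 non-zero coefficients.
  Covariates 9 and 10 carry no signal anywhere and serve as negative
  controls for Shapley inference.
* **sim2**: n=500, same signal structure plus four independent N(0,1) noise
  covariates (p=14, q=91); being sparser, one main effect and one interaction
  of each type get a stronger signal (0.15→0.5 for the main; 0.10→0.30,
  0.10→0.30, 0.15→0.35 for the interactions).
* **helius_like**: a mixed-type cohort-style covariate set — three mildly
  correlated continuous covariates, three binaries, one 5-level categorical
  and four noise columns (14 encoded columns, q=85). Covariates only; it
  exercises encoding, grouping and Shapley machinery, not recovery.

Noise is calibrated so the *population* R² of the true model is 0.5:
σ_ε² = Var(Xβ)(1−R²)/R², with Var(Xβ) estimated on a 100,000-row Monte-Carlo
draw under a fixed internal seed, making σ_ε a deterministic function of the
configuration; replicates b = 1..B use seeds seed+1..seed+B and share the
calibration. Responses are generated on the encoded (standardized) covariate
scale. The exact correlation level, effect sizes and which effects are
boosted are package conventions exposed in `SimulationConfig`; the structure
(dimensions, sparsity pattern, type counts, R² target) defines the designs.

What the generators do *not* emulate: real cohort covariate dependencies
beyond exchangeable correlation, heavy-tailed or skewed covariates,
heteroscedastic or non-Gaussian noise, missingness, and measurement error.
Passing recovery tests therefore demonstrates correctness of the machinery
under the stated conditions, not performance on arbitrary real data.

## Numerical choices and edge cases

* Standardization uses ddof=1; moments use denominator n.
* Binary mapping: sorted raw values → (−1, +1), deterministic.
* Pair order is lexicographic; all downstream indices refer to it.
* Out-of-support parameters give log density −inf, never an exception.
* Slice sampler: stepping-out width 1.0 on log τ (0.25 for τ_int within its
  bounds), interval shrinkage on rejection, capped stepping.
* Selection ties in FDR sweeps broken by coefficient index after sorting.
* Degenerate posteriors (all draws equal) give zero-width intervals and are
  treated as excluding zero iff the common value is non-zero.
* Constant columns, unknown levels, rank-deficient OLS designs, non-PSD
  correlation requests and missing values raise informative errors.

## Known limitations

* The Gibbs sampler solves a (1+p+q)-dimensional Gaussian system per
  iteration; fine for p+q in the hundreds, not intended for p ≫ 100.
* Local-scale posteriors (τ) are heavy-tailed and mix more slowly than the
  coefficients; the per-parameter ESS diagnostics make this visible.
* At sim1's signal-to-noise level (population R² 0.5 over 55 coefficients,
  n=200), single-replicate recovery of the full non-zero coefficient vector
  is inherently variable; evaluation across B replicates (rMSE, MSEp) is the
  stable comparison the package recommends.
* Interventional (not conditional) marginalization: attributions ignore
  covariate dependence between players and non-players by design.
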