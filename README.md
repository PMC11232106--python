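# linkshrink

Bayesian linear regression with **all two-way interactions** under a
**linked-shrinkage** prior, plus exact **interventional Shapley values** with
posterior uncertainty.

## The problem

Adding every pairwise interaction to a regression model is attractive in
epidemiological and clinical studies — interactions may carry real biology and
omitting them biases main effects — but the number of interaction terms
`q = p(p−1)/2` grows quadratically, so with a moderate `n : (p+q)` ratio plain
OLS becomes unstable, while sparse selection methods (hierarchical lasso and
relatives) give no usable inference. `linkshrink` targets that middle regime:
it estimates, selects and *quantifies uncertainty* for all main and
interaction effects in one model fit, and provides individual-level variable
importance scores with credible intervals.

## The model

For response `Y_i` and encoded covariates `x_ij` (`j = 1..p`):

    Y_i = α + Σ_j β_j x_ij + Σ_{j<k} β_jk x_ij x_ik + ε_i,   ε_i ~ N(0, σ²)

    α ~ N(0, 10²)
    β_j  ~ N(0, σ² τ_j²)            τ_j   ~ C⁺(0, 1)
    β_jk ~ N(0, σ² τ_j τ_k τ_int)   τ_int ~ U(0.01, 1)
    σ² ~ IG(1, 0.001)

The product `τ_j τ_k` **links** the shrinkage of an interaction to the local
scales of its parent main effects — a soft heredity principle: interactions
between strong main effects are shrunk less. The global factor `τ_int` adapts
to interactions being weaker on average than main effects; its lower bound
prevents total collapse of the interaction block. Variants: `bay0int`
(unshrunk main effects), `bayintadd` (additive link `(τ_j²+τ_k²)/2`, so one
strong parent suffices), and `bayint_star` (`τ_int = 1`, more power for
strong interactions).

Sampling is by a blocked Gibbs sampler with exact conjugate updates for
`(α, β)` and `σ²` and slice sampling for the scale parameters; convergence
diagnostics (split R-hat, bulk ESS) are computed via ArviZ.

For interpretation the package computes, per posterior draw:

* **interventional Shapley values** `φ_ij = φ_ij^main + φ_ij^int` in closed
  form (for centered covariates
  `φ_ij = β_j x*_ij + ½ Σ_{k≠j} β_jk (x*_ij x*_ik − E[x_ij x_ik])`),
  validated in-suite against a full coalition-enumeration oracle; categorical
  covariates act as one grouped player;
* global importances `I_j = (1/n) Σ_i |φ_ij|` and their main/interaction
  components;
* personalized unit-change effects `E_ij = β_j + Σ_{k≠j} β_jk x_ik` and
  range-of-significance bands for `β_j + β_jk x_k`.

Evaluation tools (per-coefficient rMSE over replicates, prediction MSEp
against the true linear predictor, sensitivity at fixed empirical FDR via
credible-interval selection scores) and seeded synthetic study designs with
known truth round out the package.

## Worked example

```python
import linkshrink as ls

# simulate one replicate of the n=200, p=10 study design (known truth,
# noise calibrated so the population R^2 is 0.5)
cfg = ls.sim_config("sim1")
ds = ls.generate_dataset(cfg, seed=1)

# encode covariates and build the 45-column interaction design
design = ls.build_interactions(ls.encode_covariates(ds.table, ds.schema))
print(f"n={design.n}, p_enc={design.p_enc}, q={design.q}")

# fit the linked-shrinkage model (reduced draws for the example)
post = ls.fit(ds.y, design, ls.PriorSpec(variant="bayint"),
              ls.MCMCConfig(chains=4, warmup=500, draws=1000, seed=1))
print(f"max R-hat: {post.diagnostics['r_hat'].max():.3f}")
print(f"posterior mean tau_int: {post.tau_int.mean():.3f}")

summary = ls.summarize(post, level=0.95)
print(summary[summary.excludes_zero][["parameter", "mean", "lower", "upper"]]
      .to_string(index=False, float_format="%.3f"))

# interventional Shapley values for the first 5 training individuals
res = ls.shapley_closed_form(post, design.X_main[:5], design)
imp = ls.global_importance(res)
print(imp.sort_values("I", ascending=False).head(4)
      .to_string(index=False, float_format="%.3f"))
```

Output:

```
n=200, p_enc=10, q=45
max R-hat: 1.024
posterior mean tau_int: 0.048
parameter   mean  lower  upper
       x1  1.058  0.698  1.419
       x2  0.633  0.270  0.992
       x4  0.752  0.359  1.132
       x8 -0.387 -0.753 -0.012
covariate     I  I_main  I_int
       x1 0.837   0.778  0.205
       x4 0.722   0.745  0.157
       x2 0.410   0.418  0.121
       x8 0.233   0.256  0.128
```

The 95% credible intervals single out the strong main effects (`x1`, `x2`,
`x4` are truly non-zero here, with `x8` a borderline false positive at this
sample size); `tau_int ≈ 0.05` shows the model has learned that interactions
are much weaker than main effects in this replicate. The importance table
ranks covariates by mean absolute Shapley value and splits each into its
main-effect and interaction contributions (which need not sum to the total
because of sign cancellation).

The same pipeline is scriptable from the shell:

```sh
linkshrink simulate --setting sim1 --reps 1 --seed 10 --out-dir data/
linkshrink fit --data data/sim1_rep1.csv --schema schema.yaml --seed 1
linkshrink shapley --data data/sim1_rep1.csv --schema schema.yaml --seed 1
```

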