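"""Independent hand-coded oracles used by the tests.

These deliberately avoid the package's own density/Shapley code paths:
densities are assembled from scipy.stats building blocks, Shapley values by
direct weighted enumeration, OLS by the normal equations.
"""

import numpy as np
from scipy import stats


def log_joint_oracle(params, y, design, prior):
    """Textbook sum of log densities for the linked-shrinkage model."""
    alpha = params["alpha"]
    bm = np.asarray(params["beta_main"], float)
    bi = np.asarray(params["beta_int"], float)
    tau = np.asarray(params["tau"], float)
    ti = params["tau_int"]
    s2 = params["sigma2"]
    sigma = np.sqrt(s2)

    mu = alpha + design.X_main @ bm + design.X_int @ bi
    lp = stats.norm.logpdf(np.asarray(y), mu, sigma).sum()
    lp += stats.norm.logpdf(alpha, 0.0, prior.alpha_sd)

    if prior.variant == "bay0int":
        lp += stats.norm.logpdf(bm, 0.0, prior.main_sd_bay0int).sum()
    else:
        lp += stats.norm.logpdf(bm, 0.0, sigma * tau).sum()

    for t, (j, k) in enumerate(design.interaction_pairs):
        if prior.variant == "bayintadd":
            relvar = 0.5 * (tau[j] ** 2 + tau[k] ** 2) * ti
        else:
            relvar = tau[j] * tau[k] * ti
        lp += stats.norm.logpdf(bi[t], 0.0, sigma * np.sqrt(relvar))

    lp += stats.halfcauchy.logpdf(tau, 0, 1).sum()
    lo, hi = prior.tau_int_bounds
    if prior.variant != "bayint_star":
        lp += stats.uniform.logpdf(ti, lo, hi - lo)
    lp += stats.invgamma.logpdf(s2, prior.sigma2_shape, scale=prior.sigma2_scale)
    return float(lp)


def ols_normal_equations(y, X):
    """OLS via explicit normal equations (independent of statsmodels)."""
    return np.linalg.solve(X.T @ X, X.T @ np.asarray(y, float))
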