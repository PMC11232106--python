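import numpy as np
import pandas as pd
import pytest
from scipy import stats

import linkshrink as ls
from linkshrink import model
from linkshrink.model import (
    MCMCConfig,
    PriorSpec,
    _sigma2_conditional_params,
    _tau_conditional_logpdf,
    _theta_conditional_params,
    interaction_relvar,
    log_joint_density,
    sample_prior,
)

from ._oracles import log_joint_oracle
from .conftest import random_continuous_design


def _random_params(rng, p, q, variant="bayint"):
    return {
        "alpha": float(rng.normal()),
        "beta_main": rng.normal(size=p),
        "beta_int": rng.normal(size=q),
        "tau": np.abs(rng.standard_cauchy(p)) + 0.05,
        "tau_int": 1.0 if variant == "bayint_star" else float(rng.uniform(0.02, 0.99)),
        "sigma2": float(rng.uniform(0.2, 3.0)),
    }


class TestLogJointDensity:
    @pytest.mark.parametrize("variant", model.VARIANTS)
    def test_matches_scipy_oracle(self, variant):
        """Hand-assembled textbook densities agree with the model density."""
        rng = np.random.default_rng(10)
        design = random_continuous_design(rng, n=25, p=4)
        y = rng.normal(size=25)
        prior = PriorSpec(variant=variant)
        for _ in range(50):
            params = _random_params(rng, design.p_enc, design.q, variant)
            ours = log_joint_density(params, y, design, prior)
            oracle = log_joint_oracle(params, y, design, prior)
            assert ours == pytest.approx(oracle, abs=1e-8)

    def test_out_of_support_is_minus_inf(self):
        rng = np.random.default_rng(11)
        design = random_continuous_design(rng, n=10, p=3)
        y = rng.normal(size=10)
        params = _random_params(rng, 3, design.q)
        for corrupt in (
            {"tau_int": 0.005},  # below the uniform lower bound
            {"tau_int": 1.5},
            {"sigma2": -1.0},
            {"tau": np.array([1.0, -0.5, 1.0])},
        ):
            bad = {**params, **corrupt}
            assert log_joint_density(bad, y, design, PriorSpec()) == -np.inf
        # bayint_star pins tau_int at exactly 1
        star = {**params, "tau_int": 0.9}
        assert log_joint_density(star, y, design, PriorSpec(variant="bayint_star")) == -np.inf

    def test_gaussian_likelihood_term(self):
        """Moving one observation changes the log joint by the N(mu, sigma^2)
        log-density difference."""
        rng = np.random.default_rng(12)
        design = random_continuous_design(rng, n=8, p=2)
        params = _random_params(rng, 2, design.q)
        y0 = rng.normal(size=8)
        y1 = y0.copy()
        y1[0] += 1.7
        mu = (
            params["alpha"]
            + design.X_main @ params["beta_main"]
            + design.X_int @ params["beta_int"]
        )
        sd = np.sqrt(params["sigma2"])
        expected = stats.norm.logpdf(y1[0], mu[0], sd) - stats.norm.logpdf(y0[0], mu[0], sd)
        got = log_joint_density(params, y1, design, PriorSpec()) - log_joint_density(
            params, y0, design, PriorSpec()
        )
        assert got == pytest.approx(expected, abs=1e-10)


class TestGibbsConditionals:
    """Each Gibbs block must be the exact conditional of the joint density."""

    @pytest.mark.parametrize("variant", model.VARIANTS)
    def test_tau_conditional_matches_joint(self, variant):
        rng = np.random.default_rng(13)
        design = random_continuous_design(rng, n=20, p=4)
        y = rng.normal(size=20)
        prior = PriorSpec(variant=variant)
        pairs = design.interaction_pairs
        pair_of = [[] for _ in range(design.p_enc)]
        for t, (j, k) in enumerate(pairs):
            pair_of[j].append((t, k))
            pair_of[k].append((t, j))
        for _ in range(10):
            params = _random_params(rng, design.p_enc, design.q, variant)
            j = int(rng.integers(design.p_enc))
            t1, t2 = float(rng.uniform(0.1, 3)), float(rng.uniform(0.1, 3))

            def joint_at(tval):
                tau = params["tau"].copy()
                tau[j] = tval
                return log_joint_density({**params, "tau": tau}, y, design, prior)

            def cond_at(tval):
                # conditional works on u = log tau and includes the Jacobian u
                u = np.log(tval)
                return (
                    _tau_conditional_logpdf(
                        u, j, params["beta_main"], params["beta_int"], params["tau"],
                        params["tau_int"], params["sigma2"], pair_of[j], prior,
                    )
                    - u
                )

            assert joint_at(t1) - joint_at(t2) == pytest.approx(
                cond_at(t1) - cond_at(t2), abs=1e-8
            )

    @pytest.mark.parametrize("variant", ["bayint", "bay0int"])
    def test_sigma2_conditional_matches_joint(self, variant):
        rng = np.random.default_rng(14)
        design = random_continuous_design(rng, n=20, p=3)
        y = rng.normal(size=20)
        prior = PriorSpec(variant=variant)
        params = _random_params(rng, 3, design.q, variant)
        theta = np.concatenate([[params["alpha"]], params["beta_main"], params["beta_int"]])
        W = np.hstack([np.ones((20, 1)), design.X_main, design.X_int])
        rss = float(np.sum((y - W @ theta) ** 2))
        shape, rate = _sigma2_conditional_params(
            rss, params["beta_main"], params["beta_int"], params["tau"],
            params["tau_int"], design.interaction_pairs, 20, prior,
        )
        s1, s2 = 0.7, 2.3
        lhs = log_joint_density({**params, "sigma2": s1}, y, design, prior) - \
            log_joint_density({**params, "sigma2": s2}, y, design, prior)
        rhs = (-(shape + 1) * (np.log(s1) - np.log(s2))) - rate * (1 / s1 - 1 / s2)
        assert lhs == pytest.approx(rhs, abs=1e-8)

    def test_theta_conditional_matches_joint(self):
        rng = np.random.default_rng(15)
        design = random_continuous_design(rng, n=20, p=3)
        y = rng.normal(size=20)
        prior = PriorSpec()
        params = _random_params(rng, 3, design.q)
        W = np.hstack([np.ones((20, 1)), design.X_main, design.X_int])
        A, b = _theta_conditional_params(
            W.T @ W, W.T @ y, params["sigma2"], params["tau"], params["tau_int"],
            design.interaction_pairs, prior,
        )
        d = 1 + 3 + design.q
        th1, th2 = rng.normal(size=d), rng.normal(size=d)

        def joint_at(th):
            return log_joint_density(
                {**params, "alpha": th[0], "beta_main": th[1:4], "beta_int": th[4:]},
                y, design, prior,
            )

        lhs = joint_at(th1) - joint_at(th2)
        rhs = (-0.5 * th1 @ A @ th1 + th1 @ b) - (-0.5 * th2 @ A @ th2 + th2 @ b)
        assert lhs == pytest.approx(rhs, abs=1e-8)


class TestPriorPredictive:
    def test_tau_int_uniform_and_tau_half_cauchy(self):
        prior = PriorSpec()
        draws = sample_prior(prior, p=3, q=3, rng=100, size=4000)
        ti = draws["tau_int"]
        assert ti.min() >= 0.01 and ti.max() <= 1.0
        ks = stats.kstest(ti, stats.uniform(0.01, 0.99).cdf)
        assert ks.pvalue > 0.01
        ks_tau = stats.kstest(draws["tau"].ravel(), stats.halfcauchy(0, 1).cdf)
        assert ks_tau.pvalue > 0.01

    def test_bayint_star_pins_tau_int(self):
        draws = sample_prior(PriorSpec(variant="bayint_star"), p=3, q=3, rng=101, size=200)
        assert np.all(draws["tau_int"] == 1.0)

    def test_variant_prior_variance_monotone_in_tau_int(self):
        """With tau_int pinned at 1, every interaction prior variance is >=
        the same quantity under any tau_int < 1."""
        rng = np.random.default_rng(16)
        pairs = [(0, 1), (0, 2), (1, 2)]
        for _ in range(20):
            tau = np.abs(rng.standard_cauchy(3)) + 0.01
            ti = rng.uniform(0.01, 1.0)
            for variant in ("bayint", "bayintadd"):
                v_star = interaction_relvar(tau, 1.0, pairs, variant)
                v = interaction_relvar(tau, ti, pairs, variant)
                assert np.all(v_star >= v)


class TestFit:
    def test_seed_reproducibility(self):
        rng = np.random.default_rng(17)
        design = random_continuous_design(rng, n=60, p=3)
        y = design.X_main @ np.array([1.0, 0.0, 0.0]) + rng.normal(size=60)
        cfg = MCMCConfig(chains=2, warmup=50, draws=50, seed=5)
        a = ls.fit(y, design, PriorSpec(), cfg)
        b = ls.fit(y, design, PriorSpec(), cfg)
        np.testing.assert_array_equal(a.beta_main, b.beta_main)
        np.testing.assert_array_equal(a.tau_int, b.tau_int)

    def test_zero_signal_intervals_cover_zero(self):
        """Pure-noise response: nearly all interaction intervals cover 0."""
        rng = np.random.default_rng(18)
        design = random_continuous_design(rng, n=400, p=6)
        y = rng.normal(size=400)
        post = ls.fit(y, design, PriorSpec(), MCMCConfig(chains=2, warmup=300, draws=600, seed=7))
        lo, hi = np.quantile(post.beta_int, [0.025, 0.975], axis=0)
        coverage = np.mean((lo <= 0) & (hi >= 0))
        assert coverage >= 0.90

    def test_bayint_star_draws_pin_tau_int(self):
        rng = np.random.default_rng(19)
        design = random_continuous_design(rng, n=50, p=3)
        y = rng.normal(size=50)
        post = ls.fit(
            y, design, PriorSpec(variant="bayint_star"),
            MCMCConfig(chains=1, warmup=30, draws=30, seed=3),
        )
        assert np.all(post.tau_int == 1.0)

    def test_shrinkage_linkage(self):
        """A covariate with a strong main effect earns a larger local scale
        than one with none."""
        rng = np.random.default_rng(20)
        design = random_continuous_design(rng, n=300, p=4)
        beta = np.array([2.5, 0.0, 0.3, 0.0])
        y = design.X_main @ beta + rng.normal(size=300)
        post = ls.fit(y, design, PriorSpec(), MCMCConfig(chains=2, warmup=300, draws=500, seed=9))
        tau_mean = post.tau.mean(axis=0)
        assert tau_mean[0] > tau_mean[1]

    def test_recovery_nonzero_mains(self, sim1_dataset, sim1_fit):
        """Posterior means of the non-zero main effects track the truth."""
        est = sim1_fit.beta_main.mean(axis=0)
        s = sim1_dataset.table.to_numpy().std(ddof=1, axis=0)
        truth = sim1_dataset.truth.beta_main * s
        nz = sim1_dataset.truth.beta_main != 0
        r = np.corrcoef(est[nz], truth[nz])[0, 1]
        assert r > 0.7

    def test_rejects_bad_inputs(self):
        rng = np.random.default_rng(21)
        design = random_continuous_design(rng, n=10, p=2)
        with pytest.raises(ValueError):
            ls.fit(np.array([np.nan] * 10), design)
        with pytest.raises(ValueError):
            ls.fit(np.ones(5), design)


@pytest.fixture(scope="module")
def toy_draws():
    rng = np.random.default_rng(22)
    S = 2000
    return ls.PosteriorDraws(
        alpha=rng.normal(0, 1, S),
        beta_main=np.column_stack([
            rng.normal(2.0, 0.1, S),       # clearly positive
            rng.normal(0.0, 1.0, S),       # symmetric about 0
            np.full(S, 0.7),               # degenerate
        ]),
        beta_int=rng.normal(0, 0.5, (S, 1)),
        tau=np.abs(rng.normal(1, 0.1, (S, 3))),
        tau_int=rng.uniform(0.01, 1, S),
        sigma2=np.abs(rng.normal(1, 0.1, S)),
        n_chains=1,
        variant="bayint",
        main_names=["a", "b", "c"],
        int_names=["a:b"],
    )


class TestSummaries:
    def test_degenerate_draws(self, toy_draws):
        summ = ls.summarize(toy_draws, 0.95).set_index("parameter")
        row = summ.loc["c"]
        assert row["mean"] == pytest.approx(0.7)
        assert row["lower"] == row["upper"] == pytest.approx(0.7)
        assert row["excludes_zero"]

    def test_symmetric_draws_cover_zero(self, toy_draws):
        summ = ls.summarize(toy_draws, 0.95).set_index("parameter")
        row = summ.loc["b"]
        assert row["lower"] < 0 < row["upper"]
        assert not row["excludes_zero"]

    def test_interval_endpoints_are_empirical_quantiles(self, toy_draws):
        summ = ls.summarize(toy_draws, 0.9).set_index("parameter")
        d = toy_draws.beta_main[:, 0]
        assert summ.loc["a", "lower"] == pytest.approx(np.quantile(d, 0.05))
        assert summ.loc["a", "upper"] == pytest.approx(np.quantile(d, 0.95))

    def test_selection_scores_and_special_cases(self, toy_draws):
        sel = ls.select_by_credible_interval(toy_draws, 0.95).set_index("parameter")
        assert sel.loc["a", "selected"]  # all-positive draws
        assert sel.loc["a", "score"] > 0.99
        assert not sel.loc["b", "selected"]  # symmetric about zero
        assert sel.loc["b", "score"] < 0.5

    def test_score_sweep_reproduces_level_selection(self, toy_draws):
        """Thresholding the score at 0.95 equals the 0.95-level selection."""
        sel = ls.select_by_credible_interval(toy_draws, 0.95)
        np.testing.assert_array_equal(sel["selected"], sel["score"] > 0.95)

    def test_level_validation(self, toy_draws):
        with pytest.raises(ValueError):
            ls.summarize(toy_draws, 1.5)

    def test_long_frame_round_trip(self, toy_draws):
        long = toy_draws.to_long_frame()
        sub = long[long["parameter"] == "c"]["value"]
        assert np.all(sub == 0.7)
        assert set(long["parameter"]) >= {"alpha", "a", "a:b", "tau_int", "sigma2"}
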