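import math

import numpy as np
import pytest
from scipy import stats

from baystdetect import (
    McmcSettings,
    PriorConfig,
    SpaceTimePanel,
    area_log_likelihood,
    build_spatial_graph,
    gibbs_update_z,
    log_rate_areaspec,
    log_rate_common,
    run_mcmc,
    sample_icar,
)
from baystdetect.config import ConfigError
from baystdetect.sampler import (
    ModelState,
    initial_state,
    posterior_z_probabilities,
)


def toy_state(n=2, t=2, seed=0, **kw):
    rng = np.random.default_rng(seed)
    defaults = dict(
        alpha0=0.3, h=rng.normal(0, 0.2, n), v=np.zeros(n),
        gamma=rng.normal(0, 0.2, t), u=rng.normal(0, 0.3, n),
        K=rng.normal(0, 0.2, (n, t)), z=np.ones(n, dtype=np.int8),
        sigma_h=0.5, sigma_v=0.5, sigma_gamma=0.5,
        log_var_ik=np.zeros(n), a=0.0, b=1.0, beta=np.array([]),
    )
    defaults.update(kw)
    return ModelState(**defaults)


def toy_panel(n=2, t=2, seed=1, X=None):
    rng = np.random.default_rng(seed)
    return SpaceTimePanel(
        y=rng.poisson(30, (n, t)),
        E=np.full(n, 25.0),
        area_labels=tuple(f"a{i}" for i in range(n)),
        time_labels=tuple(f"t{j}" for j in range(t)),
        X=X,
    )


class TestLogRates:
    def test_all_zero_fields_give_zero(self):
        st_ = toy_state(h=np.zeros(2), gamma=np.zeros(2), alpha0=0.0,
                        u=np.zeros(2), K=np.zeros((2, 2)))
        p = toy_panel()
        assert log_rate_common(st_, p, 0, 0) == 0.0
        assert log_rate_areaspec(st_, p, 0, 0) == 0.0

    def test_additive_composition(self):
        st_ = toy_state(alpha0=1.0, h=np.array([0.2, 0.0]),
                        gamma=np.array([-0.1, 0.1]))
        assert log_rate_common(st_, toy_panel(), 0, 0) == pytest.approx(1.1)
        st2 = toy_state(u=np.array([0.5, 0.0]), K=np.array([[-0.5, 0.5], [0, 0]]))
        assert log_rate_areaspec(st2, toy_panel(), 0, 0) == pytest.approx(0.0)

    def test_covariates_enter_both_components(self):
        X = np.array([[1.0], [-1.0]])
        p = toy_panel(X=X)
        st_ = toy_state(beta=np.array([0.25]))
        base = log_rate_common(toy_state(beta=np.array([0.0])), p, 0, 1)
        assert log_rate_common(st_, p, 0, 1) == pytest.approx(base + p.X[0, 0] * 0.25)
        assert log_rate_areaspec(st_, p, 0, 1) - log_rate_areaspec(
            st_, p, 0, 1, covariates_in_areaspec=False
        ) == pytest.approx(p.X[0, 0] * 0.25)


class TestAreaLogLikelihood:
    def test_zero_counts_unit_expected(self):
        p = SpaceTimePanel(
            y=np.zeros((1, 4), dtype=int), E=np.ones(1),
            area_labels=("a",), time_labels=("1", "2", "3", "4"),
        )
        assert area_log_likelihood(p, np.zeros(4), 0) == pytest.approx(-4.0)

    def test_matches_scipy_poisson_logpmf(self):
        p = toy_panel(n=2, t=2, seed=3)
        ell = np.array([0.1, -0.2])
        mine = area_log_likelihood(p, ell, 1)
        oracle = stats.poisson.logpmf(p.y[1], p.E[1] * np.exp(ell)).sum()
        assert mine == pytest.approx(oracle, rel=1e-12)

    def test_maximised_at_observed_rate(self):
        p = toy_panel(n=1, t=3, seed=4)
        ell_hat = np.log(p.y[0] / p.E[0])
        best = area_log_likelihood(p, ell_hat, 0)
        for eps in (-0.01, 0.01):
            assert area_log_likelihood(p, ell_hat + eps, 0) < best

    def test_overflow_yields_neg_inf_not_nan(self):
        p = toy_panel()
        with np.errstate(over="ignore"):
            ll = area_log_likelihood(p, np.array([1e4, 0.0]), 0)
        assert ll == -np.inf


class TestGibbsZ:
    def test_equal_evidence_recovers_prior(self):
        st_ = toy_state(alpha0=0.0, h=np.zeros(2), gamma=np.zeros(2),
                        u=np.zeros(2), K=np.zeros((2, 2)))
        p = toy_panel()
        probs = posterior_z_probabilities(st_, p, PriorConfig(pi=0.95))
        assert np.allclose(probs, 0.95)

    def test_strong_dominance(self):
        # area-specific rates match the data far better: z -> 0 a.s.
        p = toy_panel(n=1, t=2, seed=5)
        good = np.log(p.y[0] / p.E[0])
        st_ = toy_state(
            n=1, alpha0=3.0, h=np.zeros(1), gamma=np.zeros(2),
            u=np.array([good.mean()]), K=(good - good.mean())[None, :],
        )
        probs = posterior_z_probabilities(st_, p, PriorConfig())
        assert probs[0] < 1e-10
        z = gibbs_update_z(st_, p, PriorConfig(), np.random.default_rng(0))
        assert z[0] == 0

    def test_matches_two_term_bayes_oracle(self):
        p = toy_panel(n=3, t=4, seed=6)
        st_ = toy_state(n=3, t=4, seed=7)
        pi = 0.9
        probs = posterior_z_probabilities(st_, p, PriorConfig(pi=pi))
        for i in range(3):
            lc = area_log_likelihood(p, [log_rate_common(st_, p, i, t) for t in range(4)], i)
            la = area_log_likelihood(p, [log_rate_areaspec(st_, p, i, t) for t in range(4)], i)
            num = pi * math.exp(lc - max(lc, la))
            den = num + (1 - pi) * math.exp(la - max(lc, la))
            assert probs[i] == pytest.approx(num / den, rel=1e-10)

    def test_pi_endpoints_degenerate(self):
        st_ = toy_state()
        p = toy_panel()
        assert np.all(posterior_z_probabilities(st_, p, PriorConfig(pi=1.0)) == 1.0)
        assert np.all(posterior_z_probabilities(st_, p, PriorConfig(pi=0.0)) == 0.0)


def small_run(panel, graph, priors=None, **kw):
    settings = dict(n_chains=2, n_iter=1200, n_burnin=400, thin=2, seed=3)
    settings.update(kw)
    return run_mcmc(panel, graph, priors or PriorConfig(), McmcSettings(**settings))


class TestRunMcmc:
    def test_same_seed_identical_chains(self, small_panel):
        panel, _, graph = small_panel
        s1 = small_run(panel, graph)
        s2 = small_run(panel, graph)
        for name in s1.draws:
            assert np.array_equal(s1.draws[name], s2.draws[name])

    def test_different_seeds_differ(self, small_panel):
        panel, _, graph = small_panel
        s1 = small_run(panel, graph, seed=3)
        s2 = small_run(panel, graph, seed=4)
        assert not np.array_equal(s1.draws["gamma"], s2.draws["gamma"])

    def test_identifiability_constraints_every_draw(self, small_fit):
        panel, truth, graph, samples = small_fit
        gam = samples.stacked("gamma")
        assert np.all(np.abs(gam.sum(axis=1)) < 1e-8)
        K = samples.stacked("K")
        assert np.all(np.abs(K.sum(axis=2)) < 1e-8)
        v = samples.stacked("v")  # grid is connected: one global constraint
        assert np.all(np.abs(v.sum(axis=1)) < 1e-8)

    def test_acceptance_rates_in_target_band(self, small_fit):
        _, _, _, samples = small_fit
        for name in ("h", "u", "K", "gamma"):
            assert 0.25 < samples.acceptance[name] < 0.6, name

    def test_stored_draw_count_and_finiteness(self, small_fit):
        _, _, _, samples = small_fit
        assert samples.n_stored == (1500 - 500) // 2
        for name, arr in samples.draws.items():
            assert np.isfinite(arr).all(), name

    def test_graph_panel_mismatch_rejected(self, small_panel):
        panel, _, _ = small_panel
        other = build_spatial_graph([], [f"x{i}" for i in range(panel.n_areas)])
        from baystdetect.sampler import McmcError

        with pytest.raises(McmcError, match="match"):
            small_run(panel, other)

    def test_invalid_settings_rejected(self):
        with pytest.raises(ConfigError):
            McmcSettings(n_iter=100, n_burnin=200)
        with pytest.raises(ConfigError):
            McmcSettings(thin=0)


@pytest.fixture(scope="module")
def prior_draws(small_panel):
    panel, _, graph = small_panel
    return run_mcmc(
        panel, graph, PriorConfig(likelihood_off=True),
        McmcSettings(n_chains=1, n_iter=4500, n_burnin=500, thin=1, seed=21),
    )


class TestPriorRecovery:
    """With the likelihood disabled the sampler must reproduce its priors."""

    def test_scale_marginals_half_normal(self, prior_draws):
        for name in ("sigma_h", "sigma_v", "sigma_gamma"):
            d = prior_draws.stacked(name)
            ks = stats.kstest(d, stats.halfnorm(scale=1.0).cdf)
            assert ks.pvalue > 0.001, (name, ks)

    def test_field_marginal_matches_icar_sampler(self, prior_draws, small_panel):
        # gamma_1 draws vs direct constrained-ICAR draws at matched sigma
        from baystdetect import build_temporal_graph, icar_structure

        panel, _, _ = small_panel
        g = prior_draws.stacked("gamma")[:, 1]
        sig = prior_draws.stacked("sigma_gamma")
        ts = icar_structure(build_temporal_graph(panel.n_times))
        rng = np.random.default_rng(0)
        ref = np.array([sample_icar(ts, s, rng)[1] for s in sig[:2000]])
        ks = stats.ks_2samp(g[:2000], ref)
        assert ks.pvalue > 0.001

    def test_z_matches_bernoulli_prior(self, prior_draws):
        z = prior_draws.stacked("z").ravel()
        bt = stats.binomtest(int(z.sum()), len(z), 0.95)
        assert bt.pvalue > 0.001


class TestConjugateAUpdate:
    def test_posterior_moments_match_closed_form(self, small_panel):
        from baystdetect.graphs import icar_structure, build_temporal_graph
        from baystdetect.sampler import _ChainRunner

        panel, _, graph = small_panel
        priors = PriorConfig(fixed_scales={
            "sigma_h": 0.5, "sigma_v": 0.5, "sigma_gamma": 0.5,
            "sigma_ik": 0.5, "b": 0.8,
        })
        runner = _ChainRunner(
            panel, icar_structure(graph),
            icar_structure(build_temporal_graph(panel.n_times)),
            priors, McmcSettings(n_iter=100, n_burnin=10),
            np.random.default_rng(12),
        )
        c, b = 1.7, 0.8
        st_ = initial_state(panel, priors, np.random.default_rng(0))
        st_.log_var_ik = np.full(panel.n_areas, c)
        st_.b = b
        draws = []
        for _ in range(4000):
            runner.update_scales(st_, adapt_rate=0.0)
            draws.append(st_.a)
        draws = np.asarray(draws)
        prec = panel.n_areas / b**2 + 1.0 / priors.a_prior_var
        mean = panel.n_areas * c / b**2 / prec
        assert draws.mean() == pytest.approx(mean, abs=4 * (1 / np.sqrt(prec)) / np.sqrt(len(draws)) + 1e-3)
        assert draws.std() == pytest.approx(1 / np.sqrt(prec), rel=0.1)


class TestShrinkageLimit:
    def test_tiny_b_pulls_sigma_ik_to_exp_half_a(self, small_panel):
        from baystdetect.graphs import icar_structure, build_temporal_graph
        from baystdetect.sampler import _ChainRunner

        panel, _, graph = small_panel
        priors = PriorConfig(fixed_scales={
            "sigma_h": 0.5, "sigma_v": 0.5, "sigma_gamma": 0.5,
            "a": -2.0, "b": 1e-3,
        })
        runner = _ChainRunner(
            panel, icar_structure(graph),
            icar_structure(build_temporal_graph(panel.n_times)),
            priors, McmcSettings(n_iter=100, n_burnin=10),
            np.random.default_rng(5),
        )
        st_ = initial_state(panel, priors, np.random.default_rng(1))
        st_.K = np.zeros_like(st_.K)
        st_.a, st_.b = -2.0, 1e-3
        for _ in range(800):
            runner.update_scales(st_, adapt_rate=0.05)
        assert np.allclose(st_.log_var_ik, -2.0, atol=0.05)
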