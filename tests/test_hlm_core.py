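"""Model density, prior elicitation, sampler and convergence diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bivgrowth import hlm_core as hc
from bivgrowth import synthetic_cohort as sc

_LOG2PI = np.log(2 * np.pi)


def brute_force_log_joint(params, data, spec):
    """Independent term-by-term reference density (kept deliberately naive)."""
    beta = np.asarray(params["beta"], float)
    tau = np.asarray(params["tau"], float)
    lam = np.asarray(params["lambda_corr"], float)
    sigma_e = np.asarray(params["sigma_e"], float)
    omega = np.diag(tau) @ lam @ np.diag(tau)
    lp = 0.0
    if spec.prior_beta_loc is not None:
        for j in range(4):
            lp += stats.norm.logpdf(beta[j], spec.prior_beta_loc[j],
                                    spec.prior_beta_scale[j])
    for t in tau:
        lp += np.log(2.0) + stats.cauchy.logpdf(t, scale=spec.prior_tau_scale)
    lp += (spec.prior_lambda_shape - 1.0) * np.log(np.linalg.det(lam))
    for s in sigma_e:
        lp += stats.invgamma.logpdf(s, spec.prior_sigma_e_shape,
                                    scale=spec.prior_sigma_e_scale)
    for cid, e in params.get("eta", {}).items():
        lp += stats.multivariate_normal.logpdf(e, beta, omega)
    if data is not None:
        for _, row in data.iterrows():
            e = params["eta"][row["child_id"]]
            lp += stats.norm.logpdf(row["log_height"],
                                    e[0] + e[2] * row["a"], sigma_e[0])
            lp += stats.norm.logpdf(row["log_weight"],
                                    e[1] + e[3] * row["a"], sigma_e[1])
    return lp


def _params(eta=None, beta=None, tau=None, lam=None, sigma_e=None):
    return {
        "beta": np.zeros(4) if beta is None else beta,
        "tau": np.ones(4) if tau is None else tau,
        "lambda_corr": np.eye(4) if lam is None else lam,
        "sigma_e": np.ones(2) if sigma_e is None else sigma_e,
        "eta": eta or {},
    }


class TestLogJoint:
    def test_single_visit_at_conditional_mean_gives_std_normal_peak(self):
        eta = {"a": np.array([0.1, 2.5, 0.0, 0.0])}
        data = pd.DataFrame({"child_id": ["a"], "a": [0.0],
                             "log_height": [0.1], "log_weight": [2.5]})
        spec = hc.HLMSpec()
        with_obs = hc.log_joint(_params(eta), data, spec)
        without = hc.log_joint(_params(eta), None, spec)
        assert with_obs - without == pytest.approx(2 * (-0.5 * _LOG2PI))

    def test_level2_term_identity_omega_eta_at_beta(self):
        spec = hc.HLMSpec()
        with_eta = hc.log_joint(_params({"a": np.zeros(4)}), None, spec)
        without = hc.log_joint(_params(), None, spec)
        assert with_eta - without == pytest.approx(4 * (-0.5 * _LOG2PI))

    def test_matches_brute_force_reference_on_random_instance(self, rng):
        spec = hc.HLMSpec(prior_beta_loc=np.array([0.1, 2.5, 0.05, 0.1]),
                          prior_beta_scale=np.array([1.0, 1.0, 0.5, 0.5]))
        lam = np.eye(4)
        lam[0, 1] = lam[1, 0] = 0.3
        params = _params(
            eta={"a": rng.normal(size=4) * 0.1 + [0, 2.5, 0, 0],
                 "b": rng.normal(size=4) * 0.1 + [0, 2.5, 0, 0]},
            beta=np.array([0.05, 2.55, 0.06, 0.12]),
            tau=np.array([0.5, 0.4, 0.2, 0.3]), lam=lam,
            sigma_e=np.array([0.1, 0.2]))
        data = pd.DataFrame({
            "child_id": ["a", "a", "b"], "a": [0.0, 1.3, 2.0],
            "log_height": [0.02, 0.1, 0.2], "log_weight": [2.5, 2.6, 2.8]})
        ours = hc.log_joint(params, data, spec)
        ref = brute_force_log_joint(params, data, spec)
        assert ours == pytest.approx(ref, rel=1e-10)

    def test_out_of_support_returns_neg_inf_not_exception(self):
        p = _params(tau=np.array([1.0, -1.0, 1.0, 1.0]))
        assert hc.log_joint(p, None, hc.HLMSpec()) == -np.inf
        p = _params(sigma_e=np.array([0.0, 1.0]))
        assert hc.log_joint(p, None, hc.HLMSpec()) == -np.inf

    def test_likelihood_portion_doubles_when_data_doubled(self, rng):
        eta = {"a": np.array([0.05, 2.5, 0.02, 0.1])}
        data = pd.DataFrame({"child_id": ["a", "a"], "a": [0.5, 1.5],
                             "log_height": [0.05, 0.1],
                             "log_weight": [2.55, 2.7]})
        doubled = pd.concat([data, data], ignore_index=True)
        spec = hc.HLMSpec()
        base = hc.log_joint(_params(eta), None, spec)
        lik1 = hc.log_joint(_params(eta), data, spec) - base
        lik2 = hc.log_joint(_params(eta), doubled, spec) - base
        assert lik2 == pytest.approx(2 * lik1, rel=1e-12)


class TestElicitBetaPrior:
    def test_noise_free_line_recovered_exactly(self):
        a = np.array([0.0, 1.0, 2.0, 3.0])
        frame = pd.DataFrame({"a": a, "log_height": 0.1 + 0.02 * a,
                              "log_weight": 2.5 + 0.13 * a})
        loc, scale = hc.elicit_beta_prior(frame)
        assert loc == pytest.approx([0.1, 2.5, 0.02, 0.13])
        assert np.all(scale > 0)

    def test_degenerate_design_rejected(self):
        frame = pd.DataFrame({"a": [1.0, 1.0], "log_height": [0.1, 0.2],
                              "log_weight": [2.5, 2.6]})
        with pytest.raises(ValueError):
            hc.elicit_beta_prior(frame)

    def test_consistent_with_truth_on_small_fixture(self, small):
        loc, scale = hc.elicit_beta_prior(small["frame1"])
        true_beta = sc.default_true_params()["model1"].beta
        # pooled OLS ignores within-child correlation; its point estimate is
        # still consistent for beta
        assert np.all(np.abs(loc - true_beta) < 3 * (scale / 10.0) + 0.02)


class TestDiagnostics:
    def test_rhat_near_one_for_iid_chains(self, rng):
        chains = rng.standard_normal((2, 1000))
        assert 0.99 <= hc.split_rhat(chains) <= 1.01

    def test_rhat_large_for_separated_chains(self, rng):
        chains = np.stack([rng.standard_normal(500),
                           rng.standard_normal(500) + 10])
        assert hc.split_rhat(chains) > 1.5

    def test_rhat_constant_chains_is_one_by_convention(self):
        assert hc.split_rhat(np.ones((2, 100))) == 1.0

    def test_ess_iid_near_total(self, rng):
        chains = rng.standard_normal((4, 1000))
        assert 3000 <= hc.effective_sample_size(chains) <= 5000

    def test_ess_ar1_matches_closed_form_within_factor(self, rng):
        rho, n = 0.9, 20000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * np.sqrt(1 - rho**2)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + eps[t]
        expected = n * (1 - rho) / (1 + rho)
        got = hc.effective_sample_size(x[None, :])
        assert expected / 1.5 <= got <= expected * 1.5

    def test_ess_constant_chain_returns_total(self):
        assert hc.effective_sample_size(np.ones((1, 4000))) == 4000

    def test_against_arviz_on_well_mixed_chains(self, rng):
        import arviz as az
        chains = rng.standard_normal((4, 500)) + 0.05 * rng.standard_normal((4, 500))
        ours_rhat = hc.split_rhat(chains)
        az_rhat = float(az.rhat(az.convert_to_dataset(chains))["x"].values)
        assert ours_rhat == pytest.approx(az_rhat, abs=0.05)
        ours_ess = hc.effective_sample_size(chains)
        az_ess = float(az.ess(az.convert_to_dataset(chains))["x"].values)
        assert ours_ess == pytest.approx(az_ess, rel=0.3)


def _fake_draws(beta, tau, lam, sigma_e):
    S = beta.shape[0]
    return hc.PosteriorDraws(
        child_ids=[], beta_c=beta[None], tau_c=tau[None],
        lambda_c=lam[None], sigma_e_c=sigma_e[None],
        eta=np.zeros((1, 0, 4)))


class TestPluginEstimates:
    def test_single_draw_returned_as_is(self):
        beta = np.array([[0.1, 2.5, 0.05, 0.1]])
        tau = np.array([[0.1, 0.2, 0.05, 0.05]])
        d = _fake_draws(beta, tau, np.eye(4)[None].repeat(1, 0),
                        np.array([[0.01, 0.02]]))
        p = hc.plugin_estimates(d)
        assert np.allclose(p["beta_hat"], beta[0])
        assert np.allclose(p["sigma_e_hat"], [0.01, 0.02])

    def test_two_draws_give_midpoint(self):
        beta = np.array([[0.0, 2.0, 0.0, 0.0], [0.2, 3.0, 0.1, 0.2]])
        tau = np.ones((2, 4)) * 0.1
        d = _fake_draws(beta, tau, np.eye(4)[None].repeat(2, 0),
                        np.array([[0.01, 0.02], [0.03, 0.04]]))
        p = hc.plugin_estimates(d)
        assert np.allclose(p["beta_hat"], [0.1, 2.5, 0.05, 0.1])
        assert np.allclose(p["sigma_e_hat"], [0.02, 0.03])

    def test_common_tau_identity_lambda_gives_diag_tau_squared(self):
        tau = np.tile([0.1, 0.2, 0.3, 0.4], (5, 1))
        d = _fake_draws(np.zeros((5, 4)), tau, np.eye(4)[None].repeat(5, 0),
                        np.full((5, 2), 0.01))
        p = hc.plugin_estimates(d)
        assert np.allclose(p["omega_hat"], np.diag([0.01, 0.04, 0.09, 0.16]))


class TestSampler:
    def test_omega_decomposition_holds_per_draw(self, small):
        d, _ = hc.fit(small["frame1"].iloc[:200], hc.HLMSpec(),
                      hc.SamplerConfig(chains=1, warmup=50, draws=50,
                                       thin=1, seed=0, m_retained=10))
        omega = d.omega
        rebuilt = d.tau[:, :, None] * d.lambda_corr * d.tau[:, None, :]
        assert np.allclose(omega, rebuilt, rtol=1e-8)
        # every correlation draw: unit diagonal, PSD
        assert np.allclose(np.diagonal(d.lambda_corr, axis1=1, axis2=2), 1.0)
        assert min(np.linalg.eigvalsh(l).min() for l in d.lambda_corr) > -1e-10

    def test_same_seed_reproduces_draw_summaries(self, small):
        cfg = hc.SamplerConfig(chains=1, warmup=50, draws=50, thin=1, seed=12,
                               m_retained=10)
        d1, _ = hc.fit(small["frame1"], hc.HLMSpec(), cfg)
        d2, _ = hc.fit(small["frame1"], hc.HLMSpec(), cfg)
        assert np.array_equal(d1.beta, d2.beta)
        assert np.array_equal(d1.eta, d2.eta)

    def test_prior_only_run_recovers_beta_prior_moments(self):
        loc = np.array([0.1, 2.5, 0.05, 0.1])
        scale = np.array([0.5, 0.5, 0.2, 0.2])
        spec = hc.HLMSpec(prior_beta_loc=loc, prior_beta_scale=scale)
        d, _ = hc.fit(None, spec, hc.SamplerConfig(chains=2, warmup=100,
                                                   draws=2000, thin=1, seed=4,
                                                   m_retained=10))
        n = d.beta.shape[0]
        mc_se = scale / np.sqrt(n)
        assert np.all(np.abs(d.beta.mean(0) - loc) < 3 * mc_se)
        assert np.all(np.abs(d.beta.std(0) - scale) < 4 * scale / np.sqrt(n))

    def test_fewer_than_two_children_rejected(self):
        frame = pd.DataFrame({"child_id": ["a", "a"], "a": [0.0, 1.0],
                              "log_height": [0.1, 0.15],
                              "log_weight": [2.5, 2.6]})
        with pytest.raises(ValueError):
            hc.fit(frame, hc.HLMSpec(), hc.SamplerConfig())

    def test_retains_m_eta_draws_for_every_child(self, small):
        cfg = hc.SamplerConfig(chains=2, warmup=50, draws=100, thin=1,
                               seed=0, m_retained=40)
        d, _ = hc.fit(small["frame1"], hc.HLMSpec(), cfg)
        n_children = small["frame1"]["child_id"].nunique()
        assert d.eta.shape == (40, n_children, 4)
        assert d.m == 40
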