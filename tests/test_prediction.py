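"""Routing, the three prediction approaches, and the age-6 handoff."""

import numpy as np
import pytest

from bivgrowth import hlm_core as hc
from bivgrowth import prediction as pr
from bivgrowth.cohort_data import GroupAssignment


def ga(cid="a", contributing=True, target=True, models=("model1",), age=5):
    return GroupAssignment(
        child_id=cid, in_contributing=contributing, in_target=target,
        in_contributing_2021=contributing and target,
        model_membership=frozenset(models), age_in_2021=age)


class TestRoute:
    @pytest.mark.parametrize("age,models,expected", [
        (4, ("model1",), "M1_direct"),
        (5, ("model1",), "M1_direct"),
        (7, ("model1",), "M1_handoff_age6"),
        (9, ("model2",), "M2_direct"),
        (9, ("model1", "model2"), "M2_preferred"),
        (8, (), "POP"),
        (5, (), "POP"),
    ])
    def test_routing_table(self, age, models, expected):
        child = ga(models=models, age=age, contributing=bool(models))
        assert pr.route(child) == expected

    def test_age_outside_target_range_rejected(self):
        with pytest.raises(ValueError):
            pr.route(ga(age=3))
        with pytest.raises(ValueError):
            pr.route(ga(age=None, target=False, contributing=False, models=()))


class TestPredictIndividual:
    def test_point_mass_posterior_gives_exact_line(self):
        eta = np.tile([0.1, 2.5, 0.05, 0.12], (50, 1))
        out = pr.predict_individual(eta, np.array([0.01, 0.02]), age=2.5)
        assert out["mean_log"] == pytest.approx([0.225, 2.8])
        assert np.allclose(out["var_log"], 0.0)

    def test_age_zero_returns_mean_intercept(self, rng):
        eta = rng.normal(size=(200, 4))
        out = pr.predict_individual(eta, np.array([0.01, 0.02]), age=0.0)
        assert out["mean_log"] == pytest.approx(eta[:, :2].mean(0))

    def test_sampling_mode_agrees_with_closed_form(self, rng):
        eta = rng.normal(size=(100, 4)) * 0.05 + [0.1, 2.5, 0.05, 0.12]
        sig = np.array([0.05, 0.08])
        cf = pr.predict_individual(eta, sig, age=1.5)
        mc = pr.predict_individual(eta, sig, age=1.5, mode="sampling",
                                   k=100_000, seed=1)
        se = sig / np.sqrt(100 * 100_000)
        assert np.all(np.abs(cf["mean_log"] - mc["mean_log"]) < 5 * se + 1e-4)

    def test_sampling_mode_requires_positive_k(self):
        with pytest.raises(ValueError):
            pr.predict_individual(np.zeros((5, 4)), np.ones(2), 1.0,
                                  mode="sampling", k=0)


class TestPredictPopulation:
    def test_degenerate_population_collapses_to_mean_line(self):
        beta = np.array([0.1, 2.5, 0.05, 0.12])
        out = pr.predict_population(beta, np.zeros((4, 4)), np.array([0.01, 0.02]),
                                    age=2.0, n_children=50, seed=0)
        assert np.allclose(out["mean_log"], [0.2, 2.74])

    def test_between_child_variance_matches_closed_form(self, rng):
        tau = np.array([0.05, 0.1, 0.01, 0.02])
        omega = np.diag(tau**2)
        beta = np.array([0.1, 2.5, 0.05, 0.12])
        a = 3.0
        out = pr.predict_population(beta, omega, np.zeros(2), age=a,
                                    n_children=10_000, seed=3)
        expect = np.array([tau[0]**2 + a**2 * tau[2]**2,
                           tau[1]**2 + a**2 * tau[3]**2])
        emp = out["mean_log"].var(axis=0, ddof=1)
        assert np.all(np.abs(emp - expect) < 4 * np.sqrt(2.0 / 10_000) * expect)

    def test_same_seed_identical(self):
        beta = np.array([0.1, 2.5, 0.05, 0.12])
        omega = np.eye(4) * 0.01
        kw = dict(age=1.0, n_children=20, seed=9)
        a = pr.predict_population(beta, omega, np.ones(2) * 0.01, **kw)
        b = pr.predict_population(beta, omega, np.ones(2) * 0.01, **kw)
        assert np.array_equal(a["mean_log"], b["mean_log"])


class TestHandoff:
    def _plugins(self, omega):
        return {"beta_hat": np.array([0.2, 3.1, 0.04, 0.11]),
                "omega_hat": omega}

    def test_zero_cross_covariance_slopes_marginal(self, rng):
        omega = np.diag([0.04**2, 0.15**2, 0.004**2, 0.02**2])
        eta1 = rng.normal(size=(4000, 4)) * 0.02 + [0.1, 2.6, 0.07, 0.13]
        out = pr.handoff_age6(eta1, self._plugins(omega), seed=0)
        # slopes ~ N(beta slopes, slope block), independent of intercepts
        assert out[:, 2].mean() == pytest.approx(0.04, abs=4 * 0.004 / 63)
        assert out[:, 3].mean() == pytest.approx(0.11, abs=4 * 0.02 / 63)
        assert out[:, 2].std() == pytest.approx(0.004, rel=0.1)

    def test_intercept_is_model1_value_at_age_six(self):
        eta1 = np.tile([0.1, 2.6, 0.07, 0.13], (10, 1))
        omega = np.eye(4) * 1e-18
        out = pr.handoff_age6(eta1, self._plugins(omega), seed=0)
        assert np.allclose(out[:, 0], 0.1 + 4 * 0.07)
        assert np.allclose(out[:, 1], 2.6 + 4 * 0.13)
        # with omega ~ 0 the prediction at age 6 equals the model-1 value
        summ = pr.predict_individual(out, np.zeros(2), age=0.0)
        assert summ["mean_log"] == pytest.approx([0.38, 3.12])

    def test_conditional_moments_match_gaussian_oracle(self, rng):
        # full covariance with intercept-slope correlation
        tau = np.array([0.05, 0.12, 0.01, 0.03])
        corr = np.eye(4)
        corr[0, 2] = corr[2, 0] = -0.4
        corr[1, 3] = corr[3, 1] = 0.5
        omega = np.outer(tau, tau) * corr
        plug = self._plugins(omega)
        intercept = np.array([0.3, 3.4])
        eta1 = np.tile([intercept[0] - 0.0, intercept[1], 0.0, 0.0], (40_000, 1))
        out = pr.handoff_age6(eta1, plug, seed=5)
        # oracle: conditional normal formulas evaluated directly
        sii, sis, sss = omega[:2, :2], omega[:2, 2:], omega[2:, 2:]
        C = sis.T @ np.linalg.inv(sii)
        mu = plug["beta_hat"][2:] + C @ (intercept - plug["beta_hat"][:2])
        Sc = sss - C @ sis
        assert np.allclose(out[:, 2:].mean(0), mu, atol=4 * np.sqrt(np.diag(Sc).max() / 40_000))
        # off-diagonal sampling error ~ sqrt(Sc00*Sc11/n)
        atol = 4 * np.sqrt(Sc[0, 0] * Sc[1, 1] / 40_000)
        assert np.allclose(np.cov(out[:, 2:].T), Sc, rtol=0.08, atol=atol)


class TestCombined:
    def _fits_plugins(self, rng, child_ids):
        eta = rng.normal(size=(30, len(child_ids), 4)) * 0.02
        eta += np.array([0.1, 2.5, 0.05, 0.12])
        fits = {
            "model1": hc.PosteriorDraws(
                child_ids=list(child_ids), beta_c=np.zeros((1, 2, 4)),
                tau_c=np.ones((1, 2, 4)) * 0.1,
                lambda_c=np.eye(4)[None, None].repeat(2, 1)[0][None].repeat(1, 0),
                sigma_e_c=np.full((1, 2, 2), 0.02), eta=eta),
        }
        fits["model2"] = fits["model1"]
        plugins = {m: {"beta_hat": np.array([0.1, 2.5, 0.05, 0.12]),
                       "omega_hat": np.eye(4) * 0.01,
                       "sigma_e_hat": np.array([0.01, 0.02])}
                   for m in fits}
        return fits, plugins

    def test_all_contributing_equals_pred_i(self, rng):
        ids = ["a", "b", "c"]
        fits, plugins = self._fits_plugins(rng, ids)
        target = [ga(cid=c, age=5) for c in ids]
        pc = pr.predict_combined(target, fits, plugins, seed=1)
        pi = pr.predict_individual_set(target, fits, plugins, seed=1)
        cols = ["child_id", "mean_log_h", "mean_log_w"]
        assert pc.table[cols].equals(pi.table[cols])
        assert set(pc.table["source_rule"]) == {"M1_direct"}

    def test_no_contributing_equals_pred_p(self, rng):
        fits, plugins = self._fits_plugins(rng, [])
        target = [ga(cid=f"n{i}", contributing=False, models=(), age=8)
                  for i in range(5)]
        pc = pr.predict_combined(target, fits, plugins, seed=2)
        pp = pr.predict_population_set(target, plugins, seed=2)
        cols = ["child_id", "mean_log_h", "mean_log_w"]
        assert pc.table[cols].reset_index(drop=True).equals(
            pp.table[cols].reset_index(drop=True))

    def test_source_rules_match_independent_routing(self, rng):
        ids = ["a", "b"]
        fits, plugins = self._fits_plugins(rng, ids)
        target = [ga(cid="a", age=4),
                  ga(cid="b", age=9, models=("model1", "model2")),
                  ga(cid="n1", contributing=False, models=(), age=7)]
        pc = pr.predict_combined(target, fits, plugins, seed=3)
        rules = dict(zip(pc.table["child_id"], pc.table["source_rule"]))
        for g in target:
            assert rules[g.child_id] == pr.route(g)

    def test_replicates_fix_pred_i_and_vary_pop(self, rng):
        ids = ["a"]
        fits, plugins = self._fits_plugins(rng, ids)
        target = [ga(cid="a", age=4),
                  ga(cid="n1", contributing=False, models=(), age=7),
                  ga(cid="n2", contributing=False, models=(), age=7)]
        reps = pr.replicate_predictions("pred_c", target, fits, plugins,
                                        reps=3, seed=4)
        assert len(reps) == 3
        t0, t1 = reps[0].table, reps[1].table
        a0 = t0[t0["child_id"] == "a"].iloc[0]
        a1 = t1[t1["child_id"] == "a"].iloc[0]
        assert a0["mean_log_w"] == a1["mean_log_w"]
        n0 = t0[t0["child_id"] == "n1"].iloc[0]
        n1 = t1[t1["child_id"] == "n1"].iloc[0]
        assert n0["mean_log_w"] != n1["mean_log_w"]

    def test_single_replicate_allowed_zero_rejected(self, rng):
        fits, plugins = self._fits_plugins(rng, ["a"])
        target = [ga(cid="a", age=4)]
        assert len(pr.replicate_predictions("pred_i", target, fits, plugins,
                                            reps=1, seed=0)) == 1
        with pytest.raises(ValueError):
            pr.replicate_predictions("pred_i", target, fits, plugins, reps=0)

    def test_natural_scale_outputs_positive(self, rng):
        fits, plugins = self._fits_plugins(rng, ["a"])
        target = [ga(cid="a", age=4)]
        nat = pr.predict_combined(target, fits, plugins, seed=0).natural()
        assert (nat["height_cm"] > 0).all() and (nat["weight_kg"] > 0).all()
        assert nat["height_cm"].iloc[0] > 50  # cm, not metres
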