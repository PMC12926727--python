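"""Target-year prediction under three approaches.

Pred-I uses each contributing child's own posterior effect draws; Pred-P
draws fresh effects from the population law N(beta_hat, Omega_hat) for
every target child; Pred-C routes each child to Pred-I when individual
parameters exist and Pred-P otherwise.

Children measured at ages 4-5 in the target year are predicted from the
age 2-5 model.  Children aged 6-11 use the age 6-11 model when they
contributed to it; a child with only age 2-5 history is handed over: its
model-1 posterior value at age 6 becomes the model-2 individual intercept,
with the slope drawn from the model-2 conditional normal given that
intercept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from bivgrowth.cohort_data import GroupAssignment, MODEL1_CENTER, MODEL2_CENTER

logger = logging.getLogger(__name__)

ROUTING_LABELS = ("M1_direct", "M1_handoff_age6", "M2_direct", "M2_preferred", "POP")


def route(child: GroupAssignment) -> str:
    """Routing label for one target-group child (see module docstring)."""
    if child.age_in_2021 is None or not (4 <= child.age_in_2021 <= 11):
        raise ValueError(f"child {child.child_id} has no target age in 4-11")
    mm = child.model_membership
    if child.age_in_2021 <= 5:
        return "M1_direct" if "model1" in mm else "POP"
    if "model2" in mm:
        return "M2_preferred" if "model1" in mm else "M2_direct"
    if "model1" in mm:
        return "M1_handoff_age6"
    return "POP"


@dataclass
class PredictionSet:
    """Per-child posterior-predictive summaries under one approach.

    `table` columns: child_id, age_at_target (fractional years), age_year,
    source_rule, mean_log_h, mean_log_w (m_i on the log scale), var_log_h,
    var_log_w (v_i).  Natural-scale height (cm), weight (kg) and BMI are
    derived by exponentiation.
    """

    approach: str
    replicate_id: int
    seed: int
    k: int
    table: pd.DataFrame

    def natural(self) -> pd.DataFrame:
        out = self.table.copy()
        out["height_cm"] = np.exp(out["mean_log_h"]) * 100.0
        out["weight_kg"] = np.exp(out["mean_log_w"])
        out["bmi"] = out["weight_kg"] / np.exp(out["mean_log_h"]) ** 2
        return out


def predict_individual(
    eta_draws: np.ndarray,
    sigma_e_hat: np.ndarray,
    age: float,
    k: int = 100,
    seed: int | None = None,
    mode: str = "closed_form",
) -> dict[str, np.ndarray]:
    """Posterior-predictive summary for one child from m effect draws.

    For each draw j the inner expectation E(y | eta^(j)) is eta0^(j) +
    eta1^(j) * a — computed in closed form by default, or as the mean of k
    simulated N(., sigma_e_hat) draws in sampling mode.  The prediction
    m_i is the mean of those per-draw expectations and v_i their variance.
    `age` is window-centered.
    """
    eta_draws = np.atleast_2d(np.asarray(eta_draws, dtype=float))
    means = np.column_stack([
        eta_draws[:, 0] + eta_draws[:, 2] * age,
        eta_draws[:, 1] + eta_draws[:, 3] * age,
    ])
    if mode == "sampling":
        if k < 1:
            raise ValueError("k must be >= 1 in sampling mode")
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal((means.shape[0], k, 2)) * np.asarray(sigma_e_hat)
        means = (means[:, None, :] + noise).mean(axis=1)
    return {
        "mean_log": means.mean(axis=0),
        "var_log": means.var(axis=0, ddof=1) if means.shape[0] > 1 else np.zeros(2),
    }


def predict_population(
    beta_hat: np.ndarray,
    omega_hat: np.ndarray,
    sigma_e_hat: np.ndarray,
    age: float,
    n_children: int,
    seed: int | None = None,
    k: int = 100,
    mode: str = "closed_form",
) -> dict[str, np.ndarray]:
    """Population-parameter predictions for n new children at one age.

    One effect vector per child is drawn from N(beta_hat, Omega_hat); the
    per-child prediction is its implied mean at `age` (closed form, or the
    mean of k noisy draws in sampling mode).  Returns (n, 2) means and the
    per-child predictive variances (sigma_e^2 in closed form).
    """
    rng = np.random.default_rng(seed)
    # eigh-based sampling: omega_hat may be merely positive semi-definite
    eta = rng.multivariate_normal(np.asarray(beta_hat, dtype=float),
                                  np.asarray(omega_hat, dtype=float),
                                  size=n_children, method="eigh")
    means = np.column_stack([eta[:, 0] + eta[:, 2] * age,
                             eta[:, 1] + eta[:, 3] * age])
    sigma_e_hat = np.asarray(sigma_e_hat, dtype=float)
    if mode == "sampling":
        if k < 1:
            raise ValueError("k must be >= 1 in sampling mode")
        noise = rng.standard_normal((n_children, k, 2)) * sigma_e_hat
        sampled = means[:, None, :] + noise
        var = sampled.var(axis=1, ddof=1)
        means = sampled.mean(axis=1)
    else:
        var = np.tile(sigma_e_hat**2, (n_children, 1))
    return {"mean_log": means, "var_log": var}


def handoff_age6(
    eta_draws_model1: np.ndarray,
    model2_plugins: dict[str, np.ndarray],
    seed: int | None = None,
    conditional: bool = True,
) -> np.ndarray:
    """Synthetic model-2 effect draws for a child with age 2-5 history only.

    Per draw j the model-2 intercept is the model-1 value at age 6
    (eta0 + 4 * eta1); the slope is drawn from the model-2 conditional
    normal of (slopes | intercepts) under the plug-in (beta_hat,
    Omega_hat), preserving the intercept-slope correlation.  A singular
    intercept block (or conditional=False) falls back to the marginal
    slope distribution.
    """
    eta1 = np.atleast_2d(np.asarray(eta_draws_model1, dtype=float))
    m = eta1.shape[0]
    intercept = np.column_stack([eta1[:, 0] + 4.0 * eta1[:, 2],
                                 eta1[:, 1] + 4.0 * eta1[:, 3]])
    beta_hat = np.asarray(model2_plugins["beta_hat"], dtype=float)
    omega_hat = np.asarray(model2_plugins["omega_hat"], dtype=float)
    sii = omega_hat[:2, :2]
    sis = omega_hat[:2, 2:]
    sss = omega_hat[2:, 2:]
    rng = np.random.default_rng(seed)
    use_conditional = conditional
    if use_conditional:
        try:
            C = sis.T @ np.linalg.inv(sii)
        except np.linalg.LinAlgError:
            logger.warning("singular intercept block in handoff; using marginal slopes")
            use_conditional = False
    if use_conditional:
        S_c = sss - C @ sis
        mean_slope = beta_hat[2:] + (intercept - beta_hat[:2]) @ C.T
        L = np.linalg.cholesky(0.5 * (S_c + S_c.T) + 1e-14 * np.eye(2))
        slope = mean_slope + rng.standard_normal((m, 2)) @ L.T
    else:
        slope = rng.multivariate_normal(beta_hat[2:], sss, size=m, method="cholesky")
    return np.column_stack([intercept, slope])


def _target_age(age_year: int, offset: float) -> float:
    return age_year + offset


def _centered(age: float, age_year: int) -> float:
    center = MODEL1_CENTER if age_year <= 5 else MODEL2_CENTER
    return age - center


def _model_for_age(age_year: int) -> str:
    return "model1" if age_year <= 5 else "model2"


def predict_individual_set(
    target: list[GroupAssignment],
    fits: dict[str, object],
    plugins: dict[str, dict[str, np.ndarray]],
    age_offset: float = 0.5,
    k: int = 100,
    seed: int = 0,
    mode: str = "closed_form",
    replicate_id: int = 0,
) -> PredictionSet:
    """Pred-I: predictions for exactly the contributing-2021 children."""
    rows = []
    ss = np.random.SeedSequence([seed, replicate_id])
    child_seeds = ss.generate_state(max(len(target), 1))
    for j, g in enumerate(target):
        if not g.in_contributing_2021:
            continue
        rule = route(g)
        if rule == "POP":
            continue
        age_year = g.age_in_2021
        age = _target_age(age_year, age_offset)
        sub_seed = int(child_seeds[j])
        if rule == "M1_direct":
            eta = fits["model1"].eta_for(g.child_id)
            sig = plugins["model1"]["sigma_e_hat"]
        elif rule == "M1_handoff_age6":
            eta = handoff_age6(fits["model1"].eta_for(g.child_id),
                               plugins["model2"], seed=sub_seed)
            sig = plugins["model2"]["sigma_e_hat"]
        else:   # M2_direct, M2_preferred
            eta = fits["model2"].eta_for(g.child_id)
            sig = plugins["model2"]["sigma_e_hat"]
        summ = predict_individual(eta, sig, _centered(age, age_year),
                                  k=k, seed=sub_seed, mode=mode)
        rows.append({
            "child_id": g.child_id, "age_at_target": age, "age_year": age_year,
            "source_rule": rule,
            "mean_log_h": summ["mean_log"][0], "mean_log_w": summ["mean_log"][1],
            "var_log_h": summ["var_log"][0], "var_log_w": summ["var_log"][1],
        })
    return PredictionSet("pred_i", replicate_id, seed, k, pd.DataFrame(rows))


def predict_population_set(
    target: list[GroupAssignment],
    plugins: dict[str, dict[str, np.ndarray]],
    age_offset: float = 0.5,
    k: int = 100,
    seed: int = 0,
    mode: str = "closed_form",
    replicate_id: int = 0,
) -> PredictionSet:
    """Pred-P: fresh population draws for every target-group child."""
    tgt = [g for g in target if g.in_target and g.age_in_2021 is not None]
    rows = []
    by_age: dict[int, list[GroupAssignment]] = {}
    for g in tgt:
        by_age.setdefault(g.age_in_2021, []).append(g)
    for age_year in sorted(by_age):
        members = by_age[age_year]
        model = _model_for_age(age_year)
        p = plugins[model]
        age = _target_age(age_year, age_offset)
        sub_seed = int(np.random.SeedSequence([seed, replicate_id, age_year]).generate_state(1)[0])
        res = predict_population(p["beta_hat"], p["omega_hat"], p["sigma_e_hat"],
                                 _centered(age, age_year), len(members),
                                 seed=sub_seed, k=k, mode=mode)
        for i, g in enumerate(members):
            rows.append({
                "child_id": g.child_id, "age_at_target": age, "age_year": age_year,
                "source_rule": "POP",
                "mean_log_h": res["mean_log"][i, 0], "mean_log_w": res["mean_log"][i, 1],
                "var_log_h": res["var_log"][i, 0], "var_log_w": res["var_log"][i, 1],
            })
    return PredictionSet("pred_p", replicate_id, seed, k, pd.DataFrame(rows))


def predict_combined(
    target: list[GroupAssignment],
    fits: dict[str, object],
    plugins: dict[str, dict[str, np.ndarray]],
    age_offset: float = 0.5,
    k: int = 100,
    seed: int = 0,
    mode: str = "closed_form",
    replicate_id: int = 0,
) -> PredictionSet:
    """Pred-C: Pred-I for contributing-2021 children, Pred-P for the rest."""
    tgt = [g for g in target if g.in_target]
    unroutable = [g.child_id for g in tgt if g.age_in_2021 is None]
    if unroutable:
        raise ValueError(f"unroutable target children: {unroutable}")
    # Pred-I components condition on fixed posterior draws: sub-seeded at
    # replicate 0 so they are identical across replicates and draw-for-draw
    # equal to a standalone Pred-I run
    pred_i = predict_individual_set(tgt, fits, plugins, age_offset, k, seed,
                                    mode, replicate_id=0)
    covered = set(pred_i.table["child_id"]) if len(pred_i.table) else set()
    rest = [g for g in tgt if g.child_id not in covered]
    pred_p = predict_population_set(rest, plugins, age_offset, k, seed, mode,
                                    replicate_id)
    table = pd.concat([pred_i.table, pred_p.table], ignore_index=True)
    return PredictionSet("pred_c", replicate_id, seed, k, table)


def replicate_predictions(
    approach: str,
    target: list[GroupAssignment],
    fits: dict[str, object],
    plugins: dict[str, dict[str, np.ndarray]],
    reps: int = 100,
    seed: int = 0,
    age_offset: float = 0.5,
    k: int = 100,
    mode: str = "closed_form",
) -> list[PredictionSet]:
    """Independent prediction replicates with distinct sub-seeds.

    Pred-I components condition on fixed posterior draws, so they are
    identical across replicates; only population-drawn children vary.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    makers = {
        "pred_i": predict_individual_set,
        "pred_p": lambda t, f, p, **kw: predict_population_set(t, p, **kw),
        "pred_c": predict_combined,
    }
    if approach not in makers:
        raise ValueError(f"unknown approach {approach!r}")
    out = []
    for r in range(reps):
        if approach == "pred_p":
            ps = predict_population_set(target, plugins, age_offset, k, seed,
                                        mode, replicate_id=r)
        elif approach == "pred_i":
            ps = predict_individual_set(target, fits, plugins, age_offset, k,
                                        seed, mode, replicate_id=0)
            ps = PredictionSet(ps.approach, r, seed, k, ps.table)
        else:
            ps = predict_combined(target, fits, plugins, age_offset, k, seed,
                                  mode, replicate_id=r)
        out.append(ps)
    return out
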