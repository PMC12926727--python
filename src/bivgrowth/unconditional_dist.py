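"""Unconditional (random-effects-integrated) distributions of height, weight, BMI.

Under the bivariate hierarchical model the outcome vector
Y = (log height_m, log weight_kg) at centered age a is marginally bivariate
normal once the child-level random effects are integrated out:

    E(Y)   = beta0 + beta1 * a
    Var(Y) = diag(sigma_e^2) + U Omega U'

with U = [[1,0,a,0],[0,1,0,a]] mapping the stacked effect vector
(H-int, W-int, H-slope, W-slope) onto the mean at age a.  The natural-scale
variables exp(Y) are bivariate lognormal; log BMI is the linear contrast
l'Y with l = (-2, 1), i.e. log(weight) - 2*log(height_m), itself normal, so
BMI is univariate lognormal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# contrast on (log height_m, log weight_kg) giving log BMI = logW - 2*logH
BMI_CONTRAST = np.array([-2.0, 1.0])


def design_matrix(a: float) -> np.ndarray:
    """U(a): maps (H-int, W-int, H-slope, W-slope) to the bivariate mean."""
    return np.array([[1.0, 0.0, a, 0.0], [0.0, 1.0, 0.0, a]])


@dataclass(frozen=True)
class UnconditionalMoments:
    """Marginal log-scale moments of (log height_m, log weight) at one age."""

    age: float                  # model-centered age a
    mean_log: np.ndarray        # (2,) E(Y)
    cov_log: np.ndarray         # (2,2) Var(Y)
    bmi_mean_log: float
    bmi_var_log: float

    def __post_init__(self):
        if self.bmi_var_log < -1e-12:
            raise ValueError("bmi_var_log must be non-negative")


def log_scale_moments(
    beta: np.ndarray, omega: np.ndarray, sigma_e: np.ndarray, age: float
) -> UnconditionalMoments:
    """Closed-form unconditional moments of Y at centered age `age`.

    beta: (4,) population effects (H-int, W-int, H-slope, W-slope);
    omega: (4,4) between-child covariance; sigma_e: (2,) residual SDs.
    """
    beta = np.asarray(beta, dtype=float)
    omega = np.asarray(omega, dtype=float)
    sigma_e = np.asarray(sigma_e, dtype=float)
    U = design_matrix(age)
    mean_log = U @ beta
    cov_log = np.diag(sigma_e**2) + U @ omega @ U.T
    l = BMI_CONTRAST
    return UnconditionalMoments(
        age=age,
        mean_log=mean_log,
        cov_log=cov_log,
        bmi_mean_log=float(l @ mean_log),
        bmi_var_log=float(l @ cov_log @ l),
    )


def _lognormal_mean_sd(mu: float, v: float) -> tuple[float, float]:
    mean = np.exp(mu + v / 2.0)
    var = (np.exp(v) - 1.0) * np.exp(2.0 * mu + v)
    return float(mean), float(np.sqrt(max(var, 0.0)))


def natural_scale_moments(um: UnconditionalMoments) -> dict[str, float]:
    """Exact lognormal mean/SD of height (cm), weight (kg) and BMI (kg/m^2)."""
    h_mean, h_sd = _lognormal_mean_sd(um.mean_log[0], um.cov_log[0, 0])
    w_mean, w_sd = _lognormal_mean_sd(um.mean_log[1], um.cov_log[1, 1])
    b_mean, b_sd = _lognormal_mean_sd(um.bmi_mean_log, um.bmi_var_log)
    return {
        "height_mean_cm": h_mean * 100.0,
        "height_sd_cm": h_sd * 100.0,
        "weight_mean_kg": w_mean,
        "weight_sd_kg": w_sd,
        "bmi_mean": b_mean,
        "bmi_sd": b_sd,
    }


def posterior_unconditional_moments(
    draws, age: float, use_plugin: bool = False
) -> dict[str, float]:
    """Posterior natural-scale unconditional mean/SD at one centered age.

    Default averages the natural-scale moments over posterior draws of
    (beta, Omega, sigma_e); `use_plugin=True` evaluates once at the
    posterior means (faster, slightly narrower).
    """
    if use_plugin:
        from bivgrowth.hlm_core import plugin_estimates

        p = plugin_estimates(draws)
        um = log_scale_moments(p["beta_hat"], p["omega_hat"], p["sigma_e_hat"], age)
        return natural_scale_moments(um)
    keys = None
    acc = None
    n = draws.beta.shape[0]
    for j in range(n):
        um = log_scale_moments(draws.beta[j], draws.omega[j], draws.sigma_e[j], age)
        nat = natural_scale_moments(um)
        if acc is None:
            keys = list(nat)
            acc = np.zeros(len(keys))
        acc += np.array([nat[k] for k in keys])
    return dict(zip(keys, acc / n))


def within_sample_check(
    fits: dict[str, object],
    frames: dict[str, pd.DataFrame],
    centering: dict[str, float] | None = None,
    windows: dict[str, tuple[int, int]] | None = None,
    use_plugin: bool = False,
) -> pd.DataFrame:
    """Posterior vs observed unconditional mean/SD table for ages 2-11.

    `fits`/`frames` map "model1"/"model2" to PosteriorDraws and model
    frames.  Ages 2-5 come from model1, 6-11 from model2.  Observed cells
    are the empirical mean/SD of the natural-scale measurements at each
    integer age-year; ages with no observations are flagged.
    """
    centering = centering or {"model1": 2.0, "model2": 6.0}
    windows = windows or {"model1": (2, 5), "model2": (6, 11)}
    rows = []
    for model in ("model1", "model2"):
        lo, hi = windows[model]
        for age_year in range(lo, hi + 1):
            a = age_year - centering[model]
            post = posterior_unconditional_moments(fits[model], a, use_plugin=use_plugin)
            sub = frames[model][frames[model]["age_year"] == age_year]
            row = {"age": age_year, "model": model, "n_obs": len(sub)}
            for k, v in post.items():
                row["post_" + k] = v
            if len(sub) >= 2:
                h = np.exp(sub["log_height"]) * 100.0
                w = np.exp(sub["log_weight"])
                bmi = w / (np.exp(sub["log_height"]) ** 2)
                row.update(
                    obs_height_mean_cm=h.mean(), obs_height_sd_cm=h.std(ddof=1),
                    obs_weight_mean_kg=w.mean(), obs_weight_sd_kg=w.std(ddof=1),
                    obs_bmi_mean=bmi.mean(), obs_bmi_sd=bmi.std(ddof=1),
                    flagged_empty=False,
                )
            else:
                row.update(
                    obs_height_mean_cm=np.nan, obs_height_sd_cm=np.nan,
                    obs_weight_mean_kg=np.nan, obs_weight_sd_kg=np.nan,
                    obs_bmi_mean=np.nan, obs_bmi_sd=np.nan,
                    flagged_empty=True,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def render_check_table(table: pd.DataFrame) -> str:
    """One-decimal text rendering: posterior vs observed mean (SD) per age."""
    lines = ["age  height post/obs       weight post/obs       bmi post/obs"]
    for _, r in table.iterrows():
        def cell(mean, sd):
            if np.isnan(mean):
                return "   -    "
            return f"{mean:5.1f} ({sd:4.1f})"

        lines.append(
            f"{int(r['age']):>3}  "
            f"{cell(r['post_height_mean_cm'], r['post_height_sd_cm'])} / {cell(r['obs_height_mean_cm'], r['obs_height_sd_cm'])}  "
            f"{cell(r['post_weight_mean_kg'], r['post_weight_sd_kg'])} / {cell(r['obs_weight_mean_kg'], r['obs_weight_sd_kg'])}  "
            f"{cell(r['post_bmi_mean'], r['post_bmi_sd'])} / {cell(r['obs_bmi_mean'], r['obs_bmi_sd'])}"
        )
    return "\n".join(lines)
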