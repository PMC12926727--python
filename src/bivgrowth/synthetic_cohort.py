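"""Register-like synthetic longitudinal growth cohorts with known truth.

The generator emulates the structure of a primary-care growth register:
per-child bivariate-normal random intercepts and slopes on the log scale in
two age windows (2-5 and 6-11 years), within-child Gaussian measurement
noise, height rounded to whole centimetres and weight to 0.1 kg, an
imbalanced visit pattern over a contributing calendar window (2014-2020),
and a target year (2021) in which every generated child is measured once at
ages 4-11.  A configurable fraction of target children carries no
contributing-window history at all (the "non-contributing" mix).

Ground truth (per-child effect vectors and membership flags) is returned
alongside the cohort so that recovery and assignment tests can compare
against it exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from bivgrowth.cohort_data import (
    ChildRecord,
    Measurement,
    DAYS_PER_YEAR,
    MODEL1_CENTER,
    MODEL2_CENTER,
    MODEL1_WINDOW,
    MODEL2_WINDOW,
)

# maps a window-1 effect vector to the (height, weight) value at age 6
_A_HANDOFF = np.array([[1.0, 0.0, 4.0, 0.0], [0.0, 1.0, 0.0, 4.0]])


def _corr_from_pairs(pairs: dict[tuple[int, int], float]) -> np.ndarray:
    c = np.eye(4)
    for (i, j), r in pairs.items():
        c[i, j] = c[j, i] = r
    return c


@dataclass(frozen=True)
class WindowParams:
    """True population parameters of one age-window model.

    beta is stacked (H-intercept, W-intercept, H-slope, W-slope) on the log
    scale (height in metres, weight in kg); omega the 4x4 between-child
    covariance; sigma_e the within-child residual SDs (height, weight).
    """

    beta: np.ndarray
    omega: np.ndarray
    sigma_e: np.ndarray

    def __post_init__(self):
        omega = np.asarray(self.omega, dtype=float)
        if omega.shape != (4, 4) or not np.allclose(omega, omega.T):
            raise ValueError("omega must be symmetric 4x4")
        if np.min(np.linalg.eigvalsh(omega)) <= 0:
            raise ValueError("omega must be positive definite")
        if np.any(np.asarray(self.sigma_e) < 0):
            raise ValueError("sigma_e must be non-negative")


def default_true_params() -> dict[str, WindowParams]:
    """Calibrated true parameters for both windows.

    Calibrated so the implied natural-scale unconditional moments are
    realistic for Finnish boys: mean height at age 2 near 91 cm, mean
    weight at age 2 near 13.6 kg, mean BMI at age 5 near 15.9 kg/m^2, and
    mean weight at age 11 in the low 40s kg with strongly increasing
    skewness.  The window-2 intercept mean equals the window-1 value at age
    6 so that tied trajectories are continuous in expectation.
    """
    # ages 2-5, centered at 2
    tau1 = np.array([0.0467, 0.115, 0.006, 0.012])
    corr1 = _corr_from_pairs({
        (0, 1): 0.50,   # H-int, W-int
        (0, 2): -0.20,  # H-int, H-slope (taller toddlers grow a bit slower)
        (1, 3): 0.45,   # W-int, W-slope
        (0, 3): 0.10, (1, 2): 0.05, (2, 3): 0.20,
    })
    beta1 = np.array([-0.0944, 2.6032, 0.0718, 0.1327])
    m1 = WindowParams(
        beta=beta1,
        omega=np.outer(tau1, tau1) * corr1,
        sigma_e=np.array([0.012, 0.025]),
    )
    # ages 6-11, centered at 6; intercept mean = window-1 value at age 6
    tau2 = np.array([0.043, 0.150, 0.004, 0.020])
    corr2 = _corr_from_pairs({
        (0, 1): 0.55,
        (0, 2): -0.15,
        (1, 3): 0.50,   # heavier children gain weight faster at school age
        (0, 3): 0.10, (1, 2): 0.05, (2, 3): 0.25,
    })
    beta2 = np.concatenate([_A_HANDOFF @ beta1, [0.0410, 0.1159]])
    m2 = WindowParams(
        beta=beta2,
        omega=np.outer(tau2, tau2) * corr2,
        sigma_e=np.array([0.012, 0.030]),
    )
    return {"model1": m1, "model2": m2}


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_children: int = 300
    birth_year_range: tuple[int, int] = (2010, 2017)
    contributing_years: tuple[int, int] = (2014, 2020)
    target_year: int = 2021
    params: dict[str, WindowParams] = field(default_factory=default_true_params)
    visit_rate: float = 0.7
    p_dropout: float = 0.05
    height_round_cm: float = 1.0
    weight_round_kg: float = 0.1
    target_noncontributing_fraction: float = 766 / 3535
    tie_windows: bool = True
    tie_jitter: float = 0.02   # log-scale SD added to the handed-over age-6 value

    def __post_init__(self):
        for wp in self.params.values():
            np.linalg.cholesky(wp.omega)  # raises if not PD
        if not (0.0 <= self.target_noncontributing_fraction <= 1.0):
            raise ValueError("target_noncontributing_fraction must be in [0,1]")
        if self.visit_rate < 0:
            raise ValueError("visit_rate must be >= 0")


@dataclass
class TruthLabels:
    """Ground truth emitted by the generator.

    eta: child_id -> {"model1": (4,), "model2": (4,)} true effect vectors;
    flags mirror the GroupAssignment definitions computed from the visits
    the generator actually placed.
    """

    eta: dict[str, dict[str, np.ndarray]]
    in_contributing: dict[str, bool]
    in_target: dict[str, bool]
    model_membership: dict[str, frozenset[str]]
    age_in_2021: dict[str, int | None]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid, etas in self.eta.items():
            for window, eta in etas.items():
                rows.append({
                    "child_id": cid, "window": window,
                    "eta_h0": eta[0], "eta_w0": eta[1],
                    "eta_h1": eta[2], "eta_w1": eta[3],
                    "in_contributing": self.in_contributing[cid],
                    "in_target": self.in_target[cid],
                    "age_in_2021": self.age_in_2021[cid],
                })
        return pd.DataFrame(rows)


def effective_params(config: GeneratorConfig, window: str) -> WindowParams:
    """Exact population law the generated data follow in one window.

    For window 1, and for window 2 when windows are untied, this is the
    nominal parameter set.  Under the tied default the window-2 intercept is
    the child's window-1 value at age 6 plus jitter, and the slope is drawn
    from the window-2 conditional normal given that intercept, so the
    effective window-2 (beta, Omega) follow from Gaussian marginalisation.
    """
    if window == "model1" or not config.tie_windows:
        return config.params[window]
    p1, p2 = config.params["model1"], config.params["model2"]
    A = _A_HANDOFF
    sii = p2.omega[:2, :2]
    sis = p2.omega[:2, 2:]
    sss = p2.omega[2:, 2:]
    C = sis.T @ np.linalg.inv(sii)            # slope|intercept regression
    S_c = sss - C @ sis                        # conditional slope covariance
    mean_int = A @ p1.beta
    V_int = A @ p1.omega @ A.T + config.tie_jitter**2 * np.eye(2)
    mean_slope = p2.beta[2:] + C @ (mean_int - p2.beta[:2])
    beta_eff = np.concatenate([mean_int, mean_slope])
    omega_eff = np.block([[V_int, V_int @ C.T], [C @ V_int, C @ V_int @ C.T + S_c]])
    omega_eff = 0.5 * (omega_eff + omega_eff.T)
    return WindowParams(beta=beta_eff, omega=omega_eff, sigma_e=p2.sigma_e)


def _child_rng(seed: int, index: int) -> np.random.Generator:
    # one stream per (seed, child index): reproducible under reordering
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def _round_to(x: float, grid: float) -> float:
    if grid <= 0:
        return x
    return round(x / grid) * grid


def _draw_etas(config: GeneratorConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    p1, p2 = config.params["model1"], config.params["model2"]
    eta1 = rng.multivariate_normal(p1.beta, p1.omega, method="cholesky")
    if config.tie_windows:
        intercept = _A_HANDOFF @ eta1 + config.tie_jitter * rng.standard_normal(2)
        sii = p2.omega[:2, :2]
        sis = p2.omega[:2, 2:]
        sss = p2.omega[2:, 2:]
        C = sis.T @ np.linalg.inv(sii)
        S_c = sss - C @ sis
        mean_slope = p2.beta[2:] + C @ (intercept - p2.beta[:2])
        slope = rng.multivariate_normal(mean_slope, S_c, method="cholesky")
        eta2 = np.concatenate([intercept, slope])
    else:
        eta2 = rng.multivariate_normal(p2.beta, p2.omega, method="cholesky")
    return {"model1": eta1, "model2": eta2}


def _outcome(etas: dict[str, np.ndarray], age: float,
             sigma1: np.ndarray, sigma2: np.ndarray,
             rng: np.random.Generator) -> tuple[float, float]:
    """Noisy (log height_m, log weight) at fractional age, window-routed."""
    if age < MODEL2_CENTER:
        eta, sig, a = etas["model1"], sigma1, age - MODEL1_CENTER
    else:
        eta, sig, a = etas["model2"], sigma2, age - MODEL2_CENTER
    mean = np.array([eta[0] + eta[2] * a, eta[1] + eta[3] * a])
    y = mean + sig * rng.standard_normal(2)
    return float(y[0]), float(y[1])


def generate(config: GeneratorConfig) -> tuple[list[ChildRecord], TruthLabels]:
    """Generate a cohort and its ground-truth labels.

    Every child receives one target-year visit at the integer age it
    attains that year (ages 4-11 by construction of the default birth-year
    range).  Children not flagged non-contributing receive visits in the
    contributing window: one candidate per attainable age-year kept with
    probability `visit_rate`, with at least two age-years forced so the
    child genuinely contributes; visit offsets from the birthday are
    Beta(1,5)-distributed years at ages 2-6 and uniform at 7+.
    """
    p1 = config.params["model1"]
    p2 = config.params["model2"]
    lo_y, hi_y = config.contributing_years
    cohort: list[ChildRecord] = []
    labels = TruthLabels({}, {}, {}, {}, {})
    for i in range(config.n_children):
        rng = _child_rng(config.seed, i)
        cid = f"c{i:05d}"
        birth_year = int(rng.integers(config.birth_year_range[0],
                                      config.birth_year_range[1] + 1))
        birth = date(birth_year, 1, 1) + timedelta(days=int(rng.integers(0, 365)))
        etas = _draw_etas(config, rng)
        noncontrib = rng.random() < config.target_noncontributing_fraction

        # attainable age-years in the contributing window
        attainable = []
        for age_y in range(2, 12):
            bday = birth + timedelta(days=round(age_y * DAYS_PER_YEAR))
            if lo_y <= bday.year <= hi_y:
                attainable.append(age_y)

        visit_ages: list[float] = []
        if not noncontrib and attainable:
            chosen = [y for y in attainable if rng.random() < min(1.0, config.visit_rate)]
            # dropout: truncate after a geometric number of retained years
            kept = []
            for y in chosen:
                kept.append(y)
                if rng.random() < config.p_dropout:
                    break
            chosen = kept
            forced = [y for y in attainable if y not in chosen][: max(0, 2 - len(chosen))]
            chosen = sorted(set(chosen) | set(forced))
            for y in chosen:
                if y <= 6:
                    offset = float(rng.beta(1.0, 5.0))
                else:
                    offset = float(rng.random())
                vd = birth + timedelta(days=round((y + offset) * DAYS_PER_YEAR))
                age = (vd - birth).days / DAYS_PER_YEAR  # snap to day grid
                if lo_y <= vd.year <= hi_y and int(age) == y:
                    visit_ages.append(age)

        # target-year visit at the age attained in that year
        age_t = config.target_year - birth_year
        target_age_rec: int | None = None
        if 4 <= age_t <= 11:
            bday_t = birth + timedelta(days=round(age_t * DAYS_PER_YEAR))
            if bday_t.year == config.target_year:
                days_left = (date(config.target_year, 12, 31) - bday_t).days
                off_days = int(rng.integers(0, max(days_left, 0) + 1))
                vd = bday_t + timedelta(days=off_days)
                age = (vd - birth).days / DAYS_PER_YEAR
                if vd.year == config.target_year and int(age) == age_t:
                    visit_ages.append(age)
                    target_age_rec = age_t

        rec = ChildRecord(cid, birth)
        for age in sorted(visit_ages):
            log_h, log_w = _outcome(etas, age, p1.sigma_e, p2.sigma_e, rng)
            h_cm = _round_to(np.exp(log_h) * 100.0, config.height_round_cm)
            w_kg = _round_to(np.exp(log_w), config.weight_round_kg)
            vd = birth + timedelta(days=round(age * DAYS_PER_YEAR))
            rec.measurements.append(Measurement(cid, birth, vd, h_cm, w_kg))
        cohort.append(rec)

        # ground-truth flags from the visits actually placed
        contrib_years_set = {
            int((m.visit_date - birth).days / DAYS_PER_YEAR)
            for m in rec.measurements if lo_y <= m.visit_date.year <= hi_y
        }
        in_contributing = len(contrib_years_set) >= 2
        membership = set()
        if in_contributing:
            if any(MODEL1_WINDOW[0] <= y <= MODEL1_WINDOW[1] for y in contrib_years_set):
                membership.add("model1")
            if any(MODEL2_WINDOW[0] <= y <= MODEL2_WINDOW[1] for y in contrib_years_set):
                membership.add("model2")
        labels.eta[cid] = etas
        labels.in_contributing[cid] = in_contributing
        labels.in_target[cid] = target_age_rec is not None
        labels.model_membership[cid] = frozenset(membership)
        labels.age_in_2021[cid] = target_age_rec
    return cohort, labels


_FIXTURE_SEEDS = {"tiny": 101, "small": 202, "medium": 303}
_FIXTURE_SIZES = {"tiny": 20, "small": 300, "medium": 3000}


def make_fixture(size: str = "small", **overrides) -> tuple[list[ChildRecord], TruthLabels]:
    """Fixed-seed cohorts: tiny=20 (unit tests), small=300 (fit tests),
    medium=3000 (full-scale checks)."""
    if size not in _FIXTURE_SIZES:
        raise ValueError(f"unknown fixture size {size!r}")
    config = GeneratorConfig(
        seed=_FIXTURE_SEEDS[size], n_children=_FIXTURE_SIZES[size], **overrides
    )
    return generate(config)


def fixture_config(size: str = "small", **overrides) -> GeneratorConfig:
    return GeneratorConfig(
        seed=_FIXTURE_SEEDS[size], n_children=_FIXTURE_SIZES[size], **overrides
    )


def cohort_checksum(cohort: list[ChildRecord]) -> str:
    """Stable content hash of a cohort (determinism checks)."""
    h = hashlib.sha256()
    for rec in sorted(cohort, key=lambda r: r.child_id):
        for m in rec.measurements:
            h.update(
                f"{m.child_id},{m.birth_date},{m.visit_date},{m.height_cm:.6g},{m.weight_kg:.6g};".encode()
            )
    return h.hexdigest()
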