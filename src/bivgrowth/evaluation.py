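"""Prediction evaluation: summary batteries, transport distances, flags.

Distributional agreement between predictions and observations is measured
with first-order Wasserstein distances (L1 ground cost): exact
quantile-function integration in 1-D and an exact solution of the discrete
transportation problem in 2-D.  Individual agreement for children with
their own growth history uses per-child Euclidean distances in the
(height cm, weight kg) plane.  Median differences are flagged against
clinical-meaningfulness thresholds: 2 cm height, 1 kg weight,
0.5 kg/m^2 BMI.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

CLINICAL_THRESHOLDS = {"height_cm": 2.0, "weight_kg": 1.0, "bmi": 0.5}


# --------------------------------------------------------------------------
# summary battery


@dataclass(frozen=True)
class SummaryBattery:
    """Mean (SD), median (q05, q95), skewness (kurtosis) of one sample.

    Skewness and kurtosis are moment-based (m3/m2^1.5 and m4/m2^2, so a
    normal sample gives kurtosis near 3); they are None, with `degenerate`
    set, for n < 4 or constant samples.  SD uses the n-1 denominator;
    quantiles interpolate linearly between order statistics.
    """

    n: int
    mean: float
    sd: float
    median: float
    q05: float
    q95: float
    skewness: float | None
    kurtosis: float | None
    degenerate: bool = False

    def __post_init__(self):
        if not (self.q05 <= self.median <= self.q95):
            raise ValueError("quantiles out of order")
        if self.sd < 0:
            raise ValueError("SD must be non-negative")
        if self.skewness is not None and self.kurtosis is not None:
            # Pearson inequality
            if self.kurtosis < self.skewness**2 + 1 - 1e-9:
                raise ValueError("kurtosis below skewness^2 + 1")


def summarize(values) -> SummaryBattery:
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    m2 = float(np.mean((x - x.mean()) ** 2))
    degenerate = x.size < 4 or m2 <= 1e-300
    if degenerate:
        skew = kurt = None
        if m2 <= 1e-300:
            logger.info("summarize: constant sample, skew/kurtosis absent")
    else:
        m3 = float(np.mean((x - x.mean()) ** 3))
        m4 = float(np.mean((x - x.mean()) ** 4))
        skew = m3 / m2**1.5
        kurt = m4 / m2**2
    q05, med, q95 = np.quantile(x, [0.05, 0.5, 0.95], method="linear")
    return SummaryBattery(
        n=int(x.size), mean=float(x.mean()), sd=float(x.std(ddof=1)),
        median=float(med), q05=float(q05), q95=float(q95),
        skewness=skew, kurtosis=kurt, degenerate=degenerate,
    )


# --------------------------------------------------------------------------
# Wasserstein distances


def wasserstein_1d(x, y, x_weights=None, y_weights=None) -> float:
    """Exact first-order Wasserstein distance between empirical measures.

    Computed as the integrated absolute difference of the two quantile
    functions; unequal sample sizes and weights are handled exactly.
    """
    return float(stats.wasserstein_distance(x, y, x_weights, y_weights))


def _expand_for_assignment(X: np.ndarray, Y: np.ndarray, cap: int,
                           seed: int | None):
    """Equalise the two uniform clouds by LCM replication, or subsample."""
    n, m = len(X), len(Y)
    lcm = n * m // math.gcd(n, m)
    if lcm <= cap:
        return (np.repeat(X, lcm // n, axis=0), np.repeat(Y, lcm // m, axis=0))
    size = min(n, m, cap)
    rng = np.random.default_rng(seed)
    logger.warning("wasserstein_2d: instance above cap, subsampling to %d with seed", size)
    Xs = X[rng.choice(n, size, replace=False)] if n > size else X
    Ys = Y[rng.choice(m, size, replace=False)] if m > size else Y
    if len(Xs) != len(Ys):
        size = min(len(Xs), len(Ys))
        Xs, Ys = Xs[:size], Ys[:size]
    return Xs, Ys


def wasserstein_2d(X, Y, cap: int = 4096, seed: int | None = 0) -> float:
    """Exact W1 between two uniform point clouds under the L1 ground cost.

    With equal (possibly LCM-replicated) sizes and uniform weights the
    transportation problem reduces to a minimum-cost perfect matching,
    solved exactly.  Instances whose LCM expansion would exceed `cap`
    points per side are subsampled with the given seed (logged).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 0 or Y.shape[0] == 0:
        raise ValueError("empty sample")
    Xe, Ye = _expand_for_assignment(X, Y, cap, seed)
    cost = np.abs(Xe[:, None, :] - Ye[None, :, :]).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].mean())


# --------------------------------------------------------------------------
# Euclidean distances


def euclidean_paired(obs: pd.DataFrame, pred: pd.DataFrame) -> pd.DataFrame:
    """Per-child Euclidean distance in the (height cm, weight kg) plane.

    Both frames need columns child_id, height_cm, weight_kg (and optionally
    age_year for the by-age means); the child sets must match exactly.
    """
    obs_ids = set(obs["child_id"])
    pred_ids = set(pred["child_id"])
    if obs_ids != pred_ids:
        missing = sorted(obs_ids ^ pred_ids)
        raise ValueError(f"child sets differ: {missing[:10]}")
    merged = obs.merge(pred, on="child_id", suffixes=("_obs", "_pred"))
    d = np.sqrt((merged["height_cm_pred"] - merged["height_cm_obs"]) ** 2
                + (merged["weight_kg_pred"] - merged["weight_kg_obs"]) ** 2)
    out = pd.DataFrame({"child_id": merged["child_id"], "distance": d})
    if "age_year_obs" in merged:
        out["age_year"] = merged["age_year_obs"]
    elif "age_year" in merged:
        out["age_year"] = merged["age_year"]
    return out


# --------------------------------------------------------------------------
# replicate aggregation and flags


def aggregate_replicates(reports: list[pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Element-wise mean and SD of numeric cells across replicate tables.

    Tables must share shape and index/columns; a single replicate yields
    SD = None.
    """
    if not reports:
        raise ValueError("need at least one replicate")
    first = reports[0]
    num_cols = first.select_dtypes(include=[np.number]).columns
    for r in reports[1:]:
        if r.shape != first.shape or list(r.columns) != list(first.columns):
            raise ValueError("replicate tables have mismatching shapes")
    stack = np.stack([r[num_cols].to_numpy(dtype=float) for r in reports])
    mean = first.copy()
    mean[num_cols] = stack.mean(axis=0)
    if len(reports) == 1:
        return {"mean": mean, "sd": None}
    sd = first.copy()
    sd[num_cols] = stack.std(axis=0, ddof=1)
    return {"mean": mean, "sd": sd}


def clinical_flags(pred_medians: pd.DataFrame, obs_medians: pd.DataFrame,
                   thresholds: dict[str, float] | None = None) -> pd.DataFrame:
    """Flag ages where |median_pred - median_obs| meets the clinical threshold.

    Input frames are indexed by age with columns among height_cm,
    weight_kg, bmi.  A difference >= the threshold (2 cm / 1 kg /
    0.5 kg/m^2) is flagged.
    """
    thresholds = thresholds or CLINICAL_THRESHOLDS
    if not pred_medians.index.equals(obs_medians.index):
        raise ValueError("age grids differ")
    rows = []
    for age in pred_medians.index:
        for q, thr in thresholds.items():
            if q not in pred_medians.columns:
                continue
            diff = abs(float(pred_medians.loc[age, q]) - float(obs_medians.loc[age, q]))
            rows.append({"age": age, "quantity": q, "abs_diff": diff,
                         "threshold": thr, "flagged": bool(diff >= thr)})
    return pd.DataFrame(rows)


def target_group_moments(preds, age_year: int, quantity: str = "weight_kg"
                         ) -> dict[str, float]:
    """Mean and between-child variance of per-child predictive means.

    The variance uses the n-1 denominator and deliberately excludes the
    within-child predictive variances v_i, so some of the total variability
    of the target measurements is not represented.
    """
    nat = preds.natural()
    sub = nat[nat["age_year"] == age_year][quantity].to_numpy(dtype=float)
    if sub.size < 2:
        raise ValueError(f"need >= 2 children at age {age_year}")
    return {"mean": float(sub.mean()), "variance": float(sub.var(ddof=1)),
            "n": int(sub.size)}


# --------------------------------------------------------------------------
# report assembly


def observed_target_frame(cohort, groups, target_year: int = 2021) -> pd.DataFrame:
    """Natural-scale target-year observations (one row per target child)."""
    target_ids = {g.child_id: g.age_in_2021 for g in groups if g.in_target}
    rows = []
    for rec in cohort:
        if rec.child_id not in target_ids:
            continue
        for m in rec.measurements:
            if m.visit_date.year == target_year and m.age_year == target_ids[rec.child_id]:
                rows.append({
                    "child_id": rec.child_id, "age_year": m.age_year,
                    "height_cm": m.height_cm, "weight_kg": m.weight_kg,
                    "bmi": m.weight_kg / (m.height_cm / 100.0) ** 2,
                })
                break
    return pd.DataFrame(rows)


def distance_report(pred_nat: pd.DataFrame, obs: pd.DataFrame,
                    cap: int = 4096, seed: int = 0,
                    bivariate: bool = True) -> pd.DataFrame:
    """Per-age W1 distances between predictions and observations.

    Marginal W1 for height, weight and BMI, plus (optionally) the
    bivariate (height, weight) W1 under the L1 ground cost.
    """
    rows = []
    ages = sorted(set(obs["age_year"]) & set(pred_nat["age_year"]))
    for age in ages:
        o = obs[obs["age_year"] == age]
        p = pred_nat[pred_nat["age_year"] == age]
        if len(o) == 0 or len(p) == 0:
            continue
        row = {"age_year": age, "n_obs": len(o), "n_pred": len(p)}
        for q in ("height_cm", "weight_kg", "bmi"):
            row[f"w1_{q}"] = wasserstein_1d(o[q], p[q])
        if bivariate:
            row["w1_bivariate"] = wasserstein_2d(
                o[["height_cm", "weight_kg"]].to_numpy(),
                p[["height_cm", "weight_kg"]].to_numpy(),
                cap=cap, seed=seed)
        rows.append(row)
    return pd.DataFrame(rows)


def summary_report(pred_nat: pd.DataFrame, obs: pd.DataFrame) -> pd.DataFrame:
    """Per-age summary batteries of observed vs predicted distributions."""
    rows = []
    ages = sorted(set(obs["age_year"]) & set(pred_nat["age_year"]))
    for age in ages:
        for q in ("height_cm", "weight_kg", "bmi"):
            for label, frame in (("observed", obs), ("predicted", pred_nat)):
                sub = frame[frame["age_year"] == age][q]
                if len(sub) < 2:
                    continue
                s = summarize(sub)
                rows.append({
                    "age_year": age, "quantity": q, "source": label,
                    "n": s.n, "mean": s.mean, "sd": s.sd, "median": s.median,
                    "q05": s.q05, "q95": s.q95,
                    "skewness": s.skewness, "kurtosis": s.kurtosis,
                })
    return pd.DataFrame(rows)


def medians_by_age(frame: pd.DataFrame) -> pd.DataFrame:
    """Median height/weight/BMI per age (input to clinical_flags)."""
    return frame.groupby("age_year")[["height_cm", "weight_kg", "bmi"]].median()
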