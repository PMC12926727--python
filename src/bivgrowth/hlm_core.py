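"""Bivariate hierarchical linear model: specification, sampler, diagnostics.

Model (per age window, ages centered at the window start):

    level 1:  y_ti | eta_i ~ N(eta0_i + eta1_i * a_ti, diag(s_eH^2, s_eW^2))
    level 2:  eta_i ~ N(beta, Omega),  Omega = diag(tau) lambda diag(tau)

with y_ti = (log height_m, log weight_kg), eta_i the stacked child effects
(H-int, W-int, H-slope, W-slope), beta the population effects.  Priors:
beta_j ~ N(a_j, b_j) with (a, b) elicited from a pooled frequentist fit;
s_eH, s_eW ~ inverse-Gamma(0.5, 0.5) placed on the standard deviations;
tau_j ~ half-Cauchy(2.5); lambda ~ LKJ(shape).

Posterior sampling is Metropolis-within-Gibbs: child effects and beta have
conjugate Gaussian full conditionals (sampled in closed form, batched over
children); (tau, lambda) and the residual SDs are updated by adaptive
random-walk Metropolis steps on unconstrained scales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


# --------------------------------------------------------------------------
# specification


@dataclass(frozen=True)
class HLMSpec:
    """Model specification for one age window."""

    age_window: tuple[int, int] = (2, 5)
    centering_age: float = 2.0
    prior_beta_loc: np.ndarray | None = None     # (4,), elicited if None
    prior_beta_scale: np.ndarray | None = None   # (4,), > 0
    prior_sigma_e_shape: float = 0.5
    prior_sigma_e_scale: float = 0.5
    prior_tau_scale: float = 2.5
    prior_lambda_shape: float = 2.0

    def __post_init__(self):
        if self.prior_beta_scale is not None and np.any(np.asarray(self.prior_beta_scale) <= 0):
            raise ValueError("prior_beta_scale must be positive")
        for v in (self.prior_sigma_e_shape, self.prior_sigma_e_scale,
                  self.prior_tau_scale, self.prior_lambda_shape):
            if v <= 0:
                raise ValueError("prior shapes/scales must be positive")


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 2
    warmup: int = 500
    draws: int = 1000
    seed: int = 0
    m_retained: int = 1000      # per-child effect draws kept across chains
    mh_sweeps: int = 3          # (tau, lambda) Metropolis sweeps per scan
    thin: int = 2               # full Gibbs scans per stored draw
    rhat_threshold: float = 1.01
    ess_threshold: float = 400.0


@dataclass
class PosteriorDraws:
    """Posterior draws of one age-window fit, stacked per chain.

    Arrays with a leading (chains, draws) shape are exposed flattened over
    chains via the corresponding property; omega is derived per draw from
    its scale/correlation decomposition.  eta holds m retained per-child
    effect draws, (m, n_children, 4).
    """

    child_ids: list[str]
    beta_c: np.ndarray       # (C, D, 4)
    tau_c: np.ndarray        # (C, D, 4)
    lambda_c: np.ndarray     # (C, D, 4, 4)
    sigma_e_c: np.ndarray    # (C, D, 2)
    eta: np.ndarray          # (m, N, 4)

    @property
    def n_chains(self) -> int:
        return self.beta_c.shape[0]

    @property
    def beta(self) -> np.ndarray:
        return self.beta_c.reshape(-1, 4)

    @property
    def tau(self) -> np.ndarray:
        return self.tau_c.reshape(-1, 4)

    @property
    def lambda_corr(self) -> np.ndarray:
        return self.lambda_c.reshape(-1, 4, 4)

    @property
    def sigma_e(self) -> np.ndarray:
        return self.sigma_e_c.reshape(-1, 2)

    @property
    def omega(self) -> np.ndarray:
        t = self.tau
        return t[:, :, None] * self.lambda_corr * t[:, None, :]

    @property
    def m(self) -> int:
        return self.eta.shape[0]

    def eta_for(self, child_id: str) -> np.ndarray:
        """(m, 4) retained effect draws of one child."""
        return self.eta[:, self.child_ids.index(child_id), :]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of scalar parameter draws (one row per draw x parameter)."""
        names = (["beta_h0", "beta_w0", "beta_h1", "beta_w1"],
                 ["tau_h0", "tau_w0", "tau_h1", "tau_w1"],
                 ["sigma_e_h", "sigma_e_w"])
        blocks = (self.beta, self.tau, self.sigma_e)
        rows = []
        for nm, arr in zip(names, blocks):
            for j, name in enumerate(nm):
                rows.append(pd.DataFrame({"parameter": name, "draw": np.arange(arr.shape[0]),
                                          "value": arr[:, j]}))
        return pd.concat(rows, ignore_index=True)


@dataclass
class FitDiagnostics:
    rhat: dict[str, float]
    ess: dict[str, float]
    divergences: int | None
    rhat_threshold: float
    ess_threshold: float

    @property
    def passed(self) -> bool:
        ok = (max(self.rhat.values()) <= self.rhat_threshold
              and min(self.ess.values()) >= self.ess_threshold)
        if self.divergences is not None:
            ok = ok and self.divergences == 0
        return ok

    def to_dict(self) -> dict:
        return {"rhat": self.rhat, "ess": self.ess,
                "divergences": self.divergences, "passed": self.passed}


# --------------------------------------------------------------------------
# densities


def _log_half_cauchy(x: np.ndarray, scale: float) -> float:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        return -np.inf
    return float(np.sum(np.log(2.0 / (np.pi * scale)) - np.log1p((x / scale) ** 2)))


def _log_invgamma(x: np.ndarray, shape: float, scale: float) -> float:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        return -np.inf
    return float(np.sum(stats.invgamma.logpdf(x, shape, scale=scale)))


def _log_lkj(lam: np.ndarray, shape: float) -> float:
    """Unnormalised LKJ correlation density: (shape-1) * log det(lambda)."""
    sign, logdet = np.linalg.slogdet(lam)
    if sign <= 0:
        return -np.inf
    return (shape - 1.0) * logdet


def _valid_corr(lam: np.ndarray) -> bool:
    if not np.allclose(np.diag(lam), 1.0):
        return False
    if not np.allclose(lam, lam.T):
        return False
    return np.min(np.linalg.eigvalsh(lam)) > 1e-10


def log_joint(params: dict, data: pd.DataFrame | None, spec: HLMSpec) -> float:
    """Joint log density of (data, eta, beta, tau, lambda, sigma_e).

    Sums observation-level Gaussian log-densities, child-level N(beta,
    Omega) terms, and the prior terms, up to a constant fixed across calls
    (the LKJ normaliser).  Out-of-support parameters yield -inf rather than
    raising.
    """
    beta = np.asarray(params["beta"], dtype=float)
    tau = np.asarray(params["tau"], dtype=float)
    lam = np.asarray(params["lambda_corr"], dtype=float)
    sigma_e = np.asarray(params["sigma_e"], dtype=float)
    eta = params.get("eta", {})

    if np.any(tau <= 0) or np.any(sigma_e <= 0) or not _valid_corr(lam):
        return -np.inf
    omega = tau[:, None] * lam * tau[None, :]

    lp = 0.0
    # priors
    if spec.prior_beta_loc is not None:
        lp += float(np.sum(stats.norm.logpdf(
            beta, loc=spec.prior_beta_loc, scale=spec.prior_beta_scale)))
    lp += _log_half_cauchy(tau, spec.prior_tau_scale)
    lp += _log_lkj(lam, spec.prior_lambda_shape)
    lp += _log_invgamma(sigma_e, spec.prior_sigma_e_shape, spec.prior_sigma_e_scale)
    if not np.isfinite(lp):
        return -np.inf

    # level 2
    if eta:
        try:
            mvn = stats.multivariate_normal(mean=beta, cov=omega)
        except np.linalg.LinAlgError:
            return -np.inf
        for e in eta.values():
            lp += float(mvn.logpdf(np.asarray(e, dtype=float)))

    # level 1
    if data is not None and len(data):
        for _, row in data.iterrows():
            e = np.asarray(eta[row["child_id"]], dtype=float)
            a = row["a"]
            mu_h = e[0] + e[2] * a
            mu_w = e[1] + e[3] * a
            lp += float(stats.norm.logpdf(row["log_height"], mu_h, sigma_e[0]))
            lp += float(stats.norm.logpdf(row["log_weight"], mu_w, sigma_e[1]))
    return lp


# --------------------------------------------------------------------------
# prior elicitation


def elicit_beta_prior(data: pd.DataFrame, multiplier: float = 10.0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Normal prior (loc, scale) for beta from pooled per-outcome OLS.

    Locations are the OLS intercept/slope of each log outcome on centered
    age; scales are `multiplier` times the OLS standard errors (floored at
    1e-6 so noise-free data still give a proper prior).
    """
    a = data["a"].to_numpy()
    if len(np.unique(a)) < 2:
        raise ValueError("need >= 2 distinct ages to elicit beta prior")
    X = np.column_stack([np.ones_like(a), a])
    XtX_inv = np.linalg.inv(X.T @ X)
    loc = np.empty(4)
    scale = np.empty(4)
    for j, col in enumerate(("log_height", "log_weight")):
        y = data[col].to_numpy()
        coef = XtX_inv @ X.T @ y
        resid = y - X @ coef
        dof = max(len(y) - 2, 1)
        se = np.sqrt(np.maximum(resid @ resid / dof * np.diag(XtX_inv), 0.0))
        loc[j], loc[2 + j] = coef
        scale[j], scale[2 + j] = np.maximum(multiplier * se, 1e-6)
    return loc, scale


# --------------------------------------------------------------------------
# sufficient statistics


@dataclass
class _Suff:
    child_ids: list[str]
    n: np.ndarray       # (N,)
    Sa: np.ndarray
    Saa: np.ndarray
    Sy: np.ndarray      # (N, 2)  sums of (log_h, log_w)
    Say: np.ndarray     # (N, 2)  sums of a * y
    idx: np.ndarray     # (T,) child index per observation row
    a_obs: np.ndarray   # (T,)
    y_obs: np.ndarray   # (T, 2)


def _sufficient_stats(frame: pd.DataFrame) -> _Suff:
    ids = frame["child_id"].to_numpy()
    child_ids = list(pd.unique(ids))
    lookup = {c: i for i, c in enumerate(child_ids)}
    idx = np.fromiter((lookup[c] for c in ids), dtype=np.int64, count=len(ids))
    a = frame["a"].to_numpy(dtype=float)
    y = frame[["log_height", "log_weight"]].to_numpy(dtype=float)
    N = len(child_ids)
    n = np.bincount(idx, minlength=N).astype(float)
    Sa = np.bincount(idx, weights=a, minlength=N)
    Saa = np.bincount(idx, weights=a * a, minlength=N)
    Sy = np.column_stack([np.bincount(idx, weights=y[:, k], minlength=N) for k in range(2)])
    Say = np.column_stack([np.bincount(idx, weights=a * y[:, k], minlength=N) for k in range(2)])
    return _Suff(child_ids, n, Sa, Saa, Sy, Say, idx, a, y)


# --------------------------------------------------------------------------
# sampler internals


def _sample_eta(suff: _Suff, beta, omega_inv, sigma_e, rng) -> np.ndarray:
    """Batched draw from the Gaussian full conditional of all child effects."""
    N = len(suff.child_ids)
    inv_v = 1.0 / sigma_e**2     # (2,)
    P = np.broadcast_to(omega_inv, (N, 4, 4)).copy()
    for k in range(2):           # k=0 height block (0,2), k=1 weight block (1,3)
        i0, i1 = k, 2 + k
        P[:, i0, i0] += suff.n * inv_v[k]
        P[:, i0, i1] += suff.Sa * inv_v[k]
        P[:, i1, i0] += suff.Sa * inv_v[k]
        P[:, i1, i1] += suff.Saa * inv_v[k]
    b = np.tile(omega_inv @ beta, (N, 1))
    b[:, 0] += suff.Sy[:, 0] * inv_v[0]
    b[:, 1] += suff.Sy[:, 1] * inv_v[1]
    b[:, 2] += suff.Say[:, 0] * inv_v[0]
    b[:, 3] += suff.Say[:, 1] * inv_v[1]
    mu = np.linalg.solve(P, b[:, :, None])[:, :, 0]
    L = np.linalg.cholesky(P)
    z = rng.standard_normal((N, 4, 1))
    noise = np.linalg.solve(np.transpose(L, (0, 2, 1)), z)[:, :, 0]
    return mu + noise


def _sample_beta_marginal(suff: _Suff, omega_inv, sigma_e, prior_loc, prior_scale,
                          rng) -> np.ndarray:
    """Collapsed Gibbs draw of beta from p(beta | y, tau, lambda, sigma_e).

    With child effects integrated out, y_i ~ N(X_i beta, V_i) and the beta
    full conditional is Gaussian with precision sum_i X_i' V_i^-1 X_i plus
    the prior; Woodbury reduces every term to 4x4 algebra on the per-child
    sufficient statistics, batched over children.
    """
    N = len(suff.child_ids)
    inv_v = 1.0 / sigma_e**2
    M = np.zeros((N, 4, 4))
    for k in range(2):
        i0, i1 = k, 2 + k
        M[:, i0, i0] = suff.n * inv_v[k]
        M[:, i0, i1] = suff.Sa * inv_v[k]
        M[:, i1, i0] = suff.Sa * inv_v[k]
        M[:, i1, i1] = suff.Saa * inv_v[k]
    P = M + omega_inv
    c = np.zeros((N, 4))
    c[:, 0] = suff.Sy[:, 0] * inv_v[0]
    c[:, 1] = suff.Sy[:, 1] * inv_v[1]
    c[:, 2] = suff.Say[:, 0] * inv_v[0]
    c[:, 3] = suff.Say[:, 1] * inv_v[1]
    Pinv_M = np.linalg.solve(P, M)
    A = (M - M @ Pinv_M).sum(axis=0)
    Pinv_c = np.linalg.solve(P, c[:, :, None])[:, :, 0]
    r = (c - np.einsum("nij,nj->ni", M, Pinv_c)).sum(axis=0)
    prec = A + np.diag(1.0 / prior_scale**2)
    rhs = r + prior_loc / prior_scale**2
    L = np.linalg.cholesky(0.5 * (prec + prec.T))
    mu = np.linalg.solve(prec, rhs)
    noise = np.linalg.solve(L.T, rng.standard_normal(4))
    return mu + noise


def _sample_beta(eta, omega_inv, prior_loc, prior_scale, rng) -> np.ndarray:
    N = eta.shape[0]
    P = N * omega_inv + np.diag(1.0 / prior_scale**2)
    rhs = omega_inv @ eta.sum(axis=0) + prior_loc / prior_scale**2
    L = np.linalg.cholesky(P)
    mu = np.linalg.solve(P, rhs)
    noise = np.linalg.solve(L.T, rng.standard_normal(4))
    return mu + noise


def _omega_loglik(tau, lam, S, n) -> float:
    """N(beta, Omega) log-likelihood of centered effects via scatter S."""
    sign, logdet_lam = np.linalg.slogdet(lam)
    if sign <= 0:
        return -np.inf
    try:
        lam_inv = np.linalg.inv(lam)
    except np.linalg.LinAlgError:
        return -np.inf
    d_inv = 1.0 / tau
    omega_inv = d_inv[:, None] * lam_inv * d_inv[None, :]
    logdet_omega = 2.0 * np.sum(np.log(tau)) + logdet_lam
    return -0.5 * n * logdet_omega - 0.5 * float(np.sum(omega_inv * S))


@dataclass
class _MHState:
    """Per-component adaptive random-walk scales and acceptance counters."""

    s_tau: np.ndarray = field(default_factory=lambda: np.full(4, 0.3))
    s_lam: np.ndarray = field(default_factory=lambda: np.full(6, 0.08))
    s_marg: np.ndarray = field(default_factory=lambda: np.full(4, 0.3))
    acc_tau: np.ndarray = field(default_factory=lambda: np.zeros((4, 2)))
    acc_lam: np.ndarray = field(default_factory=lambda: np.zeros((6, 2)))
    acc_marg: np.ndarray = field(default_factory=lambda: np.zeros((4, 2)))

    @staticmethod
    def _adapt(scales: np.ndarray, acc: np.ndarray, target: float = 0.44):
        for j in range(len(scales)):
            tried = acc[j, 1]
            if tried >= 40:
                rate = acc[j, 0] / tried
                scales[j] = float(np.clip(
                    scales[j] * np.exp(np.clip(rate - target, -0.7, 0.7)),
                    1e-4, 3.0))
                acc[j] = 0.0


_OFFDIAG = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


def _mh_tau_lambda(tau, lam, S, n, spec: HLMSpec, mh: _MHState, rng, adapt: bool):
    """One sweep of per-component Metropolis updates for (tau, lambda)."""
    tau = tau.copy()
    # tau: per-component random walk on the log scale (Jacobian: + log tau_j)
    for j in range(4):
        cur = (_omega_loglik(tau, lam, S, n)
               + _log_half_cauchy(tau, spec.prior_tau_scale) + np.log(tau[j]))
        prop = tau.copy()
        prop[j] = np.exp(np.log(tau[j]) + mh.s_tau[j] * rng.standard_normal())
        new = (_omega_loglik(prop, lam, S, n)
               + _log_half_cauchy(prop, spec.prior_tau_scale) + np.log(prop[j]))
        mh.acc_tau[j, 1] += 1
        if np.log(rng.random()) < new - cur:
            tau = prop
            mh.acc_tau[j, 0] += 1

    # lambda: per-entry random walk on off-diagonals, rejecting non-PD moves
    for idx, (i, j) in enumerate(_OFFDIAG):
        cur = _omega_loglik(tau, lam, S, n) + _log_lkj(lam, spec.prior_lambda_shape)
        prop = lam.copy()
        r = prop[i, j] + mh.s_lam[idx] * rng.standard_normal()
        prop[i, j] = prop[j, i] = r
        mh.acc_lam[idx, 1] += 1
        if abs(r) < 1.0 and np.min(np.linalg.eigvalsh(prop)) > 1e-8:
            new = _omega_loglik(tau, prop, S, n) + _log_lkj(prop, spec.prior_lambda_shape)
            if np.log(rng.random()) < new - cur:
                lam = prop
                mh.acc_lam[idx, 0] += 1
    if adapt:
        mh._adapt(mh.s_tau, mh.acc_tau)
        mh._adapt(mh.s_lam, mh.acc_lam)
    return tau, lam


def _interweave_tau(tau, beta, eta, suff: _Suff, sigma_e, spec: HLMSpec, rng):
    """Non-centered (ancestral) update of tau with u = D^-1 (eta - beta) fixed.

    Holding u fixed, each outcome's observations follow a linear regression
    in its (intercept-scale, slope-scale) pair of tau, so the conditional is
    the regression Gaussian times the half-Cauchy prior: an independence
    proposal from the Gaussian is accepted on the prior ratio alone.  This
    breaks the slow funnel coupling between tau and sigma_e that a purely
    centered sampler suffers from.  Returns (tau, eta) with eta recomputed
    as beta + diag(tau) u.
    """
    u = (eta - beta) / tau
    u_obs = u[suff.idx]
    tau_new = tau.copy()
    for k, (i0, i1) in enumerate(((0, 2), (1, 3))):
        d = suff.y_obs[:, k] - beta[i0] - beta[i1] * suff.a_obs
        X = np.column_stack([u_obs[:, i0], u_obs[:, i1] * suff.a_obs])
        s2 = sigma_e[k] ** 2
        Q = X.T @ X / s2 + 1e-12 * np.eye(2)
        cov = np.linalg.inv(Q)
        mean = cov @ (X.T @ d / s2)
        try:
            L = np.linalg.cholesky(0.5 * (cov + cov.T))
        except np.linalg.LinAlgError:
            continue
        prop = mean + L @ rng.standard_normal(2)
        if np.all(prop > 0):
            cur = np.array([tau_new[i0], tau_new[i1]])
            log_r = (_log_half_cauchy(prop, spec.prior_tau_scale)
                     - _log_half_cauchy(cur, spec.prior_tau_scale))
            if np.log(rng.random()) < log_r:
                tau_new[i0], tau_new[i1] = prop
    return tau_new, beta + tau_new * u


def _mh_sigma_e(sigma_e, rss, n_obs, spec: HLMSpec, rng):
    """Independence sampler for the residual SDs.

    Proposes sigma^2 from the likelihood-conjugate InvGamma(n/2, RSS/2);
    the likelihood then cancels against the proposal and the acceptance
    ratio reduces to prior(s')/prior(s) * s'/s.  With the weak
    inverse-Gamma(0.5, 0.5) prior acceptance is near 1, giving nearly
    independent draws.  In prior-only mode (n_obs=0) draws come straight
    from the prior.
    """
    out = sigma_e.copy()
    for k in range(2):
        if n_obs == 0:
            out[k] = float(stats.invgamma.rvs(spec.prior_sigma_e_shape,
                                              scale=spec.prior_sigma_e_scale,
                                              random_state=rng))
            continue
        var_prop = float(stats.invgamma.rvs(n_obs / 2.0, scale=rss[k] / 2.0,
                                            random_state=rng))
        s_prop = np.sqrt(var_prop)
        log_r = (float(stats.invgamma.logpdf(s_prop, spec.prior_sigma_e_shape,
                                             scale=spec.prior_sigma_e_scale))
                 - float(stats.invgamma.logpdf(out[k], spec.prior_sigma_e_shape,
                                               scale=spec.prior_sigma_e_scale))
                 + np.log(s_prop) - np.log(out[k]))
        if np.log(rng.random()) < log_r:
            out[k] = s_prop
    return out


def _marg_stats(suff: _Suff, beta: np.ndarray):
    """Per-child residual sums for the effect-integrated likelihood."""
    d = suff.y_obs - np.column_stack([beta[0] + beta[2] * suff.a_obs,
                                      beta[1] + beta[3] * suff.a_obs])
    N = len(suff.child_ids)
    Sd = np.column_stack([np.bincount(suff.idx, weights=d[:, k], minlength=N)
                          for k in range(2)])
    Sad = np.column_stack([np.bincount(suff.idx, weights=suff.a_obs * d[:, k], minlength=N)
                           for k in range(2)])
    Sdd = (d * d).sum(axis=0)
    return Sd, Sad, Sdd


def _marginal_loglik(suff: _Suff, marg, tau, lam, sigma_e) -> float:
    """Log-likelihood of the data given (beta, tau, lambda, sigma_e) with
    child effects integrated out (Woodbury through the 4x4 per-child
    posterior precision)."""
    Sd, Sad, Sdd = marg
    d_inv = 1.0 / tau
    try:
        lam_inv = np.linalg.inv(lam)
    except np.linalg.LinAlgError:
        return -np.inf
    sign, logdet_lam = np.linalg.slogdet(lam)
    if sign <= 0:
        return -np.inf
    logdet_omega = 2.0 * np.sum(np.log(tau)) + logdet_lam
    omega_inv = d_inv[:, None] * lam_inv * d_inv[None, :]
    N = len(suff.child_ids)
    inv_v = 1.0 / sigma_e**2
    P = np.broadcast_to(omega_inv, (N, 4, 4)).copy()
    for k in range(2):
        i0, i1 = k, 2 + k
        P[:, i0, i0] += suff.n * inv_v[k]
        P[:, i0, i1] += suff.Sa * inv_v[k]
        P[:, i1, i0] += suff.Sa * inv_v[k]
        P[:, i1, i1] += suff.Saa * inv_v[k]
    b = np.zeros((N, 4))
    b[:, 0] = Sd[:, 0] * inv_v[0]
    b[:, 1] = Sd[:, 1] * inv_v[1]
    b[:, 2] = Sad[:, 0] * inv_v[0]
    b[:, 3] = Sad[:, 1] * inv_v[1]
    try:
        L = np.linalg.cholesky(P)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet_P = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)))
    sol = np.linalg.solve(P, b[:, :, None])[:, :, 0]
    quad = float(Sdd @ inv_v - np.sum(b * sol))
    n_obs = float(suff.n.sum())
    return -0.5 * (N * logdet_omega + logdet_P
                   + n_obs * float(np.sum(np.log(sigma_e**2))) + quad)


def _marginal_scale_update(suff: _Suff, beta, tau, lam, sigma_e,
                           spec: HLMSpec, mh, rng, adapt: bool):
    """Random-walk MH on (tau slopes, residual SDs) under the marginal
    likelihood.  These pairs lie on a near-flat attribution ridge that
    conditional updates cross slowly; with the effects integrated out the
    walk moves along the ridge freely."""
    marg = _marg_stats(suff, beta)
    comps = [("tau", 2), ("sig", 0), ("tau", 3), ("sig", 1)]
    tau = tau.copy()
    sigma_e = sigma_e.copy()

    def log_post(t, s):
        return (_marginal_loglik(suff, marg, t, lam, s)
                + _log_half_cauchy(t, spec.prior_tau_scale)
                + _log_invgamma(s, spec.prior_sigma_e_shape, spec.prior_sigma_e_scale)
                + float(np.sum(np.log(t))) + float(np.sum(np.log(s))))

    cur = log_post(tau, sigma_e)
    for ci, (kind, j) in enumerate(comps):
        t_prop, s_prop = tau.copy(), sigma_e.copy()
        if kind == "tau":
            t_prop[j] = np.exp(np.log(tau[j]) + mh.s_marg[ci] * rng.standard_normal())
        else:
            s_prop[j] = np.exp(np.log(sigma_e[j]) + mh.s_marg[ci] * rng.standard_normal())
        new = log_post(t_prop, s_prop)
        mh.acc_marg[ci, 1] += 1
        if np.log(rng.random()) < new - cur:
            tau, sigma_e, cur = t_prop, s_prop, new
            mh.acc_marg[ci, 0] += 1
    if adapt:
        mh._adapt(mh.s_marg, mh.acc_marg)
    return tau, sigma_e


def _residual_ss(suff: _Suff, eta: np.ndarray) -> np.ndarray:
    e = eta[suff.idx]
    mu = np.column_stack([e[:, 0] + e[:, 2] * suff.a_obs,
                          e[:, 1] + e[:, 3] * suff.a_obs])
    r = suff.y_obs - mu
    return np.sum(r * r, axis=0)


def _run_chain(suff: _Suff | None, spec: HLMSpec, cfg: SamplerConfig, chain: int,
               prior_loc, prior_scale, eta_keep_idx: np.ndarray):
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, chain]))
    D, W = cfg.draws, cfg.warmup
    beta = prior_loc + 0.01 * rng.standard_normal(4)
    tau = np.full(4, 0.1)
    lam = np.eye(4)
    sigma_e = np.array([0.05, 0.05])
    mh = _MHState()
    N = len(suff.child_ids) if suff is not None else 0
    eta = np.tile(beta, (N, 1))

    out = {"beta": np.empty((D, 4)), "tau": np.empty((D, 4)),
           "lambda": np.empty((D, 4, 4)), "sigma_e": np.empty((D, 2)),
           "eta": np.empty((len(eta_keep_idx), N, 4))}
    keep_set = {int(i): j for j, i in enumerate(eta_keep_idx)}

    thin = max(1, cfg.thin)
    for it in range((W + D) * thin):
        adapt = it < W * thin
        if N:
            tau, sigma_e = _marginal_scale_update(suff, beta, tau, lam, sigma_e,
                                                  spec, mh, rng, adapt)
        d_inv = 1.0 / tau
        lam_inv = np.linalg.inv(lam)
        omega_inv = d_inv[:, None] * lam_inv * d_inv[None, :]
        if N:
            beta = _sample_beta_marginal(suff, omega_inv, sigma_e,
                                         prior_loc, prior_scale, rng)
            eta = _sample_eta(suff, beta, omega_inv, sigma_e, rng)
            centered = eta - beta
            S = centered.T @ centered
            n_eff = N
        else:   # prior-only mode
            beta = prior_loc + prior_scale * rng.standard_normal(4)
            S = np.zeros((4, 4))
            n_eff = 0
        for _ in range(cfg.mh_sweeps):
            tau, lam = _mh_tau_lambda(tau, lam, S, n_eff, spec, mh, rng, adapt)
        if N:
            tau, eta = _interweave_tau(tau, beta, eta, suff, sigma_e, spec, rng)
            rss = _residual_ss(suff, eta)
            n_obs = int(suff.n.sum())
        else:
            rss = np.zeros(2)
            n_obs = 0
        sigma_e = _mh_sigma_e(sigma_e, rss, n_obs, spec, rng)

        if it >= W * thin and (it - W * thin) % thin == thin - 1:
            j = (it - W * thin) // thin
            out["beta"][j] = beta
            out["tau"][j] = tau
            out["lambda"][j] = lam
            out["sigma_e"][j] = sigma_e
            if j in keep_set:
                out["eta"][keep_set[j]] = eta
    return out


def fit(data: pd.DataFrame | None, spec: HLMSpec, sampler: SamplerConfig
        ) -> tuple[PosteriorDraws, FitDiagnostics]:
    """Fit the model by MH-within-Gibbs; returns draws plus diagnostics.

    `data` is a model frame (child_id, a, log_height, log_weight); pass
    None for a prior-only run.  Non-convergence does not raise: the result
    carries `FitDiagnostics.passed = False` and a warning is logged.
    """
    if data is not None and data["child_id"].nunique() < 2:
        raise ValueError("need at least two children to fit")
    if spec.prior_beta_loc is None:
        if data is None:
            raise ValueError("prior-only mode needs an explicit beta prior")
        prior_loc, prior_scale = elicit_beta_prior(data)
    else:
        prior_loc = np.asarray(spec.prior_beta_loc, dtype=float)
        prior_scale = np.asarray(spec.prior_beta_scale, dtype=float)

    suff = _sufficient_stats(data) if data is not None else None
    m_per_chain = max(1, sampler.m_retained // sampler.chains)
    eta_keep_idx = np.unique(np.linspace(0, sampler.draws - 1, m_per_chain).astype(int))

    chains = [_run_chain(suff, spec, sampler, c, prior_loc, prior_scale, eta_keep_idx)
              for c in range(sampler.chains)]

    draws = PosteriorDraws(
        child_ids=suff.child_ids if suff is not None else [],
        beta_c=np.stack([c["beta"] for c in chains]),
        tau_c=np.stack([c["tau"] for c in chains]),
        lambda_c=np.stack([c["lambda"] for c in chains]),
        sigma_e_c=np.stack([c["sigma_e"] for c in chains]),
        eta=np.concatenate([c["eta"] for c in chains], axis=0),
    )

    names = {}
    for j, nm in enumerate(["beta_h0", "beta_w0", "beta_h1", "beta_w1"]):
        names[nm] = draws.beta_c[:, :, j]
    for j, nm in enumerate(["tau_h0", "tau_w0", "tau_h1", "tau_w1"]):
        names[nm] = draws.tau_c[:, :, j]
    for j, nm in enumerate(["sigma_e_h", "sigma_e_w"]):
        names[nm] = draws.sigma_e_c[:, :, j]
    diag = FitDiagnostics(
        rhat={k: split_rhat(v) for k, v in names.items()},
        ess={k: effective_sample_size(v) for k, v in names.items()},
        divergences=None,
        rhat_threshold=sampler.rhat_threshold,
        ess_threshold=sampler.ess_threshold,
    )
    if not diag.passed:
        logger.warning("sampler convergence diagnostics failed: max rhat=%.3f min ess=%.0f",
                       max(diag.rhat.values()), min(diag.ess.values()))
    return draws, diag


# --------------------------------------------------------------------------
# convergence diagnostics


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction (Gelman-Rubin R-hat).

    `chains`: (n_chains, n_draws).  Each chain is split in half; R-hat
    compares between- and within-half variances.  Zero total variance
    returns 1 by convention.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1 or x.shape[1] < 4:
        raise ValueError("need (chains, draws) with >= 4 draws")
    half = x.shape[1] // 2
    splits = np.concatenate([x[:, :half], x[:, half:2 * half]], axis=0)
    m, n = splits.shape
    means = splits.mean(axis=1)
    W = splits.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 1e-300:
        logger.info("split_rhat: zero within variance, returning 1 by convention")
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def effective_sample_size(chains: np.ndarray) -> float:
    """Autocorrelation-based ESS with Geyer initial-monotone truncation.

    Constant chains return the total draw count by convention.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    m, n = x.shape
    total = m * n
    if n < 4:
        raise ValueError("need >= 4 draws per chain")
    chain_vars = x.var(axis=1, ddof=1)
    if np.all(chain_vars <= 1e-300) or x.std() <= 1e-300:
        logger.info("effective_sample_size: constant chains, returning total draws")
        return float(total)

    # per-chain autocovariances via FFT
    acov = np.empty((m, n))
    for c in range(m):
        d = x[c] - x[c].mean()
        size = int(2 ** np.ceil(np.log2(2 * n)))
        f = np.fft.rfft(d, size)
        ac = np.fft.irfft(f * np.conjugate(f), size)[:n].real / n
        acov[c] = ac
    W = np.mean(acov[:, 0] * n / (n - 1))
    B_over_n = np.var(x.mean(axis=1), ddof=1) if m > 1 else 0.0
    var_plus = (n - 1) / n * W + B_over_n
    rho = 1.0 - (W - acov.mean(axis=0)) / var_plus
    rho[0] = 1.0

    # Geyer: sum consecutive pairs while positive, enforce monotone decrease
    tau_sum = 0.0
    prev_pair = np.inf
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev_pair)
        tau_sum += pair
        prev_pair = pair
        t += 2
    ess = total / (1.0 + 2.0 * tau_sum)
    return float(min(ess, total * 2.0))


# --------------------------------------------------------------------------
# plug-in estimates


def _nearest_pd(mat: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    sym = 0.5 * (mat + mat.T)
    vals, vecs = np.linalg.eigh(sym)
    if np.min(vals) >= floor:
        return sym
    vals = np.maximum(vals, floor)
    return vecs @ np.diag(vals) @ vecs.T


def plugin_estimates(draws: PosteriorDraws, estimator: str = "mean") -> dict[str, np.ndarray]:
    """Posterior point summaries used as plug-in parameters downstream.

    Component-wise posterior means by default ("median" selectable);
    omega_hat is projected to the nearest positive-definite matrix if
    numerically indefinite.
    """
    if draws.beta.shape[0] == 0:
        raise ValueError("no draws")
    agg = np.mean if estimator == "mean" else np.median
    omega_hat = agg(draws.omega, axis=0)
    return {
        "beta_hat": agg(draws.beta, axis=0),
        "omega_hat": _nearest_pd(omega_hat),
        "sigma_e_hat": agg(draws.sigma_e, axis=0),
    }
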