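"""Piecewise-linear change-point mixed-effects model for maternal weight.

The mean weight of subject *i* in trial arm *g* at gestational age *t* (days
from last menstrual period) is a broken-stick curve

    mu_ij = (beta0 + b0_i) + (beta1_g + b1_i) * min(t, tau_g)
                           + (beta2_g + b2_i) * max(0, t - tau_g)

with a common population intercept ``beta0`` (the arms are randomized, so
baseline weight cannot differ systematically), arm-specific slopes before and
after an arm-specific change-point ``tau_g``, and subject-level Gaussian
random effects ``b_i = (b0, b1, b2) ~ N(0, Sigma)`` with unstructured 3x3
covariance.  Observed weights are the subject mean plus iid Normal(0, sigma^2)
residual error.  With three arms this gives exactly ten fixed effects:
one intercept, three pre-change slopes, three post-change slopes and three
change-points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("CON", "EXE", "MOT")
"""Trial arms: standard care, supervised exercise, motivational counselling."""

TAU_LOWER = 50.0
TAU_UPPER = 250.0
"""Support of the uniform prior on the change-points, in days."""


class DomainError(ValueError):
    """Raised when a model quantity is evaluated outside its domain."""


def group_index(group: str) -> int:
    try:
        return GROUPS.index(group)
    except ValueError:
        raise DomainError(f"unknown group {group!r}; expected one of {GROUPS}") from None


def _as_group_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape == ():
        arr = np.full(len(GROUPS), float(arr))
    if arr.shape != (len(GROUPS),):
        raise ValueError(f"{name} must be a scalar or length-{len(GROUPS)} vector")
    return arr


@dataclass
class TrajectoryParameters:
    """The ten fixed effects plus variance components.

    beta0   common intercept (kg)
    beta1   pre-change slope per arm, order (CON, EXE, MOT) (kg/day)
    beta2   post-change slope per arm (kg/day)
    tau     change-point per arm (days), each in (50, 250)
    Sigma   3x3 covariance of subject random effects (intercept, slope1, slope2)
    sigma   residual SD (kg); may be zero only for noise-free synthetic cohorts
    """

    beta0: float
    beta1: np.ndarray
    beta2: np.ndarray
    tau: np.ndarray
    Sigma: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    sigma: float = 1.0

    def __post_init__(self):
        self.beta1 = _as_group_vector(self.beta1, "beta1")
        self.beta2 = _as_group_vector(self.beta2, "beta2")
        self.tau = _as_group_vector(self.tau, "tau")
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.Sigma.shape != (3, 3):
            raise ValueError("Sigma must be 3x3")
        if not np.allclose(self.Sigma, self.Sigma.T, atol=1e-10):
            raise ValueError("Sigma must be symmetric")
        if np.any(np.linalg.eigvalsh(self.Sigma) < -1e-8):
            raise ValueError("Sigma must be positive semi-definite")
        if np.any(self.tau <= TAU_LOWER) or np.any(self.tau >= TAU_UPPER):
            raise ValueError(f"change-points must lie in ({TAU_LOWER}, {TAU_UPPER}) days")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def n_fixed_effects(self) -> int:
        return 1 + len(self.beta1) + len(self.beta2) + len(self.tau)

    def fixed_effect_dict(self) -> dict[str, float]:
        out = {"beta0": float(self.beta0)}
        for i, g in enumerate(GROUPS):
            out[f"beta1[{g}]"] = float(self.beta1[i])
        for i, g in enumerate(GROUPS):
            out[f"beta2[{g}]"] = float(self.beta2[i])
        for i, g in enumerate(GROUPS):
            out[f"tau[{g}]"] = float(self.tau[i])
        return out


@dataclass
class SubjectEffects:
    """Random deviations of one subject: intercept (kg) and the two slopes (kg/day)."""

    b0: float = 0.0
    b1: float = 0.0
    b2: float = 0.0

    def __post_init__(self):
        if not np.all(np.isfinite([self.b0, self.b1, self.b2])):
            raise ValueError("subject effects must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.b0, self.b1, self.b2])


def broken_stick_basis(t, tau: float) -> np.ndarray:
    """Design row(s) [1, min(t, tau), max(0, t - tau)] for time(s) ``t``."""
    t = np.asarray(t, dtype=float)
    return np.stack(
        [np.ones_like(t), np.minimum(t, tau), np.maximum(t - tau, 0.0)], axis=-1
    )


def mean_weight(params: TrajectoryParameters, effects: SubjectEffects, group: str, t):
    """Subject mean weight (kg) at gestational age ``t`` days.

    Continuous and piecewise linear in ``t``; equals ``beta0 + b0`` at t=0.
    ``t`` may be a scalar or array of non-negative days.
    """
    g = group_index(group)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("gestational age must be non-negative")
    tau = params.tau[g]
    mu = (
        (params.beta0 + effects.b0)
        + (params.beta1[g] + effects.b1) * np.minimum(t_arr, tau)
        + (params.beta2[g] + effects.b2) * np.maximum(t_arr - tau, 0.0)
    )
    return mu if mu.shape else float(mu)


def _require_columns(observations: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in observations.columns]
    if missing:
        raise ValueError(f"observations table is missing columns {missing}")


def attach_groups(observations: pd.DataFrame, participants: pd.DataFrame) -> pd.DataFrame:
    """Merge the arm label onto a weight-observation table."""
    return observations.merge(
        participants[["participant_id", "group"]], on="participant_id", how="left"
    )


def log_likelihood(
    params: TrajectoryParameters,
    effects: dict[str, SubjectEffects],
    observations: pd.DataFrame,
) -> float:
    """Conditional Gaussian log-likelihood sum_ij log N(w_ij | mu_ij, sigma^2).

    ``observations`` needs columns participant_id, ga_days, weight_kg and
    group (see :func:`attach_groups`).  Every participant appearing in the
    table must have an entry in ``effects``.
    """
    if params.sigma <= 0:
        raise DomainError("residual SD must be positive for likelihood evaluation")
    _require_columns(observations, ["participant_id", "ga_days", "weight_kg", "group"])
    total = 0.0
    for pid, sub in observations.groupby("participant_id", sort=False):
        if pid not in effects:
            raise ValueError(f"no subject effects supplied for participant {pid!r}")
        group = sub["group"].iloc[0]
        mu = mean_weight(params, effects[pid], group, sub["ga_days"].to_numpy())
        resid = sub["weight_kg"].to_numpy() - mu
        n = len(resid)
        total += -0.5 * (
            n * np.log(2.0 * np.pi * params.sigma**2)
            + np.sum(resid**2) / params.sigma**2
        )
    return float(total)


def log_marginal_fixed_tau(
    params: TrajectoryParameters, observations: pd.DataFrame
) -> float:
    """Marginal log-likelihood with subject effects integrated out analytically.

    At fixed change-points the model is a linear mixed model: per subject,
    w_i ~ N(X_i beta_g, X_i Sigma X_i' + sigma^2 I) with the broken-stick
    design X_i.  Used as an internal oracle and by the sampler.
    """
    if params.sigma <= 0:
        raise DomainError("residual SD must be positive")
    if np.any(np.linalg.eigvalsh(params.Sigma) < -1e-8):
        raise DomainError("Sigma must be positive semi-definite")
    _require_columns(observations, ["participant_id", "ga_days", "weight_kg", "group"])
    total = 0.0
    for pid, sub in observations.groupby("participant_id", sort=False):
        g = group_index(sub["group"].iloc[0])
        t = sub["ga_days"].to_numpy(dtype=float)
        w = sub["weight_kg"].to_numpy(dtype=float)
        X = broken_stick_basis(t, params.tau[g])
        beta_g = np.array([params.beta0, params.beta1[g], params.beta2[g]])
        V = X @ params.Sigma @ X.T + params.sigma**2 * np.eye(len(t))
        total += stats.multivariate_normal.logpdf(w, mean=X @ beta_g, cov=V)
    return float(total)


@dataclass
class Priors:
    """Weakly informative priors for everything the trial report leaves open.

    The change-points carry the only prior stated by the analysis plan:
    tau_g ~ Uniform(50, 250) days.  The rest are conventional choices:

    * beta0 ~ Normal(beta0_loc, beta0_scale) after centring the weights
      (the sampler centres internally, so beta0_loc = 0 by default),
    * slopes ~ Normal(0, slope_scale) kg/day,
    * sigma ~ half-Normal(sigma_scale) kg,
    * Sigma parameterized by its Cholesky factor L: half-Normal priors on the
      diagonal (scales of intercept / slope deviations) and Normal(0,
      chol_offdiag_scale) on the off-diagonal elements.
    """

    beta0_loc: float = 0.0
    beta0_scale: float = 10.0
    slope_scale: float = 1.0
    sigma_scale: float = 5.0
    chol_diag_scales: tuple[float, float, float] = (15.0, 0.1, 0.1)
    chol_offdiag_scale: float = 0.1
    tau_lower: float = TAU_LOWER
    tau_upper: float = TAU_UPPER

    def log_prior_fixed(self, beta0: float, beta1, beta2) -> float:
        lp = stats.norm.logpdf(beta0, self.beta0_loc, self.beta0_scale)
        lp += np.sum(stats.norm.logpdf(np.asarray(beta1), 0.0, self.slope_scale))
        lp += np.sum(stats.norm.logpdf(np.asarray(beta2), 0.0, self.slope_scale))
        return float(lp)

    def log_prior_tau(self, tau) -> float:
        tau = np.asarray(tau, dtype=float)
        if np.any(tau <= self.tau_lower) or np.any(tau >= self.tau_upper):
            return -np.inf
        return float(-len(tau) * np.log(self.tau_upper - self.tau_lower))

    def log_prior_sigma(self, sigma: float) -> float:
        if sigma <= 0:
            return -np.inf
        return float(stats.halfnorm.logpdf(sigma, scale=self.sigma_scale))

    def log_prior_chol(self, L: np.ndarray) -> float:
        diag = np.diag(L)
        if np.any(diag <= 0):
            return -np.inf
        lp = np.sum(stats.halfnorm.logpdf(diag, scale=self.chol_diag_scales))
        off = L[np.tril_indices(3, -1)]
        lp += np.sum(stats.norm.logpdf(off, 0.0, self.chol_offdiag_scale))
        return float(lp)


def log_posterior(
    params: TrajectoryParameters,
    effects: dict[str, SubjectEffects],
    observations: pd.DataFrame,
    priors: Priors,
) -> float:
    """Joint log-posterior of fixed effects, variance components and subject effects.

    log_likelihood + fixed-effect / Sigma / sigma priors + Uniform(50, 250)
    change-point prior + sum_i log N(b_i | 0, Sigma).  Returns -inf whenever a
    change-point leaves the prior support.
    """
    lp_tau = priors.log_prior_tau(params.tau)
    if not np.isfinite(lp_tau):
        return -np.inf
    lp = lp_tau
    lp += priors.log_prior_fixed(params.beta0, params.beta1, params.beta2)
    lp += priors.log_prior_sigma(params.sigma)
    try:
        L = np.linalg.cholesky(params.Sigma)
    except np.linalg.LinAlgError:
        raise DomainError("Sigma must be positive definite for log_posterior") from None
    lp += priors.log_prior_chol(L)
    b = np.stack([e.as_array() for e in effects.values()])
    lp += float(np.sum(stats.multivariate_normal.logpdf(b, mean=np.zeros(3), cov=params.Sigma)))
    lp += log_likelihood(params, effects, observations)
    return float(lp)
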