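"""Posterior sampling and convergence diagnostics for the trajectory model.

The sampler exploits the model's partial conjugacy.  At fixed change-points
the model is a linear mixed model, so the subject random effects are
integrated out analytically: per subject, w_i ~ N(X_i beta_g, X_i Sigma X_i'
+ sigma^2 I).  Each iteration then

1. draws the seven linear fixed effects (common intercept + six slopes)
   exactly from their Gaussian full conditional (a GLS draw), and
2. updates phi = (logit-transformed change-points, log-Cholesky factor of
   Sigma, log sigma) with an adaptive random-walk Metropolis step on the
   marginal posterior (proposal covariance adapted during warm-up only, so
   the retained chain is a valid Markov chain).

Subject random effects are recovered afterwards by exact draws from their
Gaussian conditional given each retained draw, which together with steps
1-2 yields draws from the full joint posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import GROUPS, Priors, TrajectoryParameters, attach_groups

_LOG2PI = float(np.log(2.0 * np.pi))
_TRIL = [(0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2)]
_DIAG_POS = [0, 2, 5]  # positions of diagonal elements within _TRIL


@dataclass
class SamplerConfig:
    """MCMC settings: four chains of 10,000 iterations, half warm-up, by default."""

    n_chains: int = 4
    n_iterations: int = 10_000
    warmup_fraction: float = 0.5
    seed: int = 0
    target_accept: float = 0.3
    tau_init: float = 150.0
    tau_init_jitter: float = 25.0
    adapt_start: int = 150
    adapt_interval: int = 50
    max_init_retries: int = 20

    def __post_init__(self):
        if self.n_chains < 1:
            raise ValueError("n_chains must be at least 1")
        if not 0.0 < self.warmup_fraction < 1.0:
            raise ValueError("warmup_fraction must be in (0, 1)")
        if self.n_iterations < 2:
            raise ValueError("n_iterations must be at least 2")

    @property
    def n_warmup(self) -> int:
        return int(round(self.n_iterations * self.warmup_fraction))

    @property
    def n_retained(self) -> int:
        return self.n_iterations - self.n_warmup


@dataclass
class PosteriorDraws:
    """Draws indexed by (chain, iteration, ...) for all model parameters.

    ``b`` holds the subject random effects with subjects ordered as in
    ``participant_ids``; ``group_idx`` maps each subject to their arm.
    """

    beta0: np.ndarray          # (C, D)
    beta1: np.ndarray          # (C, D, 3)
    beta2: np.ndarray          # (C, D, 3)
    tau: np.ndarray            # (C, D, 3)
    Sigma: np.ndarray          # (C, D, 3, 3)
    sigma: np.ndarray          # (C, D)
    b: np.ndarray              # (C, D, S, 3)
    participant_ids: list[str] = field(default_factory=list)
    group_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_chains(self) -> int:
        return self.beta0.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta0.shape[1]

    def subject_index(self, participant_id: str) -> int:
        try:
            return self.participant_ids.index(participant_id)
        except ValueError:
            raise KeyError(f"participant {participant_id!r} not in the fitted model") from None

    def fixed_effect_arrays(self) -> dict[str, np.ndarray]:
        out = {"beta0": self.beta0}
        for i, g in enumerate(GROUPS):
            out[f"beta1[{g}]"] = self.beta1[..., i]
        for i, g in enumerate(GROUPS):
            out[f"beta2[{g}]"] = self.beta2[..., i]
        for i, g in enumerate(GROUPS):
            out[f"tau[{g}]"] = self.tau[..., i]
        return out

    def scalar_arrays(self) -> dict[str, np.ndarray]:
        out = self.fixed_effect_arrays()
        out["sigma"] = self.sigma
        for k in range(3):
            out[f"Sigma[{k},{k}]"] = self.Sigma[..., k, k]
        return out

    def posterior_mean_params(self) -> TrajectoryParameters:
        return TrajectoryParameters(
            beta0=float(self.beta0.mean()),
            beta1=self.beta1.mean(axis=(0, 1)),
            beta2=self.beta2.mean(axis=(0, 1)),
            tau=self.tau.mean(axis=(0, 1)),
            Sigma=self.Sigma.mean(axis=(0, 1)),
            sigma=float(self.sigma.mean()),
        )

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            beta0=self.beta0, beta1=self.beta1, beta2=self.beta2, tau=self.tau,
            Sigma=self.Sigma, sigma=self.sigma, b=self.b,
            participant_ids=np.array(self.participant_ids),
            group_idx=self.group_idx,
        )

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                beta0=z["beta0"], beta1=z["beta1"], beta2=z["beta2"], tau=z["tau"],
                Sigma=z["Sigma"], sigma=z["sigma"], b=z["b"],
                participant_ids=[str(s) for s in z["participant_ids"]],
                group_idx=z["group_idx"],
            )


class ModelData:
    """Per-arm padded observation arrays for fast batched likelihood work."""

    def __init__(self, observations: pd.DataFrame, participants: pd.DataFrame | None = None):
        obs = observations
        if "group" not in obs.columns:
            if participants is None:
                raise ValueError("observations lack a group column; supply participants")
            obs = attach_groups(obs, participants)
        if len(obs) == 0:
            raise ValueError("no weight observations supplied")
        if obs["group"].isna().any():
            bad = obs.loc[obs["group"].isna(), "participant_id"].unique()
            raise ValueError(f"participants without arm label: {list(bad)[:5]}")

        self.offset = float(obs["weight_kg"].mean())
        self.participant_ids: list[str] = []
        self.group_idx_list: list[int] = []
        self.groups_present: list[int] = []
        self.T: dict[int, np.ndarray] = {}
        self.W: dict[int, np.ndarray] = {}
        self.mask: dict[int, np.ndarray] = {}
        self.subject_rows: dict[int, list[int]] = {}

        grouped = {pid: sub for pid, sub in obs.groupby("participant_id", sort=False)}
        order = (
            [p for p in participants["participant_id"] if p in grouped]
            if participants is not None
            else list(grouped)
        )
        by_group: dict[int, list[str]] = {}
        for pid in order:
            gi = GROUPS.index(grouped[pid]["group"].iloc[0])
            by_group.setdefault(gi, []).append(pid)
        for gi, pids in by_group.items():
            m = max(len(grouped[p]) for p in pids)
            T = np.zeros((len(pids), m))
            W = np.zeros((len(pids), m))
            M = np.zeros((len(pids), m))
            for s, pid in enumerate(pids):
                sub = grouped[pid]
                k = len(sub)
                T[s, :k] = sub["ga_days"].to_numpy(dtype=float)
                W[s, :k] = sub["weight_kg"].to_numpy(dtype=float) - self.offset
                M[s, :k] = 1.0
                self.subject_rows[len(self.participant_ids)] = [gi, s]
                self.participant_ids.append(pid)
                self.group_idx_list.append(gi)
            self.T[gi], self.W[gi], self.mask[gi] = T, W * M, M
            self.groups_present.append(gi)
        self.group_idx = np.array(self.group_idx_list)
        self.n_obs = int(sum(self.mask[g].sum() for g in self.groups_present))
        if self.n_obs < 2:
            raise ValueError("need at least two weight observations")

    def design(self, gi: int, tau_g: float):
        T, mask = self.T[gi], self.mask[gi]
        x1 = np.minimum(T, tau_g) * mask
        x2 = np.maximum(T - tau_g, 0.0) * mask
        return np.stack([mask, x1, x2], axis=-1)  # (S, m, 3)


def _phi_unpack(phi: np.ndarray):
    theta_tau = phi[:3]
    tau = 50.0 + 200.0 / (1.0 + np.exp(-theta_tau))
    L = np.zeros((3, 3))
    for pos, (r, c) in enumerate(_TRIL):
        val = phi[3 + pos]
        L[r, c] = np.exp(val) if pos in _DIAG_POS else val
    sigma = float(np.exp(phi[9]))
    return tau, L, sigma


def _log_prior_tau_theta(theta, priors: Priors) -> float:
    # U(50, 250) on tau times the logit-transform Jacobian (constants dropped).
    s = 1.0 / (1.0 + np.exp(-np.asarray(theta, dtype=float)))
    return float(np.sum(np.log(s) + np.log1p(-s)))


def _log_prior_vc(phi_vc: np.ndarray, priors: Priors) -> float:
    # Variance components: half-Normal diag / Normal off-diag Cholesky priors
    # and half-Normal sigma, plus log-transform Jacobians.
    diag_scales = np.asarray(priors.chol_diag_scales)
    lp = 0.0
    for pos in range(6):
        val = phi_vc[pos]
        if pos in _DIAG_POS:
            k = _DIAG_POS.index(pos)
            x = np.exp(val)
            lp += -0.5 * (x / diag_scales[k]) ** 2 + val
        else:
            lp += -0.5 * (val / priors.chol_offdiag_scale) ** 2
    sigma = np.exp(phi_vc[6])
    lp += -0.5 * (sigma / priors.sigma_scale) ** 2 + phi_vc[6]
    return float(lp)


def _log_prior_phi(phi: np.ndarray, priors: Priors) -> float:
    return _log_prior_tau_theta(phi[:3], priors) + _log_prior_vc(phi[3:], priors)


def _single_group_stats(data: ModelData, gi: int, tau_g: float, Sigma, sigma2: float):
    """Sufficient statistics of one arm's marginal Gaussian likelihood.

    M = sum_s X_s' V_s^-1 X_s, v = sum_s X_s' V_s^-1 w_s, w2 = sum_s w_s'
    V_s^-1 w_s, the summed log-determinants, and the padding correction so
    padded slots contribute nothing.
    """
    X = data.design(gi, tau_g)
    S, m, _ = X.shape
    V = np.einsum("smi,ij,snj->smn", X, Sigma, X, optimize=True)
    V[:, np.arange(m), np.arange(m)] += sigma2
    cho = np.linalg.cholesky(V)
    B = np.concatenate([X, data.W[gi][..., None]], axis=-1)  # (S, m, 4)
    Y = np.linalg.solve(cho, B)
    Yx, Yw = Y[..., :3], Y[..., 3]
    M = np.einsum("smk,sml->kl", Yx, Yx)
    v = np.einsum("smk,sm->k", Yx, Yw)
    w2 = float(np.sum(Yw**2))
    logdet = float(2.0 * np.sum(np.log(np.diagonal(cho, axis1=1, axis2=2))))
    n_pad = int(S * m - data.mask[gi].sum())
    pad_adj = 0.5 * n_pad * (_LOG2PI + np.log(sigma2))
    return (M, v, w2, logdet, pad_adj, S * m)


def _group_stats(data: ModelData, tau, Sigma, sigma2: float):
    return {
        gi: _single_group_stats(data, gi, tau[gi], Sigma, sigma2)
        for gi in data.groups_present
    }


def _loglik_one_group(stat, beta: np.ndarray, gi: int) -> float:
    M, v, w2, logdet, pad_adj, m_tot = stat
    b3 = beta[_beta_indices(gi)]
    quad = w2 - 2.0 * b3 @ v + b3 @ M @ b3
    return float(-0.5 * (quad + logdet + m_tot * _LOG2PI) + pad_adj)


def _beta_indices(gi: int):
    return [0, 1 + gi, 4 + gi]


def _loglik_from_stats(stats, beta: np.ndarray) -> float:
    ll = 0.0
    for gi, (M, v, w2, logdet, pad_adj, m_tot) in stats.items():
        b3 = beta[_beta_indices(gi)]
        quad = w2 - 2.0 * b3 @ v + b3 @ M @ b3
        ll += -0.5 * (quad + logdet + m_tot * _LOG2PI) + pad_adj
    return float(ll)


def _gibbs_beta(stats, priors: Priors, rng: np.random.Generator) -> np.ndarray:
    prior_var = np.array([priors.beta0_scale**2] + [priors.slope_scale**2] * 6)
    P = np.diag(1.0 / prior_var)
    rhs = np.zeros(7)
    rhs[0] = priors.beta0_loc / prior_var[0]
    for gi, (M, v, *_rest) in stats.items():
        idx = _beta_indices(gi)
        P[np.ix_(idx, idx)] += M
        rhs[idx] += v
    cho = np.linalg.cholesky(P)
    mean = np.linalg.solve(P, rhs)
    z = rng.standard_normal(7)
    return mean + np.linalg.solve(cho.T, z)


def _prior_beta(priors: Priors, rng: np.random.Generator) -> np.ndarray:
    sd = np.array([priors.beta0_scale] + [priors.slope_scale] * 6)
    mean = np.zeros(7)
    mean[0] = priors.beta0_loc
    return mean + sd * rng.standard_normal(7)


def _initial_state(data: ModelData, config: SamplerConfig, rng: np.random.Generator):
    # Least squares with the change-points pinned at tau_init, then jitter.
    rows, resp = [], []
    for gi in data.groups_present:
        X = data.design(gi, config.tau_init)
        mask = data.mask[gi].astype(bool)
        Xf, Wf = X[mask], data.W[gi][mask]
        A = np.zeros((len(Wf), 7))
        A[:, _beta_indices(gi)] = Xf
        rows.append(A)
        resp.append(Wf)
    A = np.vstack(rows)
    w = np.concatenate(resp)
    beta, *_ = np.linalg.lstsq(A, w, rcond=None)
    resid_sd = float(np.std(w - A @ beta)) or 0.5

    tau0 = config.tau_init + rng.uniform(-config.tau_init_jitter, config.tau_init_jitter, 3)
    tau0 = np.clip(tau0, 55.0, 245.0)
    theta = np.log((tau0 - 50.0) / (250.0 - tau0))
    phi = np.empty(10)
    phi[:3] = theta
    chol_init = {0: np.log(5.0), 2: np.log(0.02), 5: np.log(0.02)}
    for pos in range(6):
        if pos in _DIAG_POS:
            phi[3 + pos] = chol_init[pos] + rng.normal(0.0, 0.2)
        else:
            phi[3 + pos] = rng.normal(0.0, 0.005)
    phi[9] = np.log(max(resid_sd, 0.1)) + rng.normal(0.0, 0.2)
    beta = beta + rng.normal(0.0, 0.1, 7) * np.array([1, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01])
    return phi, beta


def _draw_subject_effects(data, tau, Sigma, sigma, beta, rng):
    """Exact conditional draw b_i | theta, beta, data for every subject."""
    b = np.zeros((len(data.participant_ids), 3))
    sig2 = sigma**2
    try:
        Sigma_inv = np.linalg.inv(Sigma + 1e-12 * np.eye(3))
    except np.linalg.LinAlgError:
        return b
    offset_rows = {}
    pos = 0
    for gi in data.groups_present:
        S = data.T[gi].shape[0]
        offset_rows[gi] = pos
        pos += S
    for gi in data.groups_present:
        X = data.design(gi, tau[gi])
        r = data.W[gi] - X @ beta[_beta_indices(gi)]
        XtX = np.einsum("smi,smj->sij", X, X)
        P = Sigma_inv[None] + XtX / sig2
        rhs = np.einsum("smi,sm->si", X, r) / sig2
        cho = np.linalg.cholesky(P)
        mean = np.linalg.solve(P, rhs[..., None])[..., 0]
        z = rng.standard_normal(mean.shape)
        dev = np.linalg.solve(np.transpose(cho, (0, 2, 1)), z[..., None])[..., 0]
        b[offset_rows[gi]:offset_rows[gi] + len(mean)] = mean + dev
    return b


def sample_posterior(
    observations: pd.DataFrame,
    participants: pd.DataFrame | None = None,
    config: SamplerConfig | None = None,
    priors: Priors | None = None,
    prior_only: bool = False,
    store_subject_effects: bool = True,
) -> PosteriorDraws:
    """Run the blocked MCMC sampler and return retained posterior draws.

    ``prior_only=True`` switches the data term off (a zero-information run),
    so the draws should recover the prior -- in particular Uniform(50, 250)
    change-points.  Deterministic given ``config.seed``.
    """
    config = config or SamplerConfig()
    priors = priors or Priors()
    data = ModelData(observations, participants)
    n_warm, n_keep = config.n_warmup, config.n_retained
    C, S = config.n_chains, len(data.participant_ids)

    out = PosteriorDraws(
        beta0=np.zeros((C, n_keep)),
        beta1=np.zeros((C, n_keep, 3)),
        beta2=np.zeros((C, n_keep, 3)),
        tau=np.zeros((C, n_keep, 3)),
        Sigma=np.zeros((C, n_keep, 3, 3)),
        sigma=np.zeros((C, n_keep)),
        b=np.zeros((C, n_keep, S, 3)) if store_subject_effects else np.zeros((C, 0, S, 3)),
        participant_ids=list(data.participant_ids),
        group_idx=data.group_idx.copy(),
    )

    seed_seqs = np.random.SeedSequence(config.seed).spawn(C)
    d_vc = 7  # Cholesky (6) + log sigma
    vc_base_steps = np.array([0.05, 0.01, 0.1, 0.01, 0.01, 0.1, 0.05])

    for chain, ss in enumerate(seed_seqs):
        rng = np.random.Generator(np.random.PCG64(ss))
        phi = beta = None
        for _attempt in range(config.max_init_retries):
            phi_try, beta_try = _initial_state(data, config, rng)
            tau, L, sigma = _phi_unpack(phi_try)
            if prior_only:
                phi, beta = phi_try, beta_try
                break
            stats = _group_stats(data, tau, L @ L.T, sigma**2)
            if np.isfinite(_loglik_from_stats(stats, beta_try)):
                phi, beta = phi_try, beta_try
                break
        if phi is None:
            raise RuntimeError("could not find a finite initial state")

        if not prior_only:
            tau, L, sigma = _phi_unpack(phi)
            Sigma = L @ L.T
            sigma2 = sigma**2
            stats = _group_stats(data, tau, Sigma, sigma2)

        # Block-specific adaptive proposals: one 1-D walker per change-point
        # (each tau_g touches only its own arm's likelihood) and one 7-D
        # walker for the variance components.
        tau_log_step = {gi: np.log(0.2) for gi in range(3)}
        vc_prop_chol = np.diag(vc_base_steps)
        vc_log_scale = 0.0
        vc_history = np.zeros((n_warm, d_vc))

        for it in range(config.n_iterations):
            beta = _prior_beta(priors, rng) if prior_only else _gibbs_beta(stats, priors, rng)
            gamma = 1.0 / (1.0 + it / 50.0) ** 0.6 if it < n_warm else 0.0

            # --- change-point updates, one arm at a time -------------------
            for gi in (data.groups_present if not prior_only else range(3)):
                theta_cur = phi[gi]
                theta_prop = theta_cur + np.exp(
                    tau_log_step.get(gi, np.log(0.2))
                ) * rng.standard_normal()
                lp_cur = _log_prior_tau_theta([theta_cur], priors)
                lp_prop = _log_prior_tau_theta([theta_prop], priors)
                if prior_only:
                    log_alpha = lp_prop - lp_cur
                    stat_prop = None
                else:
                    tau_prop_g = 50.0 + 200.0 / (1.0 + np.exp(-theta_prop))
                    stat_prop = _single_group_stats(data, gi, tau_prop_g, Sigma, sigma2)
                    ll_cur_g = _loglik_one_group(stats[gi], beta, gi)
                    ll_prop_g = _loglik_one_group(stat_prop, beta, gi)
                    log_alpha = (ll_prop_g + lp_prop) - (ll_cur_g + lp_cur)
                if np.log(rng.random()) < log_alpha:
                    phi[gi] = theta_prop
                    if not prior_only:
                        stats[gi] = stat_prop
                        tau[gi] = tau_prop_g
                if it < n_warm and gi in tau_log_step:
                    acc_prob = min(1.0, np.exp(min(log_alpha, 0.0)))
                    tau_log_step[gi] += gamma * (acc_prob - 0.44)

            # --- variance components (Sigma Cholesky + sigma), jointly ----
            vc_cur = phi[3:]
            step = np.exp(vc_log_scale) * (vc_prop_chol @ rng.standard_normal(d_vc))
            vc_prop = vc_cur + step
            lp_cur = _log_prior_vc(vc_cur, priors)
            lp_prop = _log_prior_vc(vc_prop, priors)
            if prior_only:
                log_alpha = lp_prop - lp_cur
            else:
                phi_prop = np.concatenate([phi[:3], vc_prop])
                _tau_p, L_p, sigma_p = _phi_unpack(phi_prop)
                stats_prop = _group_stats(data, tau, L_p @ L_p.T, sigma_p**2)
                ll_cur = _loglik_from_stats(stats, beta)
                ll_prop = _loglik_from_stats(stats_prop, beta)
                log_alpha = (ll_prop + lp_prop) - (ll_cur + lp_cur)
            if np.log(rng.random()) < log_alpha:
                phi = np.concatenate([phi[:3], vc_prop])
                if not prior_only:
                    stats = stats_prop
                    L, sigma = L_p, sigma_p
                    Sigma = L @ L.T
                    sigma2 = sigma**2
            if it < n_warm:
                vc_history[it] = phi[3:]
                acc_prob = min(1.0, np.exp(min(log_alpha, 0.0)))
                vc_log_scale += 0.3 * gamma * (acc_prob - config.target_accept)
                if it >= config.adapt_start and (it + 1) % config.adapt_interval == 0:
                    window = vc_history[it // 2:it + 1]
                    cov = np.cov(window.T) + 1e-9 * np.eye(d_vc)
                    try:
                        vc_prop_chol = np.linalg.cholesky(cov) * (2.38 / np.sqrt(d_vc))
                    except np.linalg.LinAlgError:
                        pass
            else:
                k = it - n_warm
                tau_k, L_k, sigma_k = _phi_unpack(phi)
                Sigma_k = L_k @ L_k.T
                out.beta0[chain, k] = beta[0] + data.offset
                out.beta1[chain, k] = beta[1:4]
                out.beta2[chain, k] = beta[4:7]
                out.tau[chain, k] = tau_k
                out.Sigma[chain, k] = Sigma_k
                out.sigma[chain, k] = sigma_k
                if store_subject_effects:
                    if prior_only:
                        out.b[chain, k] = rng.multivariate_normal(
                            np.zeros(3), Sigma_k, size=S
                        ) if S else np.zeros((S, 3))
                    else:
                        out.b[chain, k] = _draw_subject_effects(
                            data, tau_k, Sigma_k, sigma_k, beta, rng
                        )
    return out


def convergence_diagnostics(draws, rhat_threshold: float = 1.01) -> pd.DataFrame:
    """Split-R-hat and effective sample size per parameter (via ArviZ).

    Accepts a :class:`PosteriorDraws` or a mapping of name -> (chain, draw)
    arrays.  The returned frame carries a ``converged`` attribute in
    ``.attrs``: True when every fixed effect has R-hat below the threshold.
    Requires at least two chains.
    """
    import arviz as az

    arrays = draws.scalar_arrays() if isinstance(draws, PosteriorDraws) else dict(draws)
    first = next(iter(arrays.values()))
    if first.shape[0] < 2:
        raise ValueError("R-hat requires at least two chains")
    idata = az.from_dict(posterior={k: np.asarray(v) for k, v in arrays.items()})
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = []
    fixed_names = set()
    if isinstance(draws, PosteriorDraws):
        fixed_names = set(draws.fixed_effect_arrays())
    for name in arrays:
        rows.append(
            {
                "parameter": name,
                "rhat": float(rhat[name].values),
                "ess": float(ess[name].values),
                "is_fixed_effect": name in fixed_names,
            }
        )
    table = pd.DataFrame(rows).set_index("parameter")
    fixed = table[table["is_fixed_effect"]] if fixed_names else table
    table.attrs["converged"] = bool((fixed["rhat"] < rhat_threshold).all())
    return table
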