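"""Mean structure, likelihoods and log-posterior of the broken-stick model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, stats as sps

from gwgbayes.model import (
    GROUPS,
    DomainError,
    Priors,
    SubjectEffects,
    TrajectoryParameters,
    broken_stick_basis,
    log_likelihood,
    log_marginal_fixed_tau,
    log_posterior,
    mean_weight,
)


def make_params(**kw):
    defaults = dict(
        beta0=65.0,
        beta1=[0.05, 0.04, 0.03],
        beta2=[0.08, 0.07, 0.06],
        tau=[100.0, 120.0, 140.0],
        Sigma=np.diag([4.0, 1e-4, 1e-4]),
        sigma=1.0,
    )
    defaults.update(kw)
    return TrajectoryParameters(**defaults)


ZERO = SubjectEffects()


class TestMeanWeight:
    def test_intercept_at_t_zero(self):
        params = make_params()
        eff = SubjectEffects(b0=2.5)
        assert mean_weight(params, eff, "EXE", 0) == pytest.approx(67.5)

    def test_hand_computed_value(self):
        # 65 + 0.05*100 + 0.08*100 at t=200 with tau=100
        params = make_params(beta1=0.05, beta2=0.08, tau=100.0)
        assert mean_weight(params, ZERO, "CON", 200) == pytest.approx(78.0)

    def test_continuity_at_change_point(self):
        params = make_params()
        for g, tau in zip(GROUPS, params.tau):
            eps = 1e-9
            below = mean_weight(params, ZERO, g, tau - eps)
            above = mean_weight(params, ZERO, g, tau + eps)
            assert above == pytest.approx(below, abs=1e-6)
            assert mean_weight(params, ZERO, g, tau) == pytest.approx(below, abs=1e-6)

    @given(
        tau=st.floats(60, 240),
        b1=st.floats(-0.05, 0.05),
        b2=st.floats(-0.05, 0.05),
    )
    def test_piecewise_linear_second_differences(self, tau, b1, b2):
        """Second differences vanish except across the change-point."""
        params = make_params(tau=tau, beta1=b1, beta2=b2)
        t = np.arange(0, 300, dtype=float)
        mu = mean_weight(params, ZERO, "CON", t)
        d2 = np.diff(mu, 2)
        kink = np.abs(t[1:-1] - tau) <= 1.0
        assert np.allclose(d2[~kink], 0.0, atol=1e-9)

    def test_unknown_group_raises(self):
        with pytest.raises(DomainError):
            mean_weight(make_params(), ZERO, "XYZ", 10)

    def test_negative_time_raises(self):
        with pytest.raises(DomainError):
            mean_weight(make_params(), ZERO, "CON", -1)


class TestTrajectoryParameters:
    def test_exactly_ten_fixed_effects(self):
        assert make_params().n_fixed_effects == 10
        assert len(make_params().fixed_effect_dict()) == 10

    def test_group_specific_intercept_impossible(self):
        """The intercept is a scalar by contract; a vector is rejected."""
        with pytest.raises((TypeError, ValueError)):
            TrajectoryParameters(
                beta0=[65.0, 66.0, 67.0], beta1=0.05, beta2=0.08, tau=100.0
            ).fixed_effect_dict()

    @pytest.mark.parametrize(
        "kw",
        [
            dict(tau=40.0),
            dict(tau=260.0),
            dict(sigma=-1.0),
            dict(Sigma=np.array([[1, 2, 0], [0, 1, 0], [0, 0, 1.0]])),
            dict(Sigma=-np.eye(3)),
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            make_params(**kw)


def random_instance(seed, n_subjects=5, n_obs=4):
    rng = np.random.default_rng(seed)
    params = make_params(Sigma=np.diag([4.0, 1e-4, 4e-4]))
    rows = []
    effects = {}
    for i in range(n_subjects):
        pid = f"S{i}"
        g = GROUPS[i % 3]
        effects[pid] = SubjectEffects(*rng.multivariate_normal(np.zeros(3), params.Sigma))
        for t in rng.integers(0, 290, n_obs):
            mu = mean_weight(params, effects[pid], g, float(t))
            rows.append((pid, int(t), mu + rng.normal(0, params.sigma), g))
    obs = pd.DataFrame(rows, columns=["participant_id", "ga_days", "weight_kg", "group"])
    return params, effects, obs


class TestLogLikelihood:
    def test_zero_residual_single_observation(self):
        params = make_params(sigma=1.0)
        obs = pd.DataFrame(
            {
                "participant_id": ["A"],
                "ga_days": [0],
                "weight_kg": [65.0],
                "group": ["CON"],
            }
        )
        ll = log_likelihood(params, {"A": ZERO}, obs)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_matches_direct_normal_density_oracle(self):
        params, effects, obs = random_instance(7, n_subjects=5, n_obs=4)
        expected = 0.0
        for row in obs.itertuples(index=False):
            mu = mean_weight(params, effects[row.participant_id], row.group, row.ga_days)
            expected += sps.norm.logpdf(row.weight_kg, mu, params.sigma)
        assert log_likelihood(params, effects, obs) == pytest.approx(expected, abs=1e-10)

    def test_intercept_reparameterization_invariance(self):
        params, effects, obs = random_instance(11)
        base = log_likelihood(params, effects, obs)
        c = 3.7
        shifted = make_params(beta0=params.beta0 + c, Sigma=params.Sigma)
        shifted_eff = {
            k: SubjectEffects(e.b0 - c, e.b1, e.b2) for k, e in effects.items()
        }
        assert log_likelihood(shifted, shifted_eff, obs) == pytest.approx(base, abs=1e-9)

    def test_observation_order_invariance(self):
        params, effects, obs = random_instance(13)
        shuffled = obs.sample(frac=1.0, random_state=1)
        assert log_likelihood(params, effects, obs) == pytest.approx(
            log_likelihood(params, effects, shuffled), abs=1e-10
        )

    def test_nonpositive_sigma_raises(self):
        params, effects, obs = random_instance(5)
        params.sigma = 0.0
        with pytest.raises(DomainError):
            log_likelihood(params, effects, obs)


class TestLogMarginal:
    def test_sigma_zero_equals_conditional_at_zero_effects(self):
        params, _, obs = random_instance(17)
        params0 = make_params(
            beta0=params.beta0, Sigma=np.zeros((3, 3)), sigma=params.sigma
        )
        effects0 = {pid: ZERO for pid in obs["participant_id"].unique()}
        assert log_marginal_fixed_tau(params0, obs) == pytest.approx(
            log_likelihood(params0, effects0, obs), abs=1e-8
        )

    def test_quadrature_oracle_one_subject(self):
        """2-D numerical integration over (b0, b1), with no b2 deviation."""
        params = make_params(Sigma=np.diag([2.0, 1e-4, 0.0]), sigma=0.7)
        obs = pd.DataFrame(
            {
                "participant_id": ["A"] * 3,
                "ga_days": [0, 120, 250],
                "weight_kg": [66.0, 71.5, 81.0],
                "group": ["CON"] * 3,
            }
        )

        def integrand(b1, b0):
            eff = SubjectEffects(b0, b1, 0.0)
            ll = log_likelihood(params, {"A": eff}, obs)
            prior = sps.norm.logpdf(b0, 0, np.sqrt(2.0)) + sps.norm.logpdf(
                b1, 0, 1e-2
            )
            return np.exp(ll + prior)

        val, _err = integrate.dblquad(
            integrand, -6.0, 6.0, lambda _: -0.05, lambda _: 0.05, epsabs=1e-12
        )
        assert log_marginal_fixed_tau(params, obs) == pytest.approx(
            np.log(val), abs=1e-4
        )

    def test_monte_carlo_oracle(self):
        params = make_params(Sigma=np.diag([1.0, 4e-5, 9e-5]), sigma=0.6)
        obs = pd.DataFrame(
            {
                "participant_id": ["A"] * 4,
                "ga_days": [0, 90, 180, 270],
                "weight_kg": [65.5, 69.0, 74.0, 80.0],
                "group": ["EXE"] * 4,
            }
        )
        rng = np.random.default_rng(0)
        n = 200_000
        b = rng.multivariate_normal(np.zeros(3), params.Sigma, size=n)
        X = broken_stick_basis(obs["ga_days"].to_numpy(dtype=float), params.tau[1])
        mu0 = X @ np.array([params.beta0, params.beta1[1], params.beta2[1]])
        mu = mu0[None, :] + b @ X.T
        w = obs["weight_kg"].to_numpy()
        ll = np.sum(sps.norm.logpdf(w[None, :], mu, params.sigma), axis=1)
        m = ll.max()
        vals = np.exp(ll - m)
        estimate = m + np.log(vals.mean())
        mc_se = vals.std() / (vals.mean() * np.sqrt(n))
        assert abs(log_marginal_fixed_tau(params, obs) - estimate) < 3 * mc_se + 1e-8

    def test_non_psd_sigma_raises(self):
        params, _, obs = random_instance(3)
        params.Sigma = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(DomainError):
            log_marginal_fixed_tau(params, obs)


class TestLogPosterior:
    def test_tau_outside_prior_support_is_minus_inf(self):
        params, effects, obs = random_instance(23)
        params.tau = np.array([40.0, 120.0, 140.0])  # bypass validation on purpose
        priors = Priors()
        assert log_posterior(params, effects, obs, priors) == -np.inf

    def test_equals_sum_of_components(self):
        params, effects, obs = random_instance(29)
        params = make_params(Sigma=np.diag([4.0, 1e-4, 4e-4]))
        priors = Priors()
        expected = (
            log_likelihood(params, effects, obs)
            + priors.log_prior_fixed(params.beta0, params.beta1, params.beta2)
            + priors.log_prior_tau(params.tau)
            + priors.log_prior_sigma(params.sigma)
            + priors.log_prior_chol(np.linalg.cholesky(params.Sigma))
            + sum(
                sps.multivariate_normal.logpdf(e.as_array(), np.zeros(3), params.Sigma)
                for e in effects.values()
            )
        )
        assert log_posterior(params, effects, obs, priors) == pytest.approx(
            expected, abs=1e-10
        )

    def test_difference_under_diffuse_priors_tracks_likelihood(self):
        """With near-flat priors, posterior differences reduce to likelihood differences."""
        _, effects, obs = random_instance(31)
        wide = Priors(beta0_scale=1e8, slope_scale=1e8, sigma_scale=1e8,
                      chol_diag_scales=(1e8, 1e8, 1e8), chol_offdiag_scale=1e8)
        p1 = make_params(beta1=0.05, Sigma=np.diag([4.0, 1e-4, 4e-4]))
        p2 = make_params(beta1=0.02, Sigma=np.diag([4.0, 1e-4, 4e-4]))
        dpost = log_posterior(p1, effects, obs, wide) - log_posterior(p2, effects, obs, wide)
        dlik = log_likelihood(p1, effects, obs) - log_likelihood(p2, effects, obs)
        assert dpost == pytest.approx(dlik, abs=1e-6)
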