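import numpy as np
import pytest
from dataclasses import replace

from hypothesis import settings

from gwgbayes.cohort import CohortConfig, default_true_params, generate_cohort
from gwgbayes.inference import SamplerConfig, sample_posterior
from gwgbayes.model import attach_groups

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lownoise_cohort():
    """Fully observed cohort with tiny noise: subject curves ~ group curves."""
    params = replace(
        default_true_params(), Sigma=np.diag([1e-4, 1e-8, 1e-8]), sigma=0.1
    )
    config = CohortConfig(
        n_participants=40,
        true_params=params,
        selfreport_bias_sd=0.0,
        lost_to_followup_prob=0.0,
        seed=4,
    )
    participants, weights, outcomes = generate_cohort(config)
    return config, participants, weights, outcomes


@pytest.fixture(scope="session")
def lownoise_fit(lownoise_cohort):
    """A converged short fit of the low-noise cohort, shared across tests."""
    config, participants, weights, _ = lownoise_cohort
    draws = sample_posterior(
        attach_groups(weights, participants),
        participants,
        SamplerConfig(n_chains=2, n_iterations=1500, seed=3),
    )
    return config, participants, weights, draws


@pytest.fixture(scope="session")
def standard_cohort():
    """Realistic noise and between-subject variation, fully observed."""
    config = CohortConfig(n_participants=40, lost_to_followup_prob=0.0, seed=8)
    participants, weights, outcomes = generate_cohort(config)
    return config, participants, weights, outcomes


@pytest.fixture(scope="session")
def standard_fit(standard_cohort):
    """Fit of the realistic cohort; variance components are identifiable here."""
    config, participants, weights, _ = standard_cohort
    draws = sample_posterior(
        attach_groups(weights, participants),
        participants,
        SamplerConfig(n_chains=2, n_iterations=2500, seed=12),
    )
    return config, participants, weights, draws


@pytest.fixture(scope="session")
def default_cohort():
    """One realistic default cohort (trial-sized, with dropout and noise)."""
    config = CohortConfig(n_participants=219, seed=3)
    participants, weights, outcomes = generate_cohort(config)
    return config, participants, weights, outcomes
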