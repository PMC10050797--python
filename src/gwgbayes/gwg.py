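"""Subject-level weight prediction and gestational-weight-gain standardization.

GWG at a standardized gestational age t is the difference between the
model-predicted weight at t and the predicted pre-pregnancy weight (t = 0),
evaluated per posterior draw and summarized by the posterior mean and a
central 95% interval.  Standard timepoints: 12+0, 28+0 and 40+0 weeks
(84, 196, 280 days); "total GWG" is the 280-day value, which standardizes
pregnancies that deliver earlier or later to a common 40-week horizon.

Group-level inference follows the trial's frequentist workflow: one-way
ANOVA and Tukey pairwise comparisons on the subject-level point estimates,
with normal-theory confidence intervals for group means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as outcome_stats
from .inference import PosteriorDraws

STANDARD_TIMEPOINTS = (84, 196, 280)  # 12+0, 28+0, 40+0 weeks in days


@dataclass
class PredictionSummary:
    mean: float
    ci_low: float
    ci_high: float


def _mu_draws(draws: PosteriorDraws, idx: int, t: float) -> np.ndarray:
    g = int(draws.group_idx[idx])
    tau = draws.tau[..., g]
    x1 = np.minimum(t, tau)
    x2 = np.maximum(t - tau, 0.0)
    b = draws.b[:, :, idx, :]
    return (
        draws.beta0 + b[..., 0]
        + (draws.beta1[..., g] + b[..., 1]) * x1
        + (draws.beta2[..., g] + b[..., 2]) * x2
    )


def _gain_draws(draws: PosteriorDraws, idx: int, t: float) -> np.ndarray:
    # mu(t) - mu(0): the intercept and b0 cancel exactly.
    g = int(draws.group_idx[idx])
    tau = draws.tau[..., g]
    x1 = np.minimum(t, tau)
    x2 = np.maximum(t - tau, 0.0)
    b = draws.b[:, :, idx, :]
    return (draws.beta1[..., g] + b[..., 1]) * x1 + (draws.beta2[..., g] + b[..., 2]) * x2


def _summarize(values: np.ndarray) -> PredictionSummary:
    lo, hi = np.percentile(values, [2.5, 97.5])
    return PredictionSummary(float(values.mean()), float(lo), float(hi))


def predict_weight(draws: PosteriorDraws, participant_id: str, t: float) -> PredictionSummary:
    """Posterior summary of a subject's mean weight at gestational day ``t``.

    Extrapolates along the subject's fitted broken-stick line when ``t``
    exceeds their delivery day (that is the point of standardization).
    """
    if t < 0:
        raise ValueError("gestational age must be non-negative")
    idx = draws.subject_index(participant_id)
    return _summarize(_mu_draws(draws, idx, float(t)))


def estimate_gwg(
    draws: PosteriorDraws,
    participant_id: str,
    timepoints=STANDARD_TIMEPOINTS,
) -> pd.DataFrame:
    """Per-draw GWG mu(t) - mu(0) for one subject, summarized per timepoint."""
    idx = draws.subject_index(participant_id)
    rows = []
    for t in timepoints:
        if t < 0:
            raise ValueError("timepoints must be non-negative")
        w = _summarize(_mu_draws(draws, idx, float(t)))
        gain = _summarize(_gain_draws(draws, idx, float(t)))
        rows.append(
            {
                "participant_id": participant_id,
                "timepoint_days": int(t),
                "weight_hat": w.mean, "weight_lo": w.ci_low, "weight_hi": w.ci_high,
                "gwg_hat": gain.mean, "gwg_lo": gain.ci_low, "gwg_hi": gain.ci_high,
            }
        )
    return pd.DataFrame(rows)


def estimate_gwg_all(draws: PosteriorDraws, timepoints=STANDARD_TIMEPOINTS) -> pd.DataFrame:
    """Tidy per-subject GWG summaries at every timepoint (vectorized)."""
    S = len(draws.participant_ids)
    g = draws.group_idx
    frames = []
    for t in timepoints:
        if t < 0:
            raise ValueError("timepoints must be non-negative")
        tau = draws.tau[..., :]  # (C, D, 3)
        x1 = np.minimum(float(t), tau)[..., g]   # (C, D, S)
        x2 = np.maximum(float(t) - tau, 0.0)[..., g]
        slope1 = draws.beta1[..., g] + draws.b[..., 1]
        slope2 = draws.beta2[..., g] + draws.b[..., 2]
        gain = slope1 * x1 + slope2 * x2         # (C, D, S)
        weight = gain + draws.beta0[..., None] + draws.b[..., 0]
        flat_g = gain.reshape(-1, S)
        flat_w = weight.reshape(-1, S)
        qg = np.percentile(flat_g, [2.5, 97.5], axis=0)
        qw = np.percentile(flat_w, [2.5, 97.5], axis=0)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": draws.participant_ids,
                    "timepoint_days": int(t),
                    "weight_hat": flat_w.mean(axis=0),
                    "weight_lo": qw[0], "weight_hi": qw[1],
                    "gwg_hat": flat_g.mean(axis=0),
                    "gwg_lo": qg[0], "gwg_hi": qg[1],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def group_gwg_summary(
    estimates: pd.DataFrame, participants: pd.DataFrame, timepoint: int
) -> dict:
    """Per-arm mean GWG with normal-theory 95% CI, ANOVA p and Tukey pairs.

    ``estimates`` is the output of :func:`estimate_gwg_all`; group membership
    comes from ``participants``.
    """
    sub = estimates[estimates["timepoint_days"] == int(timepoint)]
    if sub.empty:
        raise ValueError(f"no estimates at timepoint {timepoint}")
    merged = sub.merge(participants[["participant_id", "group"]], on="participant_id")
    counts = merged.groupby("group").size()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("each arm needs at least two subjects for group inference")
    rows = []
    for g, chunk in merged.groupby("group"):
        vals = chunk["gwg_hat"].to_numpy()
        n = len(vals)
        se = vals.std(ddof=1) / np.sqrt(n)
        tcrit = sps.t.ppf(0.975, n - 1)
        rows.append(
            {
                "group": g, "n": n, "mean_gwg": float(vals.mean()),
                "ci_low": float(vals.mean() - tcrit * se),
                "ci_high": float(vals.mean() + tcrit * se),
            }
        )
    anova = outcome_stats.one_way_anova(
        merged["gwg_hat"].to_numpy(), merged["group"].to_numpy()
    )
    tukey = outcome_stats.tukey_pairwise(
        merged["gwg_hat"].to_numpy(), merged["group"].to_numpy()
    )
    return {
        "timepoint_days": int(timepoint),
        "groups": pd.DataFrame(rows),
        "anova": anova,
        "tukey": tukey,
    }


def complete_case_gwg(
    participants: pd.DataFrame, observations: pd.DataFrame
) -> tuple[pd.DataFrame, float | None]:
    """Traditional GWG: delivery weight minus self-reported pre-pregnancy weight.

    Only subjects with a delivery-source weight measurement contribute; the
    rest are excluded (this is the complete-case comparator to the
    model-standardized GWG).  Returns the per-subject table and the one-way
    ANOVA p-value across arms (None when it is not computable).
    """
    deliv = observations[observations["source"] == "delivery"]
    deliv = deliv.sort_values("ga_days").groupby("participant_id", as_index=False).last()
    merged = deliv.merge(
        participants[["participant_id", "group", "prepreg_weight_selfreport"]],
        on="participant_id",
    )
    merged["gwg"] = merged["weight_kg"] - merged["prepreg_weight_selfreport"]
    table = merged[["participant_id", "group", "ga_days", "gwg"]].reset_index(drop=True)
    p = None
    counts = table.groupby("group").size()
    if len(counts) >= 2 and (counts >= 2).all():
        try:
            p = outcome_stats.one_way_anova(
                table["gwg"].to_numpy(), table["group"].to_numpy()
            ).p_value
        except ValueError:
            p = None
    return table, p
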