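"""Synthetic randomized-trial cohorts with the structure the analysis assumes.

Emulates a three-arm pregnancy trial: 1:2:2 allocation to standard care
(CON), supervised exercise (EXE) and motivational counselling (MOT);
enrolment at GA <= 15+0 weeks; a self-reported pre-pregnancy weight at GA 0;
clinic weight measurements at baseline, GA 28+0-6 and 34+0-6 weeks and at
delivery; roughly 19% loss to follow-up; and obstetric/neonatal outcomes at
the rates reported for such cohorts.  Subject weight curves follow the
broken-stick mixed model exactly, so model-based recovery of the generating
parameters is a meaningful test.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import GROUPS, SubjectEffects, TrajectoryParameters, mean_weight
from . import neonatal

GA_MAX = 310  # latest representable gestational day

SOURCES = ("prepregnancy_selfreport", "clinic", "home", "delivery")

#: Bernoulli outcome rates, pooled across arms (defaults follow the published
#: frequencies in comparable Danish cohorts of healthy pregnant women).
DEFAULT_OUTCOME_RATES = {
    "gdm": 0.07,
    "hypertensive_disorders": 0.06,
    "induction": 0.30,
    "epidural": 0.33,
    "oxytocin": 0.26,
    "rupture_34": 0.05,
    "pph_gt_1000": 0.11,
    "apgar5_lt_7": 0.01,
}

DEFAULT_MODE_OF_DELIVERY_PROBS = {
    "unassisted_vaginal": 0.77,
    "instrumental_vaginal": 0.05,
    "planned_cesarean": 0.06,
    "emergency_cesarean": 0.12,
}

#: Log-normal (median, log-SD) for skewed duration/haemorrhage variables,
#: split by parity where the clinic reports them separately.
DEFAULT_SKEWED_DISTS = {
    "pph_ml": (350.0, 0.53),
    "labor_total_min_nulliparous": (443.0, 0.60),
    "labor_total_min_multiparous": (150.0, 0.83),
    "second_stage_min_nulliparous": (41.0, 0.80),
    "second_stage_min_multiparous": (13.0, 0.74),
}

#: Per-arm physical-activity summaries (CON, EXE, MOT): MVPA min/week,
#: steps/day, active kcal/day -- means from the trial's published averages.
DEFAULT_PA_DISTS = {
    "mvpa_min_wk": {"mean": (35.4, 53.5, 43.1), "shape": 2.0},
    "steps_per_day": {"mean": (6896.0, 6680.0, 6792.0), "sd": 2000.0},
    "active_kcal_day": {"mean": (562.0, 560.0, 583.0), "sd": 150.0},
}


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


def default_true_params() -> TrajectoryParameters:
    """Population truth for the default synthetic cohort.

    Intercept 68 kg (median pre-pregnancy BMI ~24 at ~1.68 m); slow early
    gain (0.02 kg/day) switching at 100 days to 0.072 kg/day, i.e. ~15 kg
    total gain by 280 days; between-subject SDs 12 kg (intercept), 0.010 and
    0.023 kg/day (slopes), giving a total-GWG SD of ~4.3 kg as observed in
    such trials.
    """
    sd = np.array([12.0, 0.010, 0.023])
    return TrajectoryParameters(
        beta0=68.0,
        beta1=np.full(3, 0.020),
        beta2=np.full(3, 0.072),
        tau=np.full(3, 100.0),
        Sigma=np.diag(sd**2),
        sigma=0.8,
    )


@dataclass
class CohortConfig:
    """Everything the generator needs; defaults reproduce the trial's design."""

    n_participants: int = 219
    allocation_ratio: tuple[int, int, int] = (1, 2, 2)  # CON:EXE:MOT
    true_params: TrajectoryParameters = field(default_factory=default_true_params)
    residual_sd: float | None = None  # kg; defaults to true_params.sigma
    prepreg_weight_dist: tuple[float, float] = (68.0, 12.0)  # informational
    selfreport_bias_sd: float = 2.0  # kg
    height_dist: tuple[float, float] = (168.0, 6.0)  # cm
    baseline_ga_window: tuple[int, int] = (43, 105)  # 6+1 .. 15+0 weeks
    visit_windows: tuple[tuple[int, int], ...] = ((196, 202), (238, 244))
    delivery_ga_dist: tuple[float, float, float, float] = (280.0, 12.0, 196.0, 300.0)
    lost_to_followup_prob: float = 0.19
    covid_prob: float = 0.5
    prob_nulliparous: float = 0.37
    prob_male: float = 0.5
    outcome_rates: dict = field(default_factory=lambda: dict(DEFAULT_OUTCOME_RATES))
    mode_of_delivery_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_MODE_OF_DELIVERY_PROBS)
    )
    skewed_dists: dict = field(default_factory=lambda: dict(DEFAULT_SKEWED_DISTS))
    pa_dists: dict = field(default_factory=lambda: dict(DEFAULT_PA_DISTS))
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 0:
            raise ConfigurationError("n_participants must be non-negative")
        ratio = tuple(int(r) for r in self.allocation_ratio)
        if len(ratio) != 3 or any(r < 0 for r in ratio) or sum(ratio) == 0:
            raise ConfigurationError(
                "allocation_ratio must be three non-negative integers with a positive sum"
            )
        self.allocation_ratio = ratio
        for name, p in [
            ("lost_to_followup_prob", self.lost_to_followup_prob),
            ("covid_prob", self.covid_prob),
            ("prob_nulliparous", self.prob_nulliparous),
            ("prob_male", self.prob_male),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        unknown = set(self.outcome_rates) - set(DEFAULT_OUTCOME_RATES)
        if unknown:
            raise ConfigurationError(f"unknown outcome name(s): {sorted(unknown)}")
        for name, p in self.outcome_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"outcome rate {name} must be in [0, 1]")
        windows = [self.baseline_ga_window, *self.visit_windows]
        for lo, hi in windows:
            if not (0 <= lo <= hi <= GA_MAX):
                raise ConfigurationError(f"day window ({lo}, {hi}) outside [0, {GA_MAX}]")
        mu, sd, lo, hi = self.delivery_ga_dist
        if not (0 <= lo < hi <= GA_MAX):
            raise ConfigurationError("delivery GA truncation bounds must lie in [0, 310]")

    @property
    def sigma(self) -> float:
        return self.true_params.sigma if self.residual_sd is None else self.residual_sd


def allocate_groups(n: int, ratio: tuple[int, int, int]) -> tuple[int, int, int]:
    """Deterministic arm sizes (CON, EXE, MOT) for ``n`` participants.

    The intervention arms receive their floored quota floor(n*r/sum) in order
    EXE, MOT; the control arm absorbs the remainder.  At n=219 with 1:2:2
    this yields (45, 87, 87), the realized sizes of the reference trial.
    """
    total = sum(ratio)
    n_exe = int(np.floor(n * ratio[1] / total))
    n_mot = int(np.floor(n * ratio[2] / total))
    n_con = n - n_exe - n_mot
    if min(n_con, n_exe, n_mot) < 0:
        raise ConfigurationError("allocation produced a negative arm size")
    return (n_con, n_exe, n_mot)


def _participant_rng(seed: int, pid: str) -> np.random.Generator:
    # Stable per-participant stream: independent of generation order and of
    # how many participants precede this one.
    digest = hashlib.sha256(f"{seed}:{pid}".encode()).digest()
    return np.random.Generator(np.random.PCG64(int.from_bytes(digest[:8], "little")))


def _draw_truncated_normal(rng, mu, sd, lo, hi) -> float:
    for _ in range(1000):
        x = rng.normal(mu, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(mu, lo, hi))


def generate_trajectory(
    participant: pd.Series | dict,
    true_params: TrajectoryParameters,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    effects: SubjectEffects | None = None,
) -> pd.DataFrame:
    """Weight observations for one participant.

    Records: self-reported pre-pregnancy weight at GA 0 (extra self-report
    noise on top of the residual), one baseline clinic visit, the scheduled
    visit-window measurements, and a delivery weight -- all truncated at the
    participant's dropout day when they are lost to follow-up.  Measurement
    days are integers; sources are 'home' instead of 'clinic' for visits in
    the COVID period.
    """
    p = dict(participant)
    rng = rng or _participant_rng(config.seed, p["participant_id"])
    if effects is None:
        effects = SubjectEffects(*rng.multivariate_normal(np.zeros(3), true_params.Sigma))
    sigma = config.sigma
    delivery_ga = int(p["delivery_ga"])
    baseline_ga = int(p["baseline_ga"])
    if delivery_ga <= baseline_ga:
        raise ConfigurationError("delivery GA must exceed the baseline GA")

    days: list[int] = [0, baseline_ga]
    sources: list[str] = ["prepregnancy_selfreport", "clinic"]
    visit_source = "home" if p.get("covid_period", False) else "clinic"
    for lo, hi in config.visit_windows:
        day = int(rng.integers(lo, hi + 1))
        if day < delivery_ga:
            days.append(day)
            sources.append(visit_source)
    days.append(delivery_ga)
    sources.append("delivery")

    cutoff = delivery_ga if p.get("completed", True) else int(p["dropout_ga"])
    rows = []
    for day, source in zip(days, sources):
        if source == "delivery" and not p.get("completed", True):
            continue
        if source not in ("prepregnancy_selfreport", "delivery") and day > cutoff:
            continue
        w = mean_weight(true_params, effects, p["group"], day)
        w += rng.normal(0.0, sigma) if sigma > 0 else 0.0
        if source == "prepregnancy_selfreport" and config.selfreport_bias_sd > 0:
            w += rng.normal(0.0, config.selfreport_bias_sd)
        rows.append((p["participant_id"], day, w, source))
    return pd.DataFrame(rows, columns=["participant_id", "ga_days", "weight_kg", "source"])


def generate_outcomes(
    participants: pd.DataFrame, config: CohortConfig
) -> pd.DataFrame:
    """Obstetric and neonatal outcomes for participants followed to delivery.

    Binary outcomes are Bernoulli at the configured rates; birth weight is
    drawn so that its reference z-score is standard Normal at the drawn GA
    and fetal sex (hence SGA and LGA frequencies of 10% each by
    construction); durations and haemorrhage volume come from the configured
    log-normal distributions and are missing for caesarean deliveries.
    """
    rows = []
    for _, p in participants.iterrows():
        if not p["completed"]:
            continue
        rng = _participant_rng(config.seed + 1, p["participant_id"])
        out = {"participant_id": p["participant_id"], "group": p["group"]}
        for name in DEFAULT_OUTCOME_RATES:
            rate = config.outcome_rates.get(name, 0.0)
            out[name] = int(rng.random() < rate)
        modes = list(config.mode_of_delivery_probs)
        probs = np.array([config.mode_of_delivery_probs[m] for m in modes], dtype=float)
        mode = rng.choice(modes, p=probs / probs.sum())
        out["mode_of_delivery"] = mode
        out["nulliparous"] = int(rng.random() < config.prob_nulliparous)
        parity = "nulliparous" if out["nulliparous"] else "multiparous"
        vaginal = mode in ("unassisted_vaginal", "instrumental_vaginal")
        for var in ("labor_total_min", "second_stage_min"):
            med, logsd = config.skewed_dists[f"{var}_{parity}"]
            out[var] = float(med * np.exp(rng.normal(0.0, logsd))) if vaginal else np.nan
        med, logsd = config.skewed_dists["pph_ml"]
        out["pph_ml"] = float(med * np.exp(rng.normal(0.0, logsd)))
        threshold = 60.0 if out["nulliparous"] else 30.0
        out["second_stage_prolonged"] = (
            int(out["second_stage_min"] > threshold) if vaginal else np.nan
        )
        ga = int(p["delivery_ga"])
        sex = "male" if rng.random() < config.prob_male else "female"
        z = rng.normal()
        expected = neonatal.marsal_expected_weight(ga, sex)
        out["sex"] = sex
        out["delivery_ga"] = ga
        out["premature_lt_37"] = int(ga < 259)
        out["birth_weight_g"] = float(expected * (1.0 + neonatal.SD_FRACTION * z))
        out["birth_length_cm"] = float(np.round(rng.normal(52.0, 2.0), 1))
        rows.append(out)
    columns = [
        "participant_id", "group", *DEFAULT_OUTCOME_RATES, "mode_of_delivery",
        "nulliparous", "labor_total_min", "second_stage_min", "pph_ml",
        "second_stage_prolonged", "sex", "delivery_ga", "premature_lt_37",
        "birth_weight_g", "birth_length_cm",
    ]
    return pd.DataFrame(rows, columns=columns)


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (participants, weight observations, outcomes) tables.

    Reproducible: the same seed yields bit-identical tables.  Arm sizes
    follow :func:`allocate_groups`; every participant has exactly one GA-0
    self-report record; non-completers are truncated after a dropout day
    drawn uniformly between baseline and delivery.
    """
    n = config.n_participants
    rng = np.random.Generator(np.random.PCG64(config.seed))
    sizes = allocate_groups(n, config.allocation_ratio)
    labels = np.repeat(GROUPS, sizes)
    labels = labels[rng.permutation(n)] if n else np.array([], dtype=str)

    part_rows = []
    weight_frames = []
    for i in range(n):
        pid = f"P{i + 1:04d}"
        prng = _participant_rng(config.seed, pid)
        group = labels[i]
        effects = SubjectEffects(
            *prng.multivariate_normal(np.zeros(3), config.true_params.Sigma)
        )
        mu, sd, lo, hi = config.delivery_ga_dist
        delivery_ga = int(round(_draw_truncated_normal(prng, mu, sd, lo, hi)))
        b_lo, b_hi = config.baseline_ga_window
        baseline_ga = int(prng.integers(b_lo, b_hi + 1))
        completed = prng.random() >= config.lost_to_followup_prob
        dropout_ga = (
            delivery_ga if completed else int(prng.integers(baseline_ga, delivery_ga))
        )
        covid = prng.random() < config.covid_prob
        height = float(np.round(prng.normal(*config.height_dist), 1))

        pa = {}
        mvpa = config.pa_dists["mvpa_min_wk"]
        gi = GROUPS.index(group)
        shape = mvpa.get("shape", 2.0)
        pa["mvpa_min_wk"] = float(prng.gamma(shape, mvpa["mean"][gi] / shape))
        for key in ("steps_per_day", "active_kcal_day"):
            d = config.pa_dists[key]
            pa[key] = float(max(d["mean"][gi] / 10.0, prng.normal(d["mean"][gi], d["sd"])))

        part = {
            "participant_id": pid,
            "group": group,
            "height_cm": height,
            "baseline_ga": baseline_ga,
            "delivery_ga": delivery_ga,
            "completed": completed,
            "dropout_ga": dropout_ga,
            "covid_period": covid,
            **pa,
        }
        traj = generate_trajectory(part, config.true_params, config, rng=prng, effects=effects)
        sr = traj.loc[traj["source"] == "prepregnancy_selfreport", "weight_kg"]
        part["prepreg_weight_selfreport"] = float(sr.iloc[0])
        part_rows.append(part)
        weight_frames.append(traj)

    columns = [
        "participant_id", "group", "prepreg_weight_selfreport", "height_cm",
        "baseline_ga", "delivery_ga", "completed", "dropout_ga", "covid_period",
        "mvpa_min_wk", "steps_per_day", "active_kcal_day",
    ]
    participants = pd.DataFrame(part_rows, columns=columns)
    weights = (
        pd.concat(weight_frames, ignore_index=True)
        if weight_frames
        else pd.DataFrame(columns=["participant_id", "ga_days", "weight_kg", "source"])
    )
    outcomes = generate_outcomes(participants, config)
    return participants, weights, outcomes


def null_config(**overrides) -> CohortConfig:
    """A cohort in which all three arms share the same true trajectory."""
    return CohortConfig(**overrides)


def effect_config(tau=(110.0, 140.0, 170.0), beta1=None, beta2=None, **overrides) -> CohortConfig:
    """A cohort with arm-specific change-points (and optionally slopes)."""
    params = default_true_params()
    params = replace(
        params,
        tau=np.asarray(tau, dtype=float),
        beta1=np.asarray(beta1, dtype=float) if beta1 is not None else params.beta1,
        beta2=np.asarray(beta2, dtype=float) if beta2 is not None else params.beta2,
    )
    return CohortConfig(true_params=params, **overrides)
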