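"""End-to-end pipeline: simulate -> fit -> estimate-gwg -> compare -> report.

The report mirrors the structure of a three-arm trial analysis: per-arm GWG
summaries at each standardized timepoint with ANOVA and Tukey contrasts, a
complete-case comparison, outcome comparison rows (chi-square for
categorical, ANOVA for symmetric, Kruskal-Wallis for skewed variables),
COVID-period and hospital-scale sensitivity analyses, and physical-activity
association slopes.  Given the same seed the report is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import gwg as gwg_mod
from . import io as io_mod
from . import neonatal
from . import stats as outcome_stats
from .inference import PosteriorDraws, convergence_diagnostics, sample_posterior
from .model import attach_groups

logger = logging.getLogger("gwgbayes")

#: (column, kind) rows compared between arms, mirroring a standard
#: obstetric/neonatal outcome table.  Kinds: binary -> chi-square on the
#: groups x 2 table; categorical -> chi-square per level; symmetric -> ANOVA;
#: skewed -> Kruskal-Wallis.
OUTCOME_COMPARISONS = [
    ("gdm", "binary"),
    ("hypertensive_disorders", "binary"),
    ("induction", "binary"),
    ("epidural", "binary"),
    ("oxytocin", "binary"),
    ("rupture_34", "binary"),
    ("pph_gt_1000", "binary"),
    ("apgar5_lt_7", "binary"),
    ("premature_lt_37", "binary"),
    ("mode_of_delivery", "categorical"),
    ("pph_ml", "skewed"),
    ("labor_total_min", "skewed"),
    ("second_stage_min", "skewed"),
    ("delivery_ga", "skewed"),
    ("birth_weight_g", "skewed"),
    ("birth_length_cm", "skewed"),
    ("z_score", "symmetric"),
    ("sga", "binary"),
    ("lga", "binary"),
]


def compare_outcomes(outcomes: pd.DataFrame) -> pd.DataFrame:
    """One comparison row per outcome variable present in the table."""
    out = outcomes.copy()
    if "z_score" not in out.columns and {"birth_weight_g", "delivery_ga", "sex"} <= set(out.columns):
        out = neonatal.annotate_outcomes(out)
    if "size_class" in out.columns:
        out["sga"] = (out["size_class"] == "SGA").astype(float).where(out["size_class"].notna())
        out["lga"] = (out["size_class"] == "LGA").astype(float).where(out["size_class"].notna())
    rows = []
    labels = out["group"]
    for name, kind in OUTCOME_COMPARISONS:
        if name not in out.columns:
            continue
        col = out[name]
        ok = col.notna()
        row = {"outcome": name, "kind": kind, "n": int(ok.sum()),
               "statistic": np.nan, "df": np.nan, "p_value": np.nan, "method": ""}
        try:
            if kind in ("binary", "categorical"):
                table = outcome_stats.ContingencyTable.from_series(col[ok], labels[ok])
                res = outcome_stats.pearson_chi2(table)
            elif kind == "symmetric":
                res = outcome_stats.one_way_anova(col[ok].to_numpy(), labels[ok].to_numpy())
            else:
                res = outcome_stats.kruskal_wallis(col[ok].to_numpy(), labels[ok].to_numpy())
            row.update(statistic=res.statistic, df=res.df, p_value=res.p_value, method=res.method)
        except ValueError as exc:
            row["method"] = f"not_testable ({exc})"
        rows.append(row)
    return pd.DataFrame(rows)


def hospital_scale_subset(participants: pd.DataFrame, observations: pd.DataFrame) -> pd.Series:
    """Participants whose weights were all measured on the clinic scale."""
    home = set(observations.loc[observations["source"] == "home", "participant_id"])
    return ~participants["participant_id"].isin(home)


def _fmt_p(p) -> str:
    return "NA" if p is None or not np.isfinite(p) else f"{p:.3f}"


def _report_lines(config, participants, weights, outcomes, summaries, cc_table, cc_p,
                  comparisons, covid_tab, hosp_p, hosp_n, pa_rows, diagnostics) -> list[str]:
    lines = []
    add = lines.append
    add("GWG standardization pipeline report")
    add("=" * 40)
    add(f"seed: {config.seed}")
    counts = participants.groupby("group").size() if len(participants) else {}
    add(f"participants: {len(participants)} "
        f"({', '.join(f'{g}={counts.get(g, 0)}' for g in ('CON', 'EXE', 'MOT'))})")
    add(f"weight observations: {len(weights)}")
    add(f"completers with outcomes: {len(outcomes)}")
    add("")
    add("Estimated GWG at standardized gestational ages")
    add("-" * 40)
    for summ in summaries:
        t = summ["timepoint_days"]
        add(f"GA {t} days (week {t // 7}):")
        for _, r in summ["groups"].iterrows():
            add(f"  {r['group']}: {r['mean_gwg']:.1f} kg "
                f"[{r['ci_low']:.1f};{r['ci_high']:.1f}] (n={int(r['n'])})")
        add(f"  ANOVA p = {_fmt_p(summ['anova'].p_value)}")
        for _, r in summ["tukey"].iterrows():
            add(f"  {r['group_b']} - {r['group_a']}: {r['difference']:+.1f} kg "
                f"[{r['ci_low']:.1f};{r['ci_high']:.1f}], p = {_fmt_p(r['p_adj'])}")
    add("")
    add("Complete-case GWG at delivery (delivery weight - self-reported pre-pregnancy weight)")
    add("-" * 40)
    add(f"  n = {len(cc_table)}, ANOVA p = {_fmt_p(cc_p)}")
    for g, chunk in cc_table.groupby("group"):
        add(f"  {g}: {chunk['gwg'].mean():.1f} kg (n={len(chunk)})")
    add("")
    add("Obstetric and neonatal outcome comparisons")
    add("-" * 40)
    for _, r in comparisons.iterrows():
        stat = "" if not np.isfinite(r["statistic"]) else f"stat={r['statistic']:.3f}, "
        add(f"  {r['outcome']:24s} [{r['kind']:11s}] {stat}p = {_fmt_p(r['p_value'])} "
            f"({r['method']})")
    add("")
    add("Sensitivity: total GWG during vs before the COVID period, per arm")
    add("-" * 40)
    for _, r in covid_tab.iterrows():
        if np.isfinite(r["difference"]):
            add(f"  {r['group']}: {r['difference']:+.1f} kg "
                f"[{r['ci_low']:.1f};{r['ci_high']:.1f}], p = {_fmt_p(r['p_value'])}")
        else:
            add(f"  {r['group']}: not estimable")
    add("")
    add("Sensitivity: clinic-scale-only subset")
    add("-" * 40)
    add(f"  n = {hosp_n}, ANOVA p = {_fmt_p(hosp_p)}")
    add("")
    add("Association: physical activity vs total GWG (all arms pooled)")
    add("-" * 40)
    for name, res in pa_rows:
        add(f"  {name}: slope {res.slope:+.4g} [{res.ci_low:.4g};{res.ci_high:.4g}], "
            f"p = {_fmt_p(res.p_value)}")
    add("")
    add("MCMC convergence (fixed effects)")
    add("-" * 40)
    fixed = diagnostics[diagnostics["is_fixed_effect"]]
    add(f"  max R-hat = {fixed['rhat'].max():.3f}, min ESS = {fixed['ess'].min():.0f}, "
        f"converged: {diagnostics.attrs['converged']}")
    add("")
    return lines


def run_pipeline(config: io_mod.PipelineConfig) -> dict:
    """Execute all stages and write the report bundle to ``config.out_dir``.

    Returns a dict with the in-memory artefacts.  Any stage failure is
    re-raised with the stage name attached.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        if config.simulate:
            cohort_cfg = replace(config.cohort, seed=config.seed)
            participants, weights, outcomes = cohort_mod.generate_cohort(cohort_cfg)
            io_mod.write_table(weights, out_dir / "weights.csv", "weights")
            io_mod.write_table(participants, out_dir / "participants.csv", "participants")
            io_mod.write_table(outcomes, out_dir / "outcomes.csv", "outcomes")
        else:
            weights = io_mod.read_weights(config.weights_path)
            participants = io_mod.read_participants(config.participants_path)
            outcomes = io_mod.read_outcomes(config.outcomes_path)
        logger.info("stage simulate/load done: %d participants, %d observations",
                    len(participants), len(weights))

        stage = "fit"
        sampler_cfg = replace(config.sampler, seed=config.seed)
        obs = attach_groups(weights, participants)
        draws = sample_posterior(obs, participants, sampler_cfg)
        draws.save(out_dir / "draws.npz")
        diagnostics = convergence_diagnostics(draws)
        diagnostics.to_csv(out_dir / "diagnostics.csv")
        logger.info("stage fit done: %d chains x %d retained draws",
                    draws.n_chains, draws.n_draws)

        stage = "estimate-gwg"
        timepoints = [t for t in config.timepoints]
        estimates = gwg_mod.estimate_gwg_all(draws, timepoints)
        io_mod.write_table(estimates, out_dir / "gwg_estimates.csv", "gwg_estimates")
        summaries = [
            gwg_mod.group_gwg_summary(estimates, participants, t)
            for t in timepoints
            if t > 0
        ]
        group_rows = pd.concat(
            [s["groups"].assign(timepoint_days=s["timepoint_days"]) for s in summaries],
            ignore_index=True,
        )
        io_mod.write_table(group_rows, out_dir / "gwg_group_summary.csv", "gwg_group_summary")
        cc_table, cc_p = gwg_mod.complete_case_gwg(participants, weights)

        stage = "compare"
        outcomes_z = neonatal.annotate_outcomes(outcomes) if len(outcomes) else outcomes
        comparisons = compare_outcomes(outcomes_z) if len(outcomes_z) else pd.DataFrame(
            columns=["outcome", "kind", "n", "statistic", "df", "p_value", "method"])
        io_mod.write_table(comparisons, out_dir / "outcome_comparisons.csv",
                           "outcome_comparisons")

        total = estimates[estimates["timepoint_days"] == max(timepoints)]
        merged = total.merge(participants, on="participant_id")
        covid_tab = outcome_stats.covid_sensitivity(
            merged["gwg_hat"], merged["covid_period"].astype(float), merged["group"]
        )
        hosp_mask = hospital_scale_subset(participants, weights)
        hosp_ids = set(participants.loc[hosp_mask, "participant_id"])
        hosp = merged[merged["participant_id"].isin(hosp_ids)]
        hosp_p, hosp_n = None, len(hosp)
        counts = hosp.groupby("group").size()
        if len(counts) >= 2 and (counts >= 2).all():
            try:
                hosp_p = outcome_stats.one_way_anova(
                    hosp["gwg_hat"].to_numpy(), hosp["group"].to_numpy()
                ).p_value
            except ValueError:
                hosp_p = None
        pa_rows = []
        for col in ("mvpa_min_wk", "steps_per_day", "active_kcal_day"):
            if col in merged.columns and merged[col].notna().sum() >= 3:
                pa_rows.append((col, outcome_stats.pa_gwg_association(
                    merged[col], merged["gwg_hat"])))

        stage = "report"
        lines = _report_lines(config, participants, weights, outcomes, summaries,
                              cc_table, cc_p, comparisons, covid_tab, hosp_p, hosp_n,
                              pa_rows, diagnostics)
        (out_dir / "report.txt").write_text("\n".join(lines), encoding="utf-8")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "participants": participants,
        "weights": weights,
        "outcomes": outcomes,
        "draws": draws,
        "estimates": estimates,
        "summaries": summaries,
        "comparisons": comparisons,
        "report_path": out_dir / "report.txt",
    }
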