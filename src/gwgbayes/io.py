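"""CSV schemas, validation and configuration files.

All interchange tables are UTF-8 CSV with "." as decimal separator.  Writers
prepend a schema-version comment line ``# gwgbayes:<table>:<major>.<minor>``;
readers reject unknown major versions and accept plain headerless-comment
CSVs for interoperability.

weights.csv       participant_id, ga_days, weight_kg, source
participants.csv  participant_id, group, prepreg_weight_selfreport, height_cm,
                  baseline_ga, delivery_ga, completed, dropout_ga,
                  covid_period, mvpa_min_wk, steps_per_day, active_kcal_day
outcomes.csv      one row per delivered participant (see cohort.generate_outcomes)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import SOURCES, CohortConfig
from .inference import SamplerConfig
from .model import GROUPS

logger = logging.getLogger("gwgbayes")

SCHEMA_MAJOR = 1
SCHEMA_MINOR = 0


class ValidationError(ValueError):
    """A table failed schema validation."""


def _schema_line(name: str) -> str:
    return f"# gwgbayes:{name}:{SCHEMA_MAJOR}.{SCHEMA_MINOR}"


def write_table(df: pd.DataFrame, path, name: str) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_schema_line(name) + "\n")
        df.to_csv(fh, index=False)


def _read_csv_checked(path, name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        parts = first.strip().lstrip("# ").split(":")
        if len(parts) == 3 and parts[0] == "gwgbayes":
            major = int(parts[2].split(".")[0])
            if major != SCHEMA_MAJOR:
                raise ValidationError(
                    f"{path}: schema major version {major} is not supported "
                    f"(expected {SCHEMA_MAJOR})"
                )
    return pd.read_csv(path, skiprows=skip)


def read_weights(path) -> pd.DataFrame:
    """Read and validate a weight-observation table.

    Rows must have a known source, an integer non-negative gestational day
    and a positive weight; violations raise :class:`ValidationError` naming
    the offending (1-based) data row.  Row order is preserved.
    """
    df = _read_csv_checked(path, "weights")
    required = ["participant_id", "ga_days", "weight_kg", "source"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"weights table is missing columns {missing}")
    if df.empty:
        logger.warning("weights table %s is empty", path)
        return df[required]
    for i, row in enumerate(df.itertuples(index=False), start=1):
        ga = row.ga_days
        w = row.weight_kg
        if pd.isna(ga) or float(ga) != int(ga) or int(ga) < 0:
            raise ValidationError(f"row {i}: ga_days must be a non-negative integer day")
        if pd.isna(w) or not np.isfinite(float(w)) or float(w) <= 0:
            raise ValidationError(f"row {i}: weight_kg must be a positive number")
        if row.source not in SOURCES:
            raise ValidationError(
                f"row {i}: unknown source {row.source!r}; expected one of {SOURCES}"
            )
    df["ga_days"] = df["ga_days"].astype(int)
    return df[required]


def read_participants(path) -> pd.DataFrame:
    df = _read_csv_checked(path, "participants")
    required = ["participant_id", "group", "prepreg_weight_selfreport"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"participants table is missing columns {missing}")
    bad = set(df["group"].dropna()) - set(GROUPS)
    if bad:
        raise ValidationError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
    if df["participant_id"].duplicated().any():
        raise ValidationError("duplicate participant ids")
    return df


MODE_OF_DELIVERY_LEVELS = (
    "unassisted_vaginal", "instrumental_vaginal", "planned_cesarean", "emergency_cesarean",
)
SEX_LEVELS = ("male", "female")


def read_outcomes(path) -> pd.DataFrame:
    """Read and validate an outcomes table; missing values are permitted and counted."""
    df = _read_csv_checked(path, "outcomes")
    if "participant_id" not in df.columns:
        raise ValidationError("outcomes table needs a participant_id column")
    for col, levels in [("mode_of_delivery", MODE_OF_DELIVERY_LEVELS), ("sex", SEX_LEVELS)]:
        if col in df.columns:
            bad = set(df[col].dropna()) - set(levels)
            if bad:
                raise ValidationError(f"unknown {col} level(s) {sorted(bad)}")
    missing_counts = df.isna().sum()
    for col, n in missing_counts.items():
        if n:
            logger.info("outcomes column %s: %d missing values", col, int(n))
    df.attrs["missing_counts"] = missing_counts.to_dict()
    return df


@dataclass
class PipelineConfig:
    """Configuration for the end-to-end pipeline."""

    out_dir: str = "gwgbayes_out"
    seed: int = 0
    simulate: bool = True
    weights_path: str | None = None
    participants_path: str | None = None
    outcomes_path: str | None = None
    timepoints: tuple[int, ...] = (0, 84, 196, 280)
    log_level: str = "INFO"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)

    def __post_init__(self):
        if any(t < 0 for t in self.timepoints):
            raise ValueError("timepoints must be non-negative")
        if not self.simulate:
            for p in (self.weights_path, self.participants_path, self.outcomes_path):
                if p is None or not Path(p).exists():
                    raise ValueError(
                        "non-simulation runs need existing weights/participants/outcomes paths"
                    )


def load_pipeline_config(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file mirroring its fields."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    cohort_raw = raw.pop("cohort", {}) or {}
    sampler_raw = raw.pop("sampler", {}) or {}
    if "timepoints" in raw:
        raw["timepoints"] = tuple(int(t) for t in raw["timepoints"])
    seed = raw.get("seed", 0)
    cohort_raw.setdefault("seed", seed)
    sampler_raw.setdefault("seed", seed)
    if "allocation_ratio" in cohort_raw:
        cohort_raw["allocation_ratio"] = tuple(cohort_raw["allocation_ratio"])
    cohort = CohortConfig(**cohort_raw)
    sampler = SamplerConfig(**sampler_raw)
    return PipelineConfig(cohort=cohort, sampler=sampler, **raw)
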