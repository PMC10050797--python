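"""Birth-weight z-scores and SGA/LGA classification.

Expected fetal weight comes from the sex-specific fourth-degree polynomials
of the Scandinavian ultrasound-based intrauterine growth reference (the
"Marsal formula"); the reference SD is 12% of the expected weight.  The
z-score is

    z = (birth_weight - MW(ga, sex)) / (0.12 * MW(ga, sex))

and, assuming a Normal reference distribution, small/large for gestational
age are the 10th/90th percentiles, i.e. |z| > 1.28155.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

#: Quartic coefficients (GA in days -> grams), highest degree first, as
#: circulated from the 1996 Scandinavian reference.  Pinned by regression
#: tests; treat as configuration, not as something to re-derive.
MARSAL_COEFFICIENTS = {
    "male": (-1.907345e-6, 1.140644e-3, -1.463606e-1, 6.009617, 0.0),
    "female": (-2.761948e-6, 1.744841e-3, -2.893626e-1, 16.88565, 0.0),
}

SD_FRACTION = 0.12
"""Reference SD as a fraction of the expected weight."""

GA_VALID_RANGE = (154, 301)
"""Gestational-age validity window (22+0 to 43+0 weeks), in days."""

Z_10TH_PERCENTILE = float(stats.norm.ppf(0.10))  # -1.28155...


class GestationalAgeError(ValueError):
    """GA outside the reference formula's validity range."""


def _check_sex(sex: str) -> str:
    if sex not in MARSAL_COEFFICIENTS:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    return sex


def marsal_expected_weight(ga_days, sex: str):
    """Expected fetal weight (g) at ``ga_days`` for the given sex."""
    _check_sex(sex)
    ga = np.asarray(ga_days, dtype=float)
    lo, hi = GA_VALID_RANGE
    if np.any(ga < lo) or np.any(ga > hi):
        raise GestationalAgeError(
            f"gestational age outside the reference validity range [{lo}, {hi}] days"
        )
    mw = np.polyval(MARSAL_COEFFICIENTS[sex], ga)
    return mw if mw.shape else float(mw)


def birthweight_zscore(birth_weight_g, ga_days, sex: str, sd_fraction: float = SD_FRACTION):
    """Reference z-score of a birth weight at the given GA and sex."""
    bw = np.asarray(birth_weight_g, dtype=float)
    if np.any(bw <= 0):
        raise ValueError("birth weight must be positive")
    mw = marsal_expected_weight(ga_days, sex)
    z = (bw - mw) / (sd_fraction * mw)
    return z if np.asarray(z).shape else float(z)


def classify_sga_lga(z):
    """'SGA' below the 10th percentile, 'LGA' above the 90th, else 'AGA'."""
    z = np.asarray(z, dtype=float)
    if np.any(~np.isfinite(z)):
        raise ValueError("z-score must be finite")
    out = np.where(z < Z_10TH_PERCENTILE, "SGA", np.where(z > -Z_10TH_PERCENTILE, "LGA", "AGA"))
    return out if out.shape else str(out)


def annotate_outcomes(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Add ``z_score`` and ``size_class`` columns to an outcomes table.

    Requires birth_weight_g, delivery_ga and sex columns; rows with missing
    entries get missing annotations.
    """
    out = outcomes.copy()
    z = np.full(len(out), np.nan)
    cls = np.array([None] * len(out), dtype=object)
    for sex in ("male", "female"):
        m = (out["sex"] == sex) & out["birth_weight_g"].notna() & out["delivery_ga"].notna()
        if m.any():
            z[m.to_numpy()] = birthweight_zscore(
                out.loc[m, "birth_weight_g"].to_numpy(),
                out.loc[m, "delivery_ga"].to_numpy(),
                sex,
            )
    finite = np.isfinite(z)
    cls[finite] = classify_sga_lga(z[finite])
    out["z_score"] = z
    out["size_class"] = cls
    return out
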