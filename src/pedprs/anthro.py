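"""BMI and BMI-for-age z-scores via the LMS (Box–Cox) growth-reference method.

A growth reference supplies, per sex and age, the Box–Cox power L, the median
M (kg/m²) and the coefficient of variation S. The z-score of a BMI value X is

    z = ((X/M)^L - 1) / (L*S)        (|L| > 1e-8)
    z = ln(X/M) / S                  (L ~ 0)

followed by the restricted adjustment used by growth-standard software, which
linearizes extreme scores in units of the gap between the 2-SD and 3-SD
curves so that implausible measurements do not explode:

    z > 3:   z = 3 + (X - SD3+) / (SD3+ - SD2+)
    z < -3:  z = -3 - (SD3- - X) / (SD2- - SD3-)

with SDk = M * (1 + L*S*k)^(1/L). The transform is continuous and strictly
increasing in X, and exactly invertible (``lms_inverse``), which the cohort
simulator exploits to plant known z-scores.

Ages are matched to the reference grid with the completed-month convention:
an age of a months is scored against the nearest whole-month knot not above
a + 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SEXES = ("male", "female")
_L_LOG_LIMIT = 1e-8
#: |z| beyond this is flagged biologically implausible (flag only, no exclusion)
IMPLAUSIBLE_Z = 5.0

LMS_COLUMNS = ["sex", "age_months", "L", "M", "S"]


@dataclass
class LmsReference:
    """Sex- and age-indexed (L, M, S) lookup table."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in LMS_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"LMS table lacks columns {missing}")
        if not set(t["sex"]).issubset(SEXES):
            raise ValueError(f"sex must be one of {SEXES}")
        if t.duplicated(["sex", "age_months"]).any():
            raise ValueError("duplicate (sex, age_months) rows in LMS table")
        if (t["M"] <= 0).any() or (t["S"] <= 0).any():
            raise ValueError("M and S must be positive")
        for sex in set(t["sex"]):
            ages = t.loc[t["sex"] == sex, "age_months"].to_numpy(dtype=float)
            if not np.all(np.diff(np.sort(ages)) > 0):
                raise ValueError(f"age grid must be strictly increasing for {sex}")
        self.table = t.sort_values(["sex", "age_months"]).reset_index(drop=True)

    def span(self, sex: str) -> tuple[float, float]:
        ages = self.table.loc[self.table["sex"] == sex, "age_months"]
        return float(ages.min()), float(ages.max())


def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index, kg/m²."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError(f"weight and height must be positive, got ({weight_kg}, {height_cm})")
    return weight_kg / (height_cm / 100.0) ** 2


def _sd_curve(k: float, L: np.ndarray, M: np.ndarray, S: np.ndarray) -> np.ndarray:
    """BMI on the k-SD curve of the reference (vectorized)."""
    L, M, S = (np.asarray(a, dtype=float) for a in (L, M, S))
    arg = 1.0 + L * S * k
    if np.any(arg <= 0):
        raise ValueError(f"SD{k:+g} curve undefined: 1 + L*S*k <= 0")
    with np.errstate(divide="ignore"):
        boxcox = M * np.power(arg, np.where(np.abs(L) > _L_LOG_LIMIT, 1.0 / L, 1.0))
    return np.where(np.abs(L) > _L_LOG_LIMIT, boxcox, M * np.exp(S * k))


def _zscore_vec(X, L, M, S) -> np.ndarray:
    X, L, M, S = np.broadcast_arrays(*(np.asarray(a, dtype=float) for a in (X, L, M, S)))
    if np.any(X <= 0) or np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("X, M and S must all be positive")
    near_log = np.abs(L) <= _L_LOG_LIMIT
    Lsafe = np.where(near_log, 1.0, L)
    z = np.where(
        near_log,
        np.log(X / M) / S,
        (np.power(X / M, L) - 1.0) / (Lsafe * S),
    )
    hi = z > 3.0
    if np.any(hi):
        sd3 = _sd_curve(3.0, L, M, S)
        sd2 = _sd_curve(2.0, L, M, S)
        z = np.where(hi, 3.0 + (X - sd3) / (sd3 - sd2), z)
    lo = z < -3.0
    if np.any(lo):
        sd3m = _sd_curve(-3.0, L, M, S)
        sd2m = _sd_curve(-2.0, L, M, S)
        z = np.where(lo, -3.0 - (sd3m - X) / (sd2m - sd3m), z)
    return z


def lms_zscore(X: float, L: float, M: float, S: float) -> float:
    """Restricted-adjusted LMS z-score of a measurement X."""
    return float(_zscore_vec(X, L, M, S))


def _inverse_vec(z, L, M, S) -> np.ndarray:
    z, L, M, S = np.broadcast_arrays(*(np.asarray(a, dtype=float) for a in (z, L, M, S)))
    if np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("M and S must be positive")
    zc = np.clip(z, -3.0, 3.0)
    near_log = np.abs(L) <= _L_LOG_LIMIT
    arg = 1.0 + L * S * zc
    if np.any(~near_log & (arg <= 0)):
        raise ValueError("z out of the Box-Cox domain for the given L, S")
    Lsafe = np.where(near_log, 1.0, L)
    X = np.where(near_log, M * np.exp(S * zc), M * np.power(arg, 1.0 / Lsafe))
    hi = z > 3.0
    if np.any(hi):
        sd3 = _sd_curve(3.0, L, M, S)
        sd2 = _sd_curve(2.0, L, M, S)
        X = np.where(hi, sd3 + (z - 3.0) * (sd3 - sd2), X)
    lo = z < -3.0
    if np.any(lo):
        sd3m = _sd_curve(-3.0, L, M, S)
        sd2m = _sd_curve(-2.0, L, M, S)
        X = np.where(lo, sd3m - (-3.0 - z) * (sd2m - sd3m), X)
    return X


def lms_inverse(z: float, L: float, M: float, S: float) -> float:
    """Measurement X whose restricted-adjusted z-score equals z (exact inverse)."""
    return float(_inverse_vec(z, L, M, S))


def lookup_lms(ref: LmsReference, sex: str, age_months: float) -> tuple[float, float, float]:
    """(L, M, S) at the whole-month knot for sex/age (completed-month rule)."""
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
    sub = ref.table[ref.table["sex"] == sex]
    ages = sub["age_months"].to_numpy(dtype=float)
    lo, hi = ages[0], ages[-1]
    if not (lo <= age_months + 0.5 and age_months <= hi + 0.5):
        raise ValueError(
            f"age {age_months} months outside the {sex} reference span [{lo}, {hi}]"
        )
    # nearest knot <= age + 0.5
    idx = int(np.searchsorted(ages, age_months + 0.5, side="right")) - 1
    row = sub.iloc[idx]
    return float(row["L"]), float(row["M"]), float(row["S"])


def zbmi_for_cohort(subjects: pd.DataFrame, ref: LmsReference) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Score a cohort table; returns (results, skipped).

    ``subjects`` needs columns subject_id, sex, age_months, weight_kg,
    height_cm. Subjects with missing anthropometry (or age outside the
    reference span) are skipped with a recorded reason; |z| > 5 is flagged
    implausible but retained — exclusion is the pipeline's ±4 SD step.
    """
    required = ["subject_id", "sex", "age_months", "weight_kg", "height_cm"]
    missing_cols = [c for c in required if c not in subjects.columns]
    if missing_cols:
        raise ValueError(f"subject table lacks columns {missing_cols}")

    rows = []
    skipped: list[tuple[str, str]] = []
    for rec in subjects[required].itertuples(index=False):
        sid = rec.subject_id
        vals = (rec.age_months, rec.weight_kg, rec.height_cm)
        if rec.sex not in SEXES or any(pd.isna(v) for v in vals):
            skipped.append((sid, "missing anthropometry"))
            continue
        try:
            L, M, S = lookup_lms(ref, rec.sex, float(rec.age_months))
            bmi = compute_bmi(float(rec.weight_kg), float(rec.height_cm))
        except ValueError as exc:
            skipped.append((sid, str(exc)))
            continue
        z = lms_zscore(bmi, L, M, S)
        rows.append({"subject_id": sid, "bmi": bmi, "zbmi": z, "flagged": abs(z) > IMPLAUSIBLE_Z})
    for sid, reason in skipped:
        log.warning("subject %s skipped: %s", sid, reason)
    n_flag = sum(r["flagged"] for r in rows)
    if n_flag:
        log.warning("%d subject(s) with |zBMI| > %g flagged implausible", n_flag, IMPLAUSIBLE_Z)
    return pd.DataFrame(rows, columns=["subject_id", "bmi", "zbmi", "flagged"]), skipped
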