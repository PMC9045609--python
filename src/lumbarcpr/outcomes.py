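"""Treatment-response classification and outcome summaries.

Response to the exercise program is judged on the Oswestry Disability Index
only.  For a patient assessed at baseline (T0) and a later time Tx:

    dODI  = ODI_T0 - ODI_Tx            (points; improvement positive)
    dODI% = dODI / ODI_T0 * 100        (percent of baseline)

and the cohort is trichotomized:

* success      — dODI% >= 50
* improvement  — dODI% < 50 but dODI >= 10 (the 10-point minimal clinically
  important difference)
* failure      — otherwise

Pain (NPRS) is summarized alongside but never enters the classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .cohort import AssessmentTime, Cohort

__all__ = [
    "OutcomeChange",
    "OutcomeClass",
    "EffectSize",
    "compute_change",
    "classify_outcome",
    "cohens_d",
    "outcome_classes",
    "summarize_outcomes",
]

SUCCESS_PCT_THRESHOLD = 50.0
MCID_POINTS = 10.0


class OutcomeClass(Enum):
    SUCCESS = "success"
    IMPROVEMENT = "improvement"
    FAILURE = "failure"


@dataclass(frozen=True)
class OutcomeChange:
    delta_odi: float
    delta_odi_pct: float
    time: AssessmentTime = AssessmentTime.T8


@dataclass(frozen=True)
class EffectSize:
    d: float


def compute_change(
    odi_t0: float, odi_tx: float, time: AssessmentTime = AssessmentTime.T8
) -> OutcomeChange:
    """Absolute and percentage ODI improvement from baseline."""
    if odi_t0 <= 0:
        raise ValueError("baseline ODI must be positive to define percent change")
    delta = odi_t0 - odi_tx
    return OutcomeChange(delta_odi=delta, delta_odi_pct=delta / odi_t0 * 100.0, time=time)


def classify_outcome(change: OutcomeChange) -> OutcomeClass:
    if change.delta_odi_pct >= SUCCESS_PCT_THRESHOLD:
        return OutcomeClass.SUCCESS
    if change.delta_odi >= MCID_POINTS:
        return OutcomeClass.IMPROVEMENT
    return OutcomeClass.FAILURE


def cohens_d(
    pre_mean: float, pre_sd: float, post_mean: float, post_sd: float
) -> EffectSize:
    """Standardized pre-to-post mean change.

    Pooled pre/post standard deviation, d = (M_post - M_pre) /
    sqrt((SD_pre^2 + SD_post^2) / 2).  Negative d means the score decreased
    (here: less disability or pain).
    """
    if pre_sd <= 0 or post_sd <= 0:
        raise ValueError("standard deviations must be positive")
    pooled = math.sqrt((pre_sd**2 + post_sd**2) / 2.0)
    return EffectSize(d=(post_mean - pre_mean) / pooled)


def outcome_classes(cohort: Cohort, time: AssessmentTime) -> pd.Series:
    """Per-patient outcome class at ``time`` (patients with both ODI
    measurements only), indexed by patient id."""
    out: dict[str, str] = {}
    for p in cohort.patients:
        if AssessmentTime.T0 in p.odi and time in p.odi:
            change = compute_change(p.odi[AssessmentTime.T0], p.odi[time], time)
            out[p.id] = classify_outcome(change).value
    return pd.Series(out, dtype=object, name=f"outcome_{time.name}")


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    values = values[~np.isnan(values)]
    if values.size == 0:
        return math.nan, math.nan
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if values.size > 1 else math.nan
    return mean, sd


def summarize_outcomes(cohort: Cohort, time: AssessmentTime) -> pd.DataFrame:
    """Per-class and overall outcome summary at ``time``.

    One row per group (all / failure / improvement / success) with n and
    mean (SD) of ODI and NPRS at baseline and at ``time``; the overall row
    additionally carries pre-to-post Cohen's d for both measures.
    """
    classes = outcome_classes(cohort, time)
    df = cohort.to_frame()
    df = df.loc[classes.index]
    df["outcome"] = classes

    groups = [("all", df)] + [
        (c.value, df[df["outcome"] == c.value])
        for c in (OutcomeClass.FAILURE, OutcomeClass.IMPROVEMENT, OutcomeClass.SUCCESS)
    ]
    rows = []
    for label, sub in groups:
        row: dict[str, object] = {"group": label, "n": len(sub)}
        stats: dict[str, tuple[float, float]] = {}
        for measure in ("odi", "nprs"):
            for when, col in (("t0", f"{measure}_T0"), ("tx", f"{measure}_{time.name}")):
                vals = sub[col].to_numpy(dtype=float) if len(sub) else np.array([])
                mean, sd = _mean_sd(vals)
                stats[f"{measure}_{when}"] = (mean, sd)
                row[f"{measure}_{when}_mean"] = mean
                row[f"{measure}_{when}_sd"] = sd
        for measure in ("odi", "nprs"):
            (m0, s0), (m1, s1) = stats[f"{measure}_t0"], stats[f"{measure}_tx"]
            if label == "all" and s0 > 0 and s1 > 0:
                row[f"cohens_d_{measure}"] = cohens_d(m0, s0, m1, s1).d
            else:
                row[f"cohens_d_{measure}"] = math.nan
        rows.append(row)
    return pd.DataFrame(rows)
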