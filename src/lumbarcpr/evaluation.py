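"""Count-of-positive-tests rules and their diagnostic performance.

A derived rule is an ordered set of dichotomous clinical tests; a patient
is rule-positive at threshold k when at least k of the tests are positive.
Each threshold yields a 2x2 table against success/failure, from which the
standard diagnostic statistics are computed with 95% confidence intervals:

* Se, Sp, PV+, PV-  — Wald normal approximation on the proportion scale,
  truncated to [0, 1];
* LR+, LR-          — log-method intervals,
  SE(ln LR+) = sqrt(1/tp - 1/(tp+fn) + 1/fp - 1/(fp+tn)) (mirrored for LR-).

Post-test probabilities come from Bayes' theorem on the odds scale (the
algebraic form of the Fagan nomogram): posterior odds = prior odds x LR.
With the 2x2's own prevalence as the prior, the post-test probability of a
positive result is identically the positive predictive value.

Tables with an empty false-positive cell leave LR+ undefined; on explicit
request a donor threshold's failure-group split can be substituted to give
an illustrative approximation, always flagged as such.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, PatientRecord
from .cutpoints import CutDirection, TwoByTwo

__all__ = [
    "ConfInt",
    "DiagnosticStats",
    "RuleTest",
    "CPRRule",
    "ThresholdPerformance",
    "PosttestResult",
    "UndefinedStatError",
    "diagnostic_stats",
    "lr_from_rates",
    "count_positive_tests",
    "rule_counts",
    "rule_performance",
    "zero_cell_approximation",
    "posttest_probability",
]

_Z95 = 1.959963984540054

ConfInt = tuple[float, float]


class UndefinedStatError(ValueError):
    """A requested statistic is undefined for the given inputs."""


def _wald_ci(p: float, n: int) -> ConfInt:
    if n == 0 or math.isnan(p):
        return (math.nan, math.nan)
    half = _Z95 * math.sqrt(p * (1 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


@dataclass(frozen=True)
class DiagnosticStats:
    table: TwoByTwo
    se: float
    se_ci: ConfInt
    sp: float
    sp_ci: ConfInt
    lr_pos: float | None
    lr_pos_ci: ConfInt
    lr_neg: float | None
    lr_neg_ci: ConfInt
    pv_pos: float | None
    pv_pos_ci: ConfInt
    pv_neg: float | None
    pv_neg_ci: ConfInt
    approximated: bool = False
    flags: tuple[str, ...] = ()


def diagnostic_stats(table: TwoByTwo, approximated: bool = False) -> DiagnosticStats:
    """Full diagnostic panel for a 2x2 table (see module docstring for the
    interval conventions).  Undefined quantities are ``None`` with a flag."""
    if table.n_success == 0 or table.n_failure == 0:
        raise UndefinedStatError("both outcome columns must be non-empty")
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    flags: list[str] = []

    se, sp = table.se, table.sp

    if fp == 0:
        lr_pos, lr_pos_ci = None, (math.nan, math.nan)
        flags.append("lr_pos_undefined_zero_fp")
    else:
        lr_pos = se / (1 - sp)
        if tp == 0:
            lr_pos_ci = (math.nan, math.nan)
            flags.append("lr_pos_ci_undefined_zero_tp")
        else:
            se_log = math.sqrt(1 / tp - 1 / (tp + fn) + 1 / fp - 1 / (fp + tn))
            lr_pos_ci = (lr_pos * math.exp(-_Z95 * se_log), lr_pos * math.exp(_Z95 * se_log))

    if tn == 0:
        lr_neg, lr_neg_ci = None, (math.nan, math.nan)
        flags.append("lr_neg_undefined_zero_tn")
    else:
        lr_neg = (1 - se) / sp
        if fn == 0:
            lr_neg_ci = (math.nan, math.nan)
            flags.append("lr_neg_ci_undefined_zero_fn")
        else:
            se_log = math.sqrt(1 / fn - 1 / (tp + fn) + 1 / tn - 1 / (fp + tn))
            lr_neg_ci = (lr_neg * math.exp(-_Z95 * se_log), lr_neg * math.exp(_Z95 * se_log))

    if tp + fp == 0:
        pv_pos, pv_pos_ci = None, (math.nan, math.nan)
        flags.append("pv_pos_undefined_no_positives")
    else:
        pv_pos = tp / (tp + fp)
        pv_pos_ci = _wald_ci(pv_pos, tp + fp)
    if tn + fn == 0:
        pv_neg, pv_neg_ci = None, (math.nan, math.nan)
        flags.append("pv_neg_undefined_no_negatives")
    else:
        pv_neg = tn / (tn + fn)
        pv_neg_ci = _wald_ci(pv_neg, tn + fn)

    return DiagnosticStats(
        table=table,
        se=se,
        se_ci=_wald_ci(se, table.n_success),
        sp=sp,
        sp_ci=_wald_ci(sp, table.n_failure),
        lr_pos=lr_pos,
        lr_pos_ci=lr_pos_ci,
        lr_neg=lr_neg,
        lr_neg_ci=lr_neg_ci,
        pv_pos=pv_pos,
        pv_pos_ci=pv_pos_ci,
        pv_neg=pv_neg,
        pv_neg_ci=pv_neg_ci,
        approximated=approximated,
        flags=tuple(flags),
    )


def lr_from_rates(se: float, sp: float) -> float:
    """Positive likelihood ratio from sensitivity and specificity."""
    if sp >= 1.0:
        raise UndefinedStatError("LR+ undefined when specificity is 1")
    return se / (1.0 - sp)


@dataclass(frozen=True)
class RuleTest:
    name: str
    cut: float
    direction: CutDirection

    def is_positive(self, value: float | None) -> bool | None:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        if self.direction is CutDirection.GE_POSITIVE:
            return value >= self.cut
        return value <= self.cut


@dataclass
class CPRRule:
    """Ordered clinical tests combined by counting positives."""

    tests: list[RuleTest]
    recommended_k: int | None = None

    def to_json(self, path: Path | str) -> None:
        payload = {
            "tests": [
                {"name": t.name, "cut": t.cut, "direction": t.direction.value}
                for t in self.tests
            ],
            "recommended_k": self.recommended_k,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: Path | str) -> "CPRRule":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        tests = [
            RuleTest(t["name"], float(t["cut"]), CutDirection(t["direction"]))
            for t in payload["tests"]
        ]
        return cls(tests=tests, recommended_k=payload.get("recommended_k"))


def count_positive_tests(patient: PatientRecord | pd.Series, rule: CPRRule) -> int | None:
    """Number of rule tests a patient meets; ``None`` when any component is
    missing (the patient is non-evaluable and excluded upstream)."""
    count = 0
    for t in rule.tests:
        if isinstance(patient, PatientRecord):
            value = patient.predictors.get(t.name)
        else:
            value = patient.get(t.name)
        status = t.is_positive(None if value is None else float(value))
        if status is None:
            return None
        count += int(status)
    return count


def rule_counts(cohort: Cohort | pd.DataFrame, rule: CPRRule) -> pd.Series:
    """Per-patient positive-test counts (NaN = non-evaluable)."""
    df = cohort.to_frame() if isinstance(cohort, Cohort) else cohort
    out = {}
    for pid, row in df.iterrows():
        c = count_positive_tests(row, rule)
        out[pid] = math.nan if c is None else c
    return pd.Series(out, name="n_positive_tests")


@dataclass(frozen=True)
class PosttestResult:
    pretest: float
    lr: float
    posttest: float


def posttest_probability(pretest: float, lr: float) -> PosttestResult:
    """Bayes update on the odds scale (algebraic Fagan nomogram)."""
    if not 0.0 < pretest < 1.0:
        raise ValueError("pretest probability must be strictly inside (0, 1)")
    if lr <= 0:
        raise ValueError("likelihood ratio must be positive")
    odds = pretest / (1.0 - pretest) * lr
    return PosttestResult(pretest=pretest, lr=lr, posttest=odds / (1.0 + odds))


@dataclass
class ThresholdPerformance:
    k: int
    table: TwoByTwo
    stats: DiagnosticStats
    posttest_success_probability: float | None
    pretest: float | None = None


def rule_performance(
    success, counts, k: int, pretest: float | None = None
) -> ThresholdPerformance:
    """Diagnostic performance of "k or more tests positive".

    ``success`` is boolean success/failure per patient; ``counts`` the
    positive-test counts; non-evaluable (NaN) patients are dropped pairwise.
    ``pretest`` defaults to the prevalence in the analyzed rows; pass the
    full-cohort prevalence to follow the convention that the prior includes
    the improvement class even though the 2x2 excludes it.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    success = pd.Series(success).astype(float)
    counts = pd.Series(counts).astype(float)
    keep = counts.notna() & success.notna()
    succ = success[keep].to_numpy() > 0.5
    positive = counts[keep].to_numpy() >= k
    table = TwoByTwo.from_binary(positive, succ)
    stats_ = diagnostic_stats(table)
    if pretest is None:
        pretest = float(succ.mean())
    if stats_.lr_pos is None or not 0 < pretest < 1:
        post = None
    else:
        post = posttest_probability(pretest, stats_.lr_pos).posttest
    return ThresholdPerformance(
        k=k, table=table, stats=stats_,
        posttest_success_probability=post, pretest=pretest,
    )


def zero_cell_approximation(
    perf_at_k: ThresholdPerformance,
    donor: ThresholdPerformance,
) -> ThresholdPerformance:
    """Illustrative re-estimate of a degenerate threshold.

    When the failure column at k is empty (or a single patient), the
    failure-group split from a lower, non-degenerate threshold is
    substituted while the success-group split at k is kept; the output is
    flagged ``approximated`` and must be labeled illustrative wherever it
    is reported.
    """
    t = perf_at_k.table
    if t.fp > 1:
        return perf_at_k
    d = donor.table
    if donor.k >= perf_at_k.k:
        raise ValueError("donor threshold must be lower than the degenerate one")
    if d.fp <= 1:
        raise UndefinedStatError("donor threshold is itself degenerate")
    approx_table = TwoByTwo(tp=t.tp, fn=t.fn, fp=d.fp, tn=d.tn)
    stats_ = diagnostic_stats(approx_table, approximated=True)
    pretest = perf_at_k.pretest
    post = (
        posttest_probability(pretest, stats_.lr_pos).posttest
        if stats_.lr_pos is not None and pretest and 0 < pretest < 1
        else None
    )
    return ThresholdPerformance(
        k=perf_at_k.k, table=approx_table, stats=stats_,
        posttest_success_probability=post, pretest=pretest,
    )
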