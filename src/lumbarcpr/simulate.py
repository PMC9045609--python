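"""Synthetic patient cohorts with a planted predictor→success mechanism.

The generator emulates a single-arm exercise-program study: ``n_enrolled``
patients with non-acute low back pain (baseline disability ODI >= 12%),
each carrying a battery of candidate predictors.  A small set of *planted*
class-A clinical tests drives treatment success through a logistic model on
the count of positive tests — beta_j = ln(odds ratio) per test, with the
intercept solved numerically so the expected success prevalence hits the
configured target.  Disability at follow-up is then generated *conditional
on* the drawn outcome class, so re-classifying the written cohort from its
ODI scores reproduces the intended success/improvement/failure labels
exactly.  Attrition (in-program, then a fixed follow-up loss count) is
applied last and is independent of outcome by default.

Everything is drawn from one seeded generator stream, so a (config, seed)
pair reproduces the cohort byte-for-byte after writing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import (
    AssessmentTime,
    Cohort,
    DirectionHint,
    DropoutStage,
    PatientRecord,
    Scale,
    VariableClass,
    VariableSpec,
)
from .cutpoints import CutDirection

__all__ = [
    "PlantedTest",
    "NoiseVariable",
    "SimulationConfig",
    "PlantedTruth",
    "ConfigurationError",
    "default_study_config",
    "simulate_cohort",
    "apply_attrition",
]


class ConfigurationError(ValueError):
    """Simulation configuration cannot be satisfied."""


@dataclass(frozen=True)
class PlantedTest:
    """One predictor with a true association to treatment success.

    ``cut``/``direction`` define the true positive status; ``odds_ratio``
    is the per-test effect on the success odds given the other tests.
    Continuous tests are normal(mean, sd); binary tests are Bernoulli
    (``positive_rate``); ordinal tests are discretized truncated normals on
    [lo, hi], optionally sex-shifted (females: ``female_mean/sd``).
    """

    name: str
    var_class: VariableClass
    scale: Scale
    cut: float
    direction: CutDirection
    odds_ratio: float
    mean: float = 0.0
    sd: float = 1.0
    positive_rate: float = 0.5
    female_mean: float | None = None
    female_sd: float | None = None
    lo: float = 0.0
    hi: float = 9.0

    @property
    def direction_hint(self) -> DirectionHint:
        return (
            DirectionHint.HIGH_IS_POSITIVE
            if self.direction is CutDirection.GE_POSITIVE
            else DirectionHint.LOW_IS_POSITIVE
        )


@dataclass(frozen=True)
class NoiseVariable:
    """A predictor with no association to outcome."""

    name: str
    var_class: VariableClass
    scale: Scale
    mean: float = 0.0
    sd: float = 1.0
    lo: float = -math.inf
    hi: float = math.inf
    integer: bool = False
    positive_rate: float = 0.5  # binary noise only


@dataclass(frozen=True)
class SimulationConfig:
    n_enrolled: int = 134
    seed: int = 0
    success_prevalence_t8: float = 0.49
    success_prevalence_t34: float = 0.53
    attrition_in_program: float = 0.18
    attrition_followup: int = 10
    improvement_fraction: float = 0.2  # of non-successes, given dODI in [10, 50%)
    planted_tests: tuple[PlantedTest, ...] = ()
    noise_tests: tuple[NoiseVariable, ...] = ()
    odi_t0_mean: float = 26.8
    odi_t0_sd: float = 10.0
    nprs_t0_mean: float = 5.0
    nprs_t0_sd: float = 1.3
    bmi_mean: float = 26.5
    bmi_sd: float = 4.7
    age_mean: float = 43.5
    age_sd: float = 12.0
    female_fraction: float = 60.0 / 110.0
    t34_effect_scale: float = 0.8     # planted log-odds carried to follow-up
    t34_persistence: float = 1.0      # log-odds bonus for T8 successes
    attrition_outcome_dependent: bool = False

    def __post_init__(self) -> None:
        probs = [
            self.success_prevalence_t8,
            self.success_prevalence_t34,
            self.attrition_in_program,
            self.improvement_fraction,
            self.female_fraction,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("probabilities must lie in [0, 1]")
        if any(t.odds_ratio <= 0 for t in self.planted_tests):
            raise ConfigurationError("odds ratios must be positive")
        if self.n_enrolled < 20:
            raise ConfigurationError("n_enrolled must be at least 20")


@dataclass
class PlantedTruth:
    """Ground truth kept beside (never inside) the analysis-facing cohort."""

    p_success_t8: np.ndarray
    p_success_t34: np.ndarray
    statuses: dict[str, np.ndarray]
    rule_tests: list[tuple[str, float, CutDirection]]
    seed: int


def default_study_config(seed: int = 0) -> SimulationConfig:
    """Packaged calibration mirroring the study marginals.

    134 enrolled; baseline ODI 26.8 (10) — the midpoint of the male
    25.6 (9.0) and female 27.8 (10.6) marginals; NPRS 5.0 (1.3); BMI
    26.5 (4.7); age 43.5 (12); 18% in-program attrition and 10 further
    follow-up losses; success prevalence 0.49 (T8) / 0.53 (T34).  Four
    planted class-A instability tests (a 0–1 loaded-reach ratio cut at
    0.75, a pain-provocation binary, an aberrant-movement binary, and a
    0–9 joint-laxity score positive below 5, females shifted higher) with
    odds ratio 6 each, plus class-B/C noise variables.
    """
    planted = (
        PlantedTest(
            name="ppt_reach", var_class=VariableClass.A, scale=Scale.CONTINUOUS,
            cut=0.75, direction=CutDirection.GE_POSITIVE, odds_ratio=6.0,
            mean=0.70, sd=0.10,
        ),
        PlantedTest(
            name="hip_rotation_pain", var_class=VariableClass.A, scale=Scale.BINARY,
            cut=0.5, direction=CutDirection.GE_POSITIVE, odds_ratio=6.0,
            positive_rate=0.35,
        ),
        PlantedTest(
            name="aberrant_movement", var_class=VariableClass.A, scale=Scale.BINARY,
            cut=0.5, direction=CutDirection.GE_POSITIVE, odds_ratio=6.0,
            positive_rate=0.40,
        ),
        PlantedTest(
            name="beighton", var_class=VariableClass.A, scale=Scale.ORDINAL,
            cut=4.0, direction=CutDirection.LE_POSITIVE, odds_ratio=6.0,
            mean=0.5, sd=1.4, female_mean=2.2, female_sd=2.6, lo=0.0, hi=9.0,
        ),
    )
    noise = (
        NoiseVariable("pain_catastrophizing", VariableClass.B, Scale.CONTINUOUS,
                      mean=20.4, sd=11.9, lo=0, hi=52),
        NoiseVariable("exercise_self_efficacy", VariableClass.B, Scale.CONTINUOUS,
                      mean=60.0, sd=20.0, lo=0, hi=100),
        NoiseVariable("social_support", VariableClass.B, Scale.ORDINAL,
                      mean=12.0, sd=4.0, lo=0, hi=20, integer=True),
        NoiseVariable("psych_distress", VariableClass.C, Scale.CONTINUOUS,
                      mean=24.0, sd=14.0, lo=0, hi=100),
        NoiseVariable("startback", VariableClass.C, Scale.ORDINAL,
                      mean=4.0, sd=2.0, lo=0, hi=9, integer=True),
        NoiseVariable("physical_activity", VariableClass.C, Scale.CONTINUOUS,
                      mean=50.0, sd=25.0, lo=0, hi=200),
    )
    return SimulationConfig(seed=seed, planted_tests=planted, noise_tests=noise)


def _truncated_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    """Rejection sampling; falls back to clipping if acceptance is hopeless."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    for _ in range(200):
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return np.clip(out, lo, hi)


def _solve_intercept(s: np.ndarray, target: float) -> float:
    def f(alpha: float) -> float:
        return float(np.mean(expit(alpha + s)) - target)

    lo, hi = -30.0, 30.0
    if f(lo) > 0 or f(hi) < 0:
        raise ConfigurationError(
            f"cannot reach success prevalence {target}: intercept search fails to bracket"
        )
    return float(brentq(f, lo, hi, xtol=1e-10))


def _draw_class_conditional_odi(
    rng, odi_t0: np.ndarray, success: np.ndarray, improvement: np.ndarray
) -> np.ndarray:
    """Follow-up ODI consistent with the assigned outcome class."""
    n = odi_t0.size
    out = np.empty(n)
    for i in range(n):
        t0 = odi_t0[i]
        if success[i]:
            frac = rng.uniform(0.55, 0.95)        # dODI% in [55, 95]
            out[i] = t0 * (1.0 - frac)
        elif improvement[i]:
            upper = 0.5 * t0 - 0.5                # keeps dODI% strictly < 50
            out[i] = t0 - rng.uniform(10.5, max(10.6, upper))
        else:
            upper = min(9.5, 0.5 * t0 - 0.5)      # dODI < 10 and dODI% < 50
            out[i] = t0 - rng.uniform(-4.0, upper)
    return np.clip(out, 0.0, 100.0)


def _draw_class_conditional_nprs(rng, success, improvement, params) -> np.ndarray:
    means = np.where(success, params[0][0], np.where(improvement, params[1][0], params[2][0]))
    sds = np.where(success, params[0][1], np.where(improvement, params[1][1], params[2][1]))
    return np.clip(rng.normal(means, sds), 0.0, 10.0)


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, PlantedTruth]:
    """Generate one cohort plus its ground truth; deterministic in the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_enrolled

    female = rng.random(n) < config.female_fraction
    age = _truncated_normal(rng, config.age_mean, config.age_sd, 18, 65, n)
    bmi = _truncated_normal(rng, config.bmi_mean, config.bmi_sd, 16, 48, n)
    odi_t0 = _truncated_normal(rng, config.odi_t0_mean, config.odi_t0_sd, 12, 80, n)
    nprs_t0 = _truncated_normal(rng, config.nprs_t0_mean, config.nprs_t0_sd, 0, 10, n)

    values: dict[str, np.ndarray] = {}
    statuses: dict[str, np.ndarray] = {}
    for t in config.planted_tests:
        if t.scale is Scale.BINARY:
            vals = (rng.random(n) < t.positive_rate).astype(float)
        elif t.scale is Scale.ORDINAL:
            if t.female_mean is not None:
                raw = np.where(
                    female,
                    _truncated_normal(rng, t.female_mean, t.female_sd or t.sd, t.lo, t.hi, n),
                    _truncated_normal(rng, t.mean, t.sd, t.lo, t.hi, n),
                )
            else:
                raw = _truncated_normal(rng, t.mean, t.sd, t.lo, t.hi, n)
            vals = np.round(raw)
        else:
            vals = rng.normal(t.mean, t.sd, n)
        if t.direction is CutDirection.GE_POSITIVE:
            status = vals >= t.cut
        else:
            status = vals <= t.cut
        values[t.name] = vals
        statuses[t.name] = status.astype(int)

    for nv in config.noise_tests:
        if nv.scale is Scale.BINARY:
            values[nv.name] = (rng.random(n) < nv.positive_rate).astype(float)
        else:
            raw = _truncated_normal(rng, nv.mean, nv.sd, nv.lo, nv.hi, n)
            values[nv.name] = np.round(raw) if nv.integer else raw

    s8 = np.zeros(n)
    for t in config.planted_tests:
        s8 += math.log(t.odds_ratio) * statuses[t.name]
    alpha8 = _solve_intercept(s8, config.success_prevalence_t8)
    p8 = expit(alpha8 + s8)
    success8 = rng.random(n) < p8

    eligible_improve = odi_t0 > 21.5  # dODI >= 10 with dODI% < 50 needs t0 > 21
    improvement8 = (
        ~success8 & eligible_improve & (rng.random(n) < config.improvement_fraction)
    )

    s34 = config.t34_effect_scale * s8 + config.t34_persistence * success8
    alpha34 = _solve_intercept(s34, config.success_prevalence_t34)
    p34 = expit(alpha34 + s34)
    success34 = rng.random(n) < p34
    improvement34 = (
        ~success34 & eligible_improve & (rng.random(n) < config.improvement_fraction)
    )

    odi_t8 = _draw_class_conditional_odi(rng, odi_t0, success8, improvement8)
    odi_t34 = _draw_class_conditional_odi(rng, odi_t0, success34, improvement34)
    nprs_t8 = _draw_class_conditional_nprs(
        rng, success8, improvement8, [(2.1, 1.0), (3.0, 1.2), (3.4, 1.4)]
    )
    nprs_t34 = _draw_class_conditional_nprs(
        rng, success34, improvement34, [(2.1, 1.1), (3.8, 1.9), (3.9, 1.8)]
    )

    variables = [
        VariableSpec(t.name, t.var_class, t.scale, t.direction_hint)
        for t in config.planted_tests
    ] + [
        VariableSpec(nv.name, nv.var_class, nv.scale, DirectionHint.UNKNOWN)
        for nv in config.noise_tests
    ]
    patients = []
    for i in range(n):
        patients.append(
            PatientRecord(
                id=f"P{i + 1:04d}",
                sex="F" if female[i] else "M",
                age=float(age[i]),
                bmi=float(bmi[i]),
                odi={
                    AssessmentTime.T0: float(odi_t0[i]),
                    AssessmentTime.T8: float(odi_t8[i]),
                    AssessmentTime.T34: float(odi_t34[i]),
                },
                nprs={
                    AssessmentTime.T0: float(nprs_t0[i]),
                    AssessmentTime.T8: float(nprs_t8[i]),
                    AssessmentTime.T34: float(nprs_t34[i]),
                },
                predictors={name: float(values[name][i]) for name in values},
            )
        )
    cohort = Cohort(
        patients=patients,
        variables=variables,
        provenance=f"simulated(seed={config.seed}, n_enrolled={n})",
    )
    truth = PlantedTruth(
        p_success_t8=p8,
        p_success_t34=p34,
        statuses=statuses,
        rule_tests=[(t.name, t.cut, t.direction) for t in config.planted_tests],
        seed=config.seed,
    )
    cohort = apply_attrition(cohort, truth, config, rng)
    cohort.validate()
    return cohort, truth


def apply_attrition(
    cohort: Cohort,
    truth: PlantedTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Cohort:
    """Mark dropouts and blank their unobserved measurements.

    In-program dropouts (probability ``attrition_in_program`` each, by
    default independent of outcome) lose T8 and T34; then exactly
    ``attrition_followup`` completers (or as many as exist) lose T34.
    Outcomes were already generated, so attrition only hides data.
    """
    n = cohort.n
    if config.attrition_outcome_dependent:
        # weight dropout toward patients with low latent success probability
        w = 1.0 - truth.p_success_t8
        prob = config.attrition_in_program * w / w.mean() if w.mean() > 0 else w
        in_program = rng.random(n) < np.clip(prob, 0, 1)
    else:
        in_program = rng.random(n) < config.attrition_in_program

    completer_idx = np.flatnonzero(~in_program)
    k = min(config.attrition_followup, completer_idx.size)
    lost_follow = set(
        rng.choice(completer_idx, size=k, replace=False).tolist() if k else []
    )

    patients = []
    for i, p in enumerate(cohort.patients):
        odi, nprs = dict(p.odi), dict(p.nprs)
        if in_program[i]:
            stage = DropoutStage.LOST_IN_PROGRAM
            for t in (AssessmentTime.T8, AssessmentTime.T34):
                odi.pop(t, None)
                nprs.pop(t, None)
        elif i in lost_follow:
            stage = DropoutStage.LOST_AFTER_T8
            odi.pop(AssessmentTime.T34, None)
            nprs.pop(AssessmentTime.T34, None)
        else:
            stage = DropoutStage.COMPLETED_T34
        patients.append(replace(p, odi=odi, nprs=nprs, dropout_stage=stage))
    return Cohort(patients=patients, variables=list(cohort.variables),
                  provenance=cohort.provenance)
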