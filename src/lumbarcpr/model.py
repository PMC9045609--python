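"""The derivation pipeline as a model/results pair.

:class:`CPRDerivation` is constructed from a cohort and an assessment time;
``fit()`` runs the whole derivation — outcome trichotomization, six-method
cut-point audit, univariate screening, three-step hierarchical logistic
selection, and count-of-positive-tests rule evaluation — and returns a
:class:`CPRDerivationResults` carrying every intermediate table plus a
formatted ``summary()``.

Typical use::

    from lumbarcpr import CPRDerivation, AssessmentTime, default_study_config, simulate_cohort

    cohort, truth = simulate_cohort(default_study_config(seed=7))
    res = CPRDerivation(cohort, time=AssessmentTime.T8).fit()
    print(res.summary())
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import AssessmentTime, Cohort, DropoutStage, Scale, VariableClass
from .cutpoints import (
    CutDirection,
    CutMethod,
    CutpointResult,
    DegenerateDataError,
    ScreenResult,
    dichotomize,
    screen_variables,
    select_cutpoint,
    select_cutpoint_auto,
)
from .evaluation import (
    CPRRule,
    RuleTest,
    ThresholdPerformance,
    rule_counts,
    rule_performance,
)
from .modeling import HierarchicalStep, ModelingConfig, hierarchical_modeling
from .outcomes import OutcomeClass, outcome_classes, summarize_outcomes

log = logging.getLogger(__name__)

__all__ = ["DerivationConfig", "CPRDerivation", "CPRDerivationResults"]


@dataclass(frozen=True)
class DerivationConfig:
    """Tunable knobs of the derivation pipeline.

    ``cut_method`` picks which of the six audited cut-point criteria
    supplies the working threshold of each continuous/ordinal test (the
    audit always reports all of them); ``rule_step`` names the hierarchical
    step whose final model becomes the rule; ``pretest_convention``
    chooses whether the Bayes prior is the prevalence among all completers
    (improvement class included) or only among the modeled success/failure
    rows.
    """

    cut_method: CutMethod = CutMethod.YI
    screen_alpha: float = 0.20
    screen_lr_threshold: float = 2.0
    alpha_retain: float = 0.05
    force_confounders: bool = False
    rule_step: str = "A_only"
    pretest_convention: str = "all_completers"  # or "analysis_subset"


class CPRDerivation:
    """Derive a clinical prediction rule for treatment success."""

    def __init__(
        self,
        cohort: Cohort,
        time: AssessmentTime = AssessmentTime.T8,
        config: DerivationConfig | None = None,
    ):
        self.cohort = cohort
        self.time = time
        self.config = config or DerivationConfig()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        variables,
        time: AssessmentTime = AssessmentTime.T8,
        config: DerivationConfig | None = None,
    ) -> "CPRDerivation":
        """Build from an analysis frame (columns as written by
        :func:`lumbarcpr.cohort.write_cohort`) plus a variable list."""
        from .cohort import PatientRecord

        patients = []
        for _, row in df.iterrows():
            odi, nprs = {}, {}
            for t in AssessmentTime:
                for measure, store in (("odi", odi), ("nprs", nprs)):
                    col = f"{measure}_{t.name}"
                    if col in row and not pd.isna(row[col]):
                        store[t] = float(row[col])
            predictors = {
                v.name: (None if pd.isna(row[v.name]) else float(row[v.name]))
                for v in variables
            }
            patients.append(
                PatientRecord(
                    id=str(row["id"]),
                    sex=str(row["sex"]),
                    age=float(row["age"]),
                    bmi=float(row["bmi"]),
                    odi=odi,
                    nprs=nprs,
                    predictors=predictors,
                    dropout_stage=DropoutStage(row.get("dropout_stage", "completed_T34")),
                )
            )
        cohort = Cohort(patients=patients, variables=list(variables)).validate()
        return cls(cohort, time=time, config=config)

    # ------------------------------------------------------------------

    def fit(self) -> "CPRDerivationResults":
        cfg = self.config
        time = self.time

        classes = outcome_classes(self.cohort, time)
        if classes.empty:
            raise DegenerateDataError(f"no patients with ODI at T0 and {time.name}")
        outcome_summary = summarize_outcomes(self.cohort, time)

        df = self.cohort.to_frame().loc[classes.index]
        sf_mask = classes != OutcomeClass.IMPROVEMENT.value
        success = (classes == OutcomeClass.SUCCESS.value)[sf_mask]
        sf = df.loc[success.index]

        audit_rows: list[CutpointResult] = []
        chosen: dict[str, tuple[float, CutDirection]] = {}
        tests = pd.DataFrame(index=df.index)
        for spec in self.cohort.variables:
            col = sf[spec.name].astype(float)
            if spec.scale is Scale.BINARY:
                # scan both orientations so "test negative" predictors work
                try:
                    best = select_cutpoint_auto(
                        col, success, cfg.cut_method, spec.direction_hint, spec.name
                    )
                except DegenerateDataError:
                    continue
                chosen[spec.name] = (0.5, best.direction)
            else:
                try:
                    for method in CutMethod:
                        res = select_cutpoint_auto(
                            col, success, method, spec.direction_hint, spec.name
                        )
                        audit_rows.append(res)
                        if method is cfg.cut_method:
                            chosen[spec.name] = (res.cut, res.direction)
                except DegenerateDataError:
                    continue
            cut, direction = chosen[spec.name]
            tests[spec.name] = dichotomize(df, spec.name, cut, direction)

        screen = screen_variables(
            tests.loc[success.index], success,
            alpha=cfg.screen_alpha, lr_threshold=cfg.screen_lr_threshold,
        )
        accepted = [s.variable for s in screen if s.accepted]

        # modeling frame: accepted tests + confounders, complete cases only
        X = tests.loc[success.index, accepted].copy()
        X["age"] = sf["age"].astype(float)
        X["sex_female"] = (sf["sex"] == "F").astype(float)
        X["bmi"] = sf["bmi"].astype(float)
        keep = X.notna().all(axis=1)
        n_excluded = int((~keep).sum())
        if n_excluded:
            log.info("modeling: excluded %d incomplete cases", n_excluded)
        Xc, yc = X[keep], success[keep].astype(float)

        classes_map = {
            s.name: s.var_class for s in self.cohort.variables if s.name in accepted
        }
        steps = hierarchical_modeling(
            Xc, yc, classes_map,
            ModelingConfig(alpha_retain=cfg.alpha_retain,
                           force_confounders=cfg.force_confounders),
        )

        step_by_name = {s.step: s for s in steps}
        rule_fit = step_by_name[cfg.rule_step].final_fit
        rule_tests = [
            RuleTest(name, *chosen[name])
            for name in rule_fit.term_names
            if name in chosen
        ]
        rule = CPRRule(tests=rule_tests) if rule_tests else None

        prevalence_all = float((classes == OutcomeClass.SUCCESS.value).mean())
        pretest = (
            prevalence_all
            if cfg.pretest_convention == "all_completers"
            else float(success.mean())
        )
        performance: list[ThresholdPerformance] = []
        counts = None
        if rule is not None:
            counts = rule_counts(df, rule)
            sf_counts = counts[success.index]
            for k in range(1, len(rule.tests) + 1):
                performance.append(
                    rule_performance(success.astype(float), sf_counts, k, pretest=pretest)
                )
            defined = [
                p for p in performance if p.stats.lr_pos is not None and p.table.fp >= 1
            ]
            if defined:
                rule.recommended_k = max(defined, key=lambda p: p.stats.lr_pos).k

        return CPRDerivationResults(
            model=self,
            time=time,
            classes=classes,
            outcome_summary=outcome_summary,
            cutpoint_audit=audit_rows,
            chosen_cuts=chosen,
            screen=screen,
            steps=steps,
            rule=rule,
            rule_counts=counts,
            performance=performance,
            pretest=pretest,
            n_modeled=int(keep.sum()),
            n_excluded_modeling=n_excluded,
        )


@dataclass
class CPRDerivationResults:
    """Everything the derivation produced, with a printable summary."""

    model: CPRDerivation
    time: AssessmentTime
    classes: pd.Series
    outcome_summary: pd.DataFrame
    cutpoint_audit: list[CutpointResult]
    chosen_cuts: dict[str, tuple[float, CutDirection]]
    screen: list[ScreenResult]
    steps: list[HierarchicalStep]
    rule: CPRRule | None
    rule_counts: pd.Series | None
    performance: list[ThresholdPerformance]
    pretest: float
    n_modeled: int
    n_excluded_modeling: int

    @property
    def class_counts(self) -> dict[str, int]:
        return self.classes.value_counts().to_dict()

    def step(self, name: str) -> HierarchicalStep:
        for s in self.steps:
            if s.step == name:
                return s
        raise KeyError(name)

    def audit_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.cutpoint_audit:
            rows.append(
                {
                    "variable": r.variable,
                    "method": r.method.value,
                    "cut": r.cut,
                    "direction": r.direction.value,
                    "se": r.table.se,
                    "sp": r.table.sp,
                    "lr_pos": r.lr_pos,
                    "youden_j": r.youden_j,
                    "kl_fg": r.kl_fg,
                    "kl_gf": r.kl_gf,
                    "fallback_to_yi": r.fallback_to_yi,
                }
            )
        return pd.DataFrame(rows)

    def screen_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variable": s.variable,
                    "chi2": s.chi2,
                    "p": s.p,
                    "lr_pos": s.lr_pos,
                    "accepted": s.accepted,
                    "reason": s.acceptance_reason,
                }
                for s in self.screen
            ]
        )

    def performance_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.performance:
            st = p.stats
            rows.append(
                {
                    "k": p.k,
                    "tp": p.table.tp,
                    "fp": p.table.fp,
                    "fn": p.table.fn,
                    "tn": p.table.tn,
                    "se_pct": st.se * 100,
                    "sp_pct": st.sp * 100,
                    "lr_pos": st.lr_pos,
                    "pv_pos_pct": None if st.pv_pos is None else st.pv_pos * 100,
                    "posttest_pct": (
                        None
                        if p.posttest_success_probability is None
                        else p.posttest_success_probability * 100
                    ),
                    "approximated": st.approximated,
                }
            )
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------

    def summary(self) -> str:
        lines: list[str] = []
        t = self.time.name
        add = lines.append
        add(f"Clinical prediction rule derivation — success at {t}")
        add("=" * 60)
        counts = self.class_counts
        add(
            f"Patients classified: {len(self.classes)} "
            f"(success {counts.get('success', 0)}, "
            f"improvement {counts.get('improvement', 0)}, "
            f"failure {counts.get('failure', 0)})"
        )
        all_row = self.outcome_summary.iloc[0]
        add(
            f"ODI  {all_row['odi_t0_mean']:.1f} ({all_row['odi_t0_sd']:.1f}) -> "
            f"{all_row['odi_tx_mean']:.1f} ({all_row['odi_tx_sd']:.1f}), "
            f"Cohen's d = {all_row['cohens_d_odi']:.2f}"
        )
        add(
            f"NPRS {all_row['nprs_t0_mean']:.1f} ({all_row['nprs_t0_sd']:.1f}) -> "
            f"{all_row['nprs_tx_mean']:.1f} ({all_row['nprs_tx_sd']:.1f}), "
            f"Cohen's d = {all_row['cohens_d_nprs']:.2f}"
        )
        add("")
        add(f"Screening (p < {self.model.config.screen_alpha} or LR+ >= "
            f"{self.model.config.screen_lr_threshold}):")
        for s in self.screen:
            mark = "accepted" if s.accepted else "rejected"
            add(f"  {s.variable:<24} chi2={s.chi2:7.3f}  p={s.p:.4f}  "
                f"LR+={s.lr_pos:6.2f}  {mark} ({s.acceptance_reason})")
        add("")
        for step in self.steps:
            fit = step.final_fit
            add(f"Step {step.step}: n={fit.n}, -2LL={fit.minus2ll:.2f}, "
                f"Nagelkerke R2={step.summary.nagelkerke_r2 * 100:.1f}%, "
                f"AUC={step.summary.auc:.2f}" if not math.isnan(step.summary.auc)
                else f"Step {step.step}: n={fit.n}, intercept-only")
            hl = step.summary.hl
            if not hl.skipped:
                add(f"  Hosmer-Lemeshow chi2={hl.chi2:.2f}, df={hl.df}, p={hl.p:.2f}")
            adequacy = {name: rank for name, _, rank in step.summary.adequacy}
            for term in fit.terms:
                lo, hi = term.ci95
                add(
                    f"  {term.name:<24} B={term.b:6.2f} ({lo:.2f}-{hi:.2f})  "
                    f"p={term.wald_p:.4f}  OR={term.odds_ratio:6.2f}  "
                    f"adequacy rank {adequacy.get(term.name, '-')}"
                )
            if not fit.terms:
                add("  (no terms retained)")
        add("")
        if self.rule is None:
            add("No rule could be derived (empty final model).")
        else:
            add(f"Derived rule ({len(self.rule.tests)} tests, pretest probability "
                f"{self.pretest * 100:.0f}%):")
            for rt in self.rule.tests:
                op = ">=" if rt.direction is CutDirection.GE_POSITIVE else "<="
                add(f"  {rt.name} {op} {rt.cut:g}")
            add("  k  tp  fp   Se%    Sp%    LR+    PV+%  posttest%")
            for p in self.performance:
                st = p.stats
                lr = f"{st.lr_pos:6.2f}" if st.lr_pos is not None else "  und."
                pv = f"{st.pv_pos * 100:6.1f}" if st.pv_pos is not None else "  und."
                post = (
                    f"{p.posttest_success_probability * 100:8.0f}"
                    if p.posttest_success_probability is not None
                    else "    und."
                )
                add(
                    f"  {p.k}  {p.table.tp:2d}  {p.table.fp:2d}  "
                    f"{st.se * 100:5.1f}  {st.sp * 100:5.1f}  {lr}  {pv}  {post}"
                )
            if self.rule.recommended_k is not None:
                add(f"Recommended threshold: {self.rule.recommended_k} or more positive tests")
        return "\n".join(lines)

    def plot_roc(self, step: str | None = None, ax=None):
        """ROC curve of the (chosen step's) model predictions."""
        import matplotlib.pyplot as plt  # optional dependency

        from .cutpoints import roc_points

        step_obj = self.step(step or self.model.config.rule_step)
        fit = step_obj.final_fit
        if not fit.terms:
            raise ValueError("model has no terms; nothing to plot")
        # rebuild the modeling frame for prediction
        raise_if_missing = [t.name for t in fit.terms]
        df = self.model.cohort.to_frame().loc[self.classes.index]
        sf_mask = self.classes != OutcomeClass.IMPROVEMENT.value
        success = (self.classes == OutcomeClass.SUCCESS.value)[sf_mask]
        cols = {}
        for name in raise_if_missing:
            if name in self.chosen_cuts:
                cut, direction = self.chosen_cuts[name]
                cols[name] = dichotomize(df, name, cut, direction)[success.index]
            elif name == "sex_female":
                cols[name] = (df.loc[success.index, "sex"] == "F").astype(float)
            else:
                cols[name] = df.loc[success.index, name].astype(float)
        X = pd.DataFrame(cols)
        keep = X.notna().all(axis=1)
        scores = fit.predict(X[keep])
        pts = roc_points(scores, success[keep].astype(float))
        if ax is None:
            _, ax = plt.subplots()
        ax.plot([1 - p.sp for p in pts], [p.se for p in pts], marker="o")
        ax.plot([0, 1], [0, 1], linestyle="--", color="grey")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"ROC — step {step_obj.step}")
        return ax

    def save_report(self, outdir) -> dict:
        from .report import build_report

        return build_report(self, outdir)
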