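"""Machine- and human-readable derivation reports.

``build_report`` serializes a :class:`~lumbarcpr.model.CPRDerivationResults`
into ``report.json`` (structured, validated by :func:`validate_report`) and
``report.txt`` (the results ``summary()``).  Approximated or degenerate
quantities carry explicit flags so nothing illustrative can be mistaken for
an estimate.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

__all__ = ["build_report", "validate_report", "ReportSchemaError"]

REQUIRED_SECTIONS = {
    "meta": dict,
    "outcomes": list,
    "cutpoint_audit": list,
    "screening": list,
    "models": list,
    "rule": (dict, type(None)),
    "performance": list,
}


class ReportSchemaError(ValueError):
    pass


def _clean(obj):
    """JSON-safe: NaN/inf -> None, tuples -> lists."""
    if isinstance(obj, float):
        return obj if math.isfinite(obj) else None
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    return obj


def validate_report(payload: dict) -> bool:
    """Structural check of a report dict; raises :class:`ReportSchemaError`."""
    if not isinstance(payload, dict):
        raise ReportSchemaError("report must be a JSON object")
    for key, typ in REQUIRED_SECTIONS.items():
        if key not in payload:
            raise ReportSchemaError(f"missing section {key!r}")
        if not isinstance(payload[key], typ):
            raise ReportSchemaError(f"section {key!r} has wrong type")
    for model in payload["models"]:
        for field in ("step", "terms", "minus2ll", "nagelkerke_r2_pct"):
            if field not in model:
                raise ReportSchemaError(f"model entry missing {field!r}")
    for row in payload["performance"]:
        for field in ("k", "table", "approximated"):
            if field not in row:
                raise ReportSchemaError(f"performance entry missing {field!r}")
    return True


def build_report(results, outdir: Path | str) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    payload: dict = {
        "meta": {
            "time": results.time.name,
            "n_classified": int(len(results.classes)),
            "class_counts": {k: int(v) for k, v in results.class_counts.items()},
            "pretest_probability": results.pretest,
            "n_modeled": results.n_modeled,
            "n_excluded_modeling": results.n_excluded_modeling,
            "provenance": results.model.cohort.provenance,
        },
        "outcomes": results.outcome_summary.to_dict(orient="records"),
        "cutpoint_audit": results.audit_frame().to_dict(orient="records"),
        "screening": results.screen_frame().to_dict(orient="records"),
        "models": [
            {
                "step": s.step,
                "candidate_pool": s.candidate_pool,
                "n": s.final_fit.n,
                "converged": s.final_fit.converged,
                "separation": s.final_fit.separation,
                "minus2ll": s.final_fit.minus2ll,
                "intercept": s.final_fit.intercept,
                "nagelkerke_r2_pct": s.summary.nagelkerke_r2 * 100,
                "auc": s.summary.auc,
                "hosmer_lemeshow": {
                    "chi2": s.summary.hl.chi2,
                    "p": s.summary.hl.p,
                    "df": s.summary.hl.df,
                    "skipped": s.summary.hl.skipped,
                    "reason": s.summary.hl.reason,
                },
                "removal_trace": [
                    {"term": name, "wald_p": p} for name, p in s.elimination.removal_trace
                ],
                "terms": [
                    {
                        "name": t.name,
                        "b": t.b,
                        "se": t.se,
                        "ci95": list(t.ci95),
                        "wald_p": t.wald_p,
                        "odds_ratio": t.odds_ratio,
                    }
                    for t in s.final_fit.terms
                ],
                "adequacy": [
                    {"term": name, "adequacy": a, "rank": rank}
                    for name, a, rank in s.summary.adequacy
                ],
            }
            for s in results.steps
        ],
        "rule": (
            None
            if results.rule is None
            else {
                "tests": [
                    {"name": t.name, "cut": t.cut, "direction": t.direction.value}
                    for t in results.rule.tests
                ],
                "recommended_k": results.rule.recommended_k,
            }
        ),
        "performance": [
            {
                "k": p.k,
                "table": {
                    "tp": p.table.tp, "fp": p.table.fp,
                    "fn": p.table.fn, "tn": p.table.tn,
                },
                "se": p.stats.se,
                "se_ci": list(p.stats.se_ci),
                "sp": p.stats.sp,
                "sp_ci": list(p.stats.sp_ci),
                "lr_pos": p.stats.lr_pos,
                "lr_pos_ci": list(p.stats.lr_pos_ci),
                "lr_neg": p.stats.lr_neg,
                "lr_neg_ci": list(p.stats.lr_neg_ci),
                "pv_pos": p.stats.pv_pos,
                "pv_neg": p.stats.pv_neg,
                "posttest_success_probability": p.posttest_success_probability,
                "approximated": p.stats.approximated,
                "flags": list(p.stats.flags),
            }
            for p in results.performance
        ],
    }
    payload = _clean(payload)
    validate_report(payload)

    (outdir / "report.json").write_text(
        json.dumps(payload, indent=2) + "\n", encoding="utf-8"
    )
    (outdir / "report.txt").write_text(results.summary() + "\n", encoding="utf-8")
    return payload
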