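"""Logistic-regression machinery and hierarchical backward-stepwise selection.

The multivariate stage models treatment success (success vs failure rows
only) on dichotomized clinical tests plus the demographic covariates age,
sex and BMI.  Selection is hierarchical in three steps — class-A
(treatment-specific) candidates first, then class-B (adherence-related),
then class-C (treatment-nonspecific) — with backward elimination inside
each step driven by Wald p-values until every retained term is significant.

The fitter is plain maximum likelihood via iteratively reweighted least
squares with Wald standard errors; quasi-separation is detected and flagged
rather than penalized.  Model-level diagnostics follow the usual clinical
reporting set: Nagelkerke's R², the Hosmer–Lemeshow calibration test, the
ROC area of the predicted risks, and per-term "adequacy" — the share of the
full model's deviance reduction each predictor achieves on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import expit

from .cohort import VariableClass
from .cutpoints import concordance_auc

__all__ = [
    "TermEstimate",
    "LogisticFit",
    "ModelSummary",
    "EliminationResult",
    "HierarchicalStep",
    "RankDeficiencyError",
    "fit_logistic",
    "nagelkerke_r2",
    "hosmer_lemeshow",
    "HosmerLemeshowResult",
    "adequacy_ranks",
    "backward_eliminate",
    "hierarchical_modeling",
    "ModelingConfig",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile
_SEPARATION_BOUND = 15.0  # |log-odds| beyond which we flag quasi-separation


class RankDeficiencyError(ValueError):
    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(f"design matrix is rank deficient; collinear columns: {columns}")


@dataclass(frozen=True)
class TermEstimate:
    name: str
    b: float
    se: float
    wald_p: float
    ci95: tuple[float, float]
    odds_ratio: float


@dataclass
class LogisticFit:
    terms: list[TermEstimate]
    intercept: float
    intercept_se: float
    minus2ll: float
    n: int
    converged: bool
    separation: bool = False
    _design_columns: list[str] = field(default_factory=list, repr=False)
    _beta: np.ndarray | None = field(default=None, repr=False)

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    def term(self, name: str) -> TermEstimate:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        A = np.column_stack(
            [np.ones(len(X))] + [X[c].to_numpy(dtype=float) for c in self._design_columns]
        )
        return expit(A @ self._beta)


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    eps = 1e-12
    mu = np.clip(mu, eps, 1 - eps)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def fit_logistic(X: pd.DataFrame, y, max_iter: int = 200) -> LogisticFit:
    """Maximum-likelihood logistic fit (intercept added internally).

    Converges when the largest score component falls below 1e-8 or the
    relative deviance change below 1e-10.  Diverging coefficients (quasi-
    separation) yield ``converged=False`` with the ``separation`` flag; a
    singular design raises :class:`RankDeficiencyError` naming the
    offending columns.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    cols = list(X.columns)
    n = len(y)
    if n <= len(cols):
        raise ValueError("need more observations than terms")
    A = np.column_stack([np.ones(n)] + [X[c].to_numpy(dtype=float) for c in cols])
    if np.isnan(A).any():
        raise ValueError("design matrix contains missing values")

    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # pivoted QR: columns past the numerical rank are the dependent ones
        _, r, piv = linalg.qr(A, mode="economic", pivoting=True)
        tol = abs(r[0, 0]) * max(A.shape) * np.finfo(float).eps
        bad = sorted(piv[np.sum(np.abs(np.diag(r)) > tol):])
        names = ["const"] + cols
        raise RankDeficiencyError([names[i] for i in bad])

    beta = np.zeros(A.shape[1])
    mu = expit(A @ beta)
    dev = _deviance(y, mu)
    converged = False
    for _ in range(max_iter):
        w = np.clip(mu * (1 - mu), 1e-10, None)
        score = A.T @ (y - mu)
        if np.max(np.abs(score)) < 1e-8:
            converged = True
            break
        H = (A * w[:, None]).T @ A
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            break
        # step halving keeps the deviance monotone
        new_beta, new_dev = beta + step, math.inf
        for _ in range(30):
            new_dev = _deviance(y, expit(A @ new_beta))
            if new_dev <= dev + 1e-12:
                break
            new_beta = (beta + new_beta) / 2.0
        rel = abs(dev - new_dev) / (abs(dev) + 1e-12)
        beta, dev, mu = new_beta, new_dev, expit(A @ new_beta)
        if rel < 1e-10:
            converged = True
            break

    separation = bool(np.max(np.abs(beta)) > _SEPARATION_BOUND)
    if separation:
        converged = False

    w = np.clip(mu * (1 - mu), 1e-10, None)
    H = (A * w[:, None]).T @ A
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((A.shape[1], A.shape[1]), np.nan)
    ses = np.sqrt(np.clip(np.diag(cov), 0, None))

    terms = []
    for i, name in enumerate(cols, start=1):
        b, se = float(beta[i]), float(ses[i])
        z = b / se if se > 0 else math.nan
        terms.append(
            TermEstimate(
                name=name,
                b=b,
                se=se,
                wald_p=float(2 * stats.norm.sf(abs(z))) if se > 0 else math.nan,
                ci95=(b - _Z95 * se, b + _Z95 * se),
                odds_ratio=math.exp(b),
            )
        )
    return LogisticFit(
        terms=terms,
        intercept=float(beta[0]),
        intercept_se=float(ses[0]),
        minus2ll=dev,
        n=n,
        converged=converged,
        separation=separation,
        _design_columns=cols,
        _beta=beta,
    )


def nagelkerke_r2(fit: LogisticFit, null_minus2ll: float) -> float:
    """Rescaled likelihood R²  in [0, 1)."""
    n = fit.n
    cox_snell = 1.0 - math.exp((fit.minus2ll - null_minus2ll) / n)
    max_r2 = 1.0 - math.exp(-null_minus2ll / n)
    return cox_snell / max_r2 if max_r2 > 0 else 0.0


@dataclass(frozen=True)
class HosmerLemeshowResult:
    chi2: float
    p: float
    df: int
    n_bins: int
    skipped: bool = False
    reason: str = ""


def hosmer_lemeshow(p_hat, y, groups: int = 10) -> HosmerLemeshowResult:
    """Hosmer–Lemeshow calibration test on predicted-risk bins.

    Risks are cut at decile boundaries with ties kept together; bins whose
    expected event or non-event count is zero are merged with a neighbour
    and the degrees of freedom (bins − 2) adjusted.  With fewer than three
    distinct predicted values — common when the model holds only a few
    binary tests — the test is skipped and flagged.
    """
    p_hat = np.asarray(p_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(np.round(p_hat, 12)).size < 3:
        return HosmerLemeshowResult(math.nan, math.nan, 0, 0, True, "fewer than 3 distinct risks")
    try:
        bins = pd.qcut(p_hat, q=min(groups, len(p_hat)), duplicates="drop")
    except ValueError:
        return HosmerLemeshowResult(math.nan, math.nan, 0, 0, True, "binning failed")
    df_bins = (
        pd.DataFrame({"y": y, "p": p_hat, "bin": bins})
        .groupby("bin", observed=True)
        .agg(o1=("y", "sum"), e1=("p", "sum"), n=("y", "size"))
        .reset_index(drop=True)
    )
    # merge degenerate bins (zero expected events or non-events) upward
    rows = df_bins.to_dict("records")
    merged: list[dict] = []
    for row in rows:
        if merged and (
            merged[-1]["e1"] <= 1e-9 or merged[-1]["n"] - merged[-1]["e1"] <= 1e-9
        ):
            merged[-1] = {k: merged[-1][k] + row[k] for k in ("o1", "e1", "n")}
        else:
            merged.append(dict(row))
    if len(merged) > 1 and (
        merged[-1]["e1"] <= 1e-9 or merged[-1]["n"] - merged[-1]["e1"] <= 1e-9
    ):
        last = merged.pop()
        merged[-1] = {k: merged[-1][k] + last[k] for k in ("o1", "e1", "n")}
    g = len(merged)
    if g < 3:
        return HosmerLemeshowResult(math.nan, math.nan, 0, g, True, "too few usable bins")
    chi2 = 0.0
    for row in merged:
        e1, n_b, o1 = row["e1"], row["n"], row["o1"]
        e0 = n_b - e1
        chi2 += (o1 - e1) ** 2 / e1 + ((n_b - o1) - e0) ** 2 / e0
    df = g - 2
    return HosmerLemeshowResult(float(chi2), float(stats.chi2.sf(chi2, df)), df, g)


def adequacy_ranks(
    X: pd.DataFrame, y, fit: LogisticFit
) -> list[tuple[str, float, int]]:
    """Per-term share of the full model's deviance reduction.

    For each retained term, the single-predictor model (term + intercept)
    is refitted on the same rows; adequacy = (D_null − D_single) /
    (D_null − D_full).  Rank 1 is the most influential; ties (to 1e-9)
    share a rank.
    """
    y = np.asarray(y, dtype=float)
    null_dev = _deviance(y, np.full_like(y, y.mean()))
    denom = null_dev - fit.minus2ll
    entries = []
    for name in fit.term_names:
        single = fit_logistic(X[[name]], y)
        adequacy = (null_dev - single.minus2ll) / denom if denom > 0 else math.nan
        entries.append((name, float(adequacy)))
    order = sorted(entries, key=lambda e: -e[1])
    ranks: dict[str, int] = {}
    rank, prev = 0, None
    for i, (name, a) in enumerate(order, start=1):
        if prev is None or abs(a - prev) > 1e-9:
            rank = i
        ranks[name] = rank
        prev = a
    return [(name, a, ranks[name]) for name, a in entries]


@dataclass
class EliminationResult:
    final_fit: LogisticFit
    removal_trace: list[tuple[str, float]]
    pool: list[str]
    forced: list[str]
    intercept_only: bool = False
    halted_on_separation: bool = False


def backward_eliminate(
    X: pd.DataFrame,
    y,
    pool: list[str],
    forced_stay: list[str] | None = None,
    alpha_retain: float = 0.05,
) -> EliminationResult:
    """Backward stepwise elimination on Wald p-values.

    Repeatedly drops the removable term with the largest p ≥ ``alpha_retain``
    (ties broken alphabetically for determinism) until every removable term
    is significant.  Forced terms are never dropped.  A quasi-separated fit
    halts elimination with a flag; an emptied pool returns the intercept-only
    fit, flagged.
    """
    forced = list(forced_stay or [])
    current = list(dict.fromkeys(list(pool) + forced))
    trace: list[tuple[str, float]] = []
    halted = False
    while True:
        fit = fit_logistic(X[current], y) if current else _intercept_only(y)
        if not current:
            return EliminationResult(fit, trace, list(pool), forced, intercept_only=True)
        if fit.separation:
            halted = True
            break
        removable = [t for t in fit.terms if t.name not in forced]
        if not removable:
            break
        worst = max(removable, key=lambda t: (t.wald_p, t.name))
        if not (worst.wald_p >= alpha_retain or math.isnan(worst.wald_p)):
            break
        trace.append((worst.name, float(worst.wald_p)))
        current.remove(worst.name)
    return EliminationResult(
        fit, trace, list(pool), forced,
        intercept_only=not current, halted_on_separation=halted,
    )


def _intercept_only(y) -> LogisticFit:
    y = np.asarray(y, dtype=float)
    p = y.mean()
    n = len(y)
    return LogisticFit(
        terms=[],
        intercept=math.log(p / (1 - p)),
        intercept_se=math.sqrt(1.0 / (n * p * (1 - p))),
        minus2ll=_deviance(y, np.full_like(y, p)),
        n=n,
        converged=True,
        _design_columns=[],
        _beta=np.array([math.log(p / (1 - p))]),
    )


@dataclass(frozen=True)
class ModelSummary:
    nagelkerke_r2: float
    hl: HosmerLemeshowResult
    auc: float
    adequacy: list[tuple[str, float, int]]


@dataclass
class HierarchicalStep:
    step: str  # "A_only" | "A_plus_B" | "A_plus_B_plus_C"
    candidate_pool: list[str]
    elimination: EliminationResult
    summary: ModelSummary

    @property
    def final_fit(self) -> LogisticFit:
        return self.elimination.final_fit


@dataclass(frozen=True)
class ModelingConfig:
    alpha_retain: float = 0.05
    force_confounders: bool = False
    confounders: tuple[str, ...] = ("age", "sex_female", "bmi")


def _summarize(X: pd.DataFrame, y, fit: LogisticFit) -> ModelSummary:
    y_arr = np.asarray(y, dtype=float)
    null_dev = _deviance(y_arr, np.full_like(y_arr, y_arr.mean()))
    if fit.term_names:
        p_hat = fit.predict(X)
        auc_val = concordance_auc(p_hat, y_arr) if np.unique(p_hat).size > 1 else math.nan
        hl = hosmer_lemeshow(p_hat, y_arr)
        adequacy = adequacy_ranks(X, y_arr, fit)
    else:
        auc_val, hl, adequacy = math.nan, HosmerLemeshowResult(
            math.nan, math.nan, 0, 0, True, "intercept-only model"
        ), []
    return ModelSummary(
        nagelkerke_r2=nagelkerke_r2(fit, null_dev),
        hl=hl,
        auc=auc_val,
        adequacy=adequacy,
    )


def hierarchical_modeling(
    X: pd.DataFrame,
    y,
    classes: dict[str, VariableClass],
    config: ModelingConfig = ModelingConfig(),
) -> list[HierarchicalStep]:
    """Three-step hierarchical selection over screened candidates.

    ``X`` holds the dichotomized accepted tests plus any confounder columns
    (age, sex_female, BMI); ``classes`` assigns each test its A/B/C tier.
    Step 1 eliminates within class-A candidates + confounders; step 2 adds
    class-B candidates to the step-1 survivors and re-eliminates; step 3
    likewise with class-C.  Confounders are removable unless
    ``force_confounders`` is set.
    """
    by_class = {k: [] for k in VariableClass}
    for name, klass in classes.items():
        if name in X.columns:
            by_class[klass].append(name)
    confounders = [c for c in config.confounders if c in X.columns]
    forced = confounders if config.force_confounders else []

    steps: list[HierarchicalStep] = []
    survivors: list[str] = []
    plan = [
        ("A_only", by_class[VariableClass.A] + confounders),
        ("A_plus_B", by_class[VariableClass.B]),
        ("A_plus_B_plus_C", by_class[VariableClass.C]),
    ]
    for label, additions in plan:
        pool = list(dict.fromkeys(survivors + additions))
        elim = backward_eliminate(X, y, pool, forced_stay=forced,
                                  alpha_retain=config.alpha_retain)
        summary = _summarize(X, y, elim.final_fit)
        steps.append(HierarchicalStep(label, pool, elim, summary))
        survivors = elim.final_fit.term_names
    return steps
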