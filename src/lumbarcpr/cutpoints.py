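"""Dichotomization of candidate predictors and univariate screening.

Continuous and ordinal predictors are turned into binary clinical tests by
scanning candidate thresholds (midpoints between consecutive distinct
observed values, plus infinite sentinels) and optimizing one of six
criteria against the success/failure labels:

* ROC       — point closest to perfect (Se, Sp) = (1, 1)
* Md        — pooled median (no optimization)
* YI        — maximum Youden index J = Se + Sp - 1
* dMinSnSp  — minimum |Se - Sp| (balances the two error rates)
* LRmax     — maximum positive likelihood ratio Se / (1 - Sp), requiring at
  least one false positive so the ratio is finite
* KLfg/KLgf — maximum Kullback–Leibler divergence between the Bernoulli
  "test positive" distributions in the success (f) and failure (g) groups,
  D(f‖g) = Se·ln(Se/(1-Sp)) + (1-Se)·ln((1-Se)/Sp) and its mirror,
  with 0·ln 0 = 0 and cuts giving an infinite divergence inadmissible.

Ties are broken toward the cut with the larger Youden J, then the smaller
cut value.  Screening then accepts a dichotomous test for multivariate
modeling when its Pearson chi-square p-value is < 0.20 (a deliberately
liberal filter) or its LR+ is >= 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, DirectionHint

__all__ = [
    "CutDirection",
    "CutMethod",
    "TwoByTwo",
    "RocPoint",
    "CutpointResult",
    "ScreenResult",
    "DegenerateDataError",
    "roc_points",
    "auc",
    "concordance_auc",
    "select_cutpoint",
    "select_cutpoint_auto",
    "dichotomize",
    "chi_square_2x2",
    "screen_variables",
]


class DegenerateDataError(ValueError):
    """Labels contain a single class; no discrimination is measurable."""


class CutDirection(Enum):
    GE_POSITIVE = "ge_positive"  # value >= cut counts as a positive test
    LE_POSITIVE = "le_positive"  # value <= cut counts as a positive test


class CutMethod(Enum):
    ROC = "ROC"
    MD = "Md"
    YI = "YI"
    DMINSNSP = "dMinSnSp"
    LRMAX = "LRmax"
    KLFG = "KLfg"
    KLGF = "KLgf"


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 diagnostic table: rows = test +/-, columns = success/failure."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_success(self) -> int:
        return self.tp + self.fn

    @property
    def n_failure(self) -> int:
        return self.fp + self.tn

    @property
    def se(self) -> float:
        return self.tp / self.n_success if self.n_success else math.nan

    @property
    def sp(self) -> float:
        return self.tn / self.n_failure if self.n_failure else math.nan

    @property
    def youden_j(self) -> float:
        return self.se + self.sp - 1.0

    @property
    def lr_pos(self) -> float:
        """Se/(1-Sp); +inf when there are no false positives but some hits."""
        fpr = 1.0 - self.sp
        if fpr > 0:
            return self.se / fpr
        return math.inf if self.se > 0 else math.nan

    @classmethod
    def from_binary(cls, test: np.ndarray, success: np.ndarray) -> "TwoByTwo":
        test = np.asarray(test, dtype=bool)
        success = np.asarray(success, dtype=bool)
        return cls(
            tp=int(np.sum(test & success)),
            fp=int(np.sum(test & ~success)),
            fn=int(np.sum(~test & success)),
            tn=int(np.sum(~test & ~success)),
        )


@dataclass(frozen=True)
class RocPoint:
    cut: float
    se: float
    sp: float


@dataclass(frozen=True)
class CutpointResult:
    variable: str
    method: CutMethod
    cut: float
    direction: CutDirection
    table: TwoByTwo
    youden_j: float
    lr_pos: float
    kl_fg: float
    kl_gf: float
    fallback_to_yi: bool = False  # set when LRmax/KL had no admissible cut


@dataclass(frozen=True)
class ScreenResult:
    variable: str
    chi2: float
    p: float
    lr_pos: float
    accepted: bool
    acceptance_reason: str  # "p_lt_020" | "lr_ge_2" | "rejected"
    haldane_corrected: bool = False
    table: TwoByTwo | None = None


def _clean(values, labels) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=float)
    keep = ~np.isnan(values) & ~np.isnan(labels)
    values, labels = values[keep], labels[keep].astype(bool)
    if values.size == 0 or labels.all() or not labels.any():
        raise DegenerateDataError("need observations from both outcome classes")
    return values, labels


def _candidate_cuts(values: np.ndarray) -> np.ndarray:
    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate(([-math.inf], mids, [math.inf]))


def _se_sp_at_cuts(
    values: np.ndarray,
    labels: np.ndarray,
    cuts: np.ndarray,
    direction: CutDirection,
) -> tuple[np.ndarray, np.ndarray]:
    """Se/Sp at every cut via a single sorted sweep (O(n log n))."""
    n1 = int(labels.sum())
    n0 = labels.size - n1
    order = np.argsort(values, kind="mergesort")
    sv, sl = values[order], labels[order]
    # successes with value < cut, via searchsorted on the sorted values
    cum_succ = np.concatenate(([0], np.cumsum(sl)))
    idx = np.searchsorted(sv, cuts, side="left")
    succ_below = cum_succ[idx]          # successes strictly below cut
    total_below = idx
    if direction is CutDirection.GE_POSITIVE:
        tp = n1 - succ_below
        fp = n0 - (total_below - succ_below)
    else:  # value <= cut positive: count strictly above cut as negative
        idx_hi = np.searchsorted(sv, cuts, side="right")
        succ_le = cum_succ[idx_hi]
        tp = succ_le
        fp = idx_hi - succ_le
    se = tp / n1
    sp = (n0 - fp) / n0
    return se, sp


def roc_points(
    values,
    labels,
    direction: CutDirection = CutDirection.GE_POSITIVE,
) -> list[RocPoint]:
    """One (cut, Se, Sp) per candidate threshold, including ±inf sentinels."""
    values, labels = _clean(values, labels)
    cuts = _candidate_cuts(values)
    se, sp = _se_sp_at_cuts(values, labels, cuts, direction)
    return [RocPoint(float(c), float(a), float(b)) for c, a, b in zip(cuts, se, sp)]


def auc(points: list[RocPoint]) -> float:
    """Trapezoidal area under the ROC curve traced by ``points``.

    Equals the Mann–Whitney concordance probability of the underlying
    scores (ties counted half).
    """
    if len(points) < 2:
        raise ValueError("need at least two ROC points")
    fpr = np.array([1.0 - p.sp for p in points])
    tpr = np.array([p.se for p in points])
    order = np.lexsort((tpr, fpr))
    return float(abs(np.trapezoid(tpr[order], fpr[order])))


def concordance_auc(scores, labels) -> float:
    """AUC as the rank (Mann–Whitney) concordance of scores vs labels."""
    scores, labels = _clean(scores, labels)
    n1 = int(labels.sum())
    n0 = scores.size - n1
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _kl(se: np.ndarray, sp: np.ndarray, mirrored: bool) -> np.ndarray:
    """D(f‖g) between Bernoulli(positive | success) and (positive | failure).

    0·ln 0 = 0; inadmissible (infinite) divergences come out as +inf and
    are excluded by the caller.
    """
    if mirrored:                # D(g‖f): g = Bernoulli(1-Sp), f = Bernoulli(Se)
        p, q = 1.0 - sp, se
    else:                       # D(f‖g)
        p, q = se, 1.0 - sp
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(p > 0, p * np.log(p / q), 0.0)
        t2 = np.where(p < 1, (1 - p) * np.log((1 - p) / (1 - q)), 0.0)
    out = t1 + t2
    out[np.isnan(out)] = math.inf
    return out


def _pick(cuts, score, je, better_is_larger=True, admissible=None) -> int | None:
    """Index of the optimal cut; ties to larger Youden J then smaller cut."""
    score = np.asarray(score, dtype=float)
    if admissible is None:
        admissible = np.isfinite(score)
    else:
        admissible = admissible & np.isfinite(score)
    if not admissible.any():
        return None
    idx = np.flatnonzero(admissible)
    s = score[idx]
    best = s.max() if better_is_larger else s.min()
    tied = idx[np.isclose(s, best, rtol=0, atol=1e-12)]
    best_j = np.max(je[tied])
    tied = tied[np.isclose(je[tied], best_j, rtol=0, atol=1e-12)]
    return int(tied[np.argmin(cuts[tied])])


def select_cutpoint(
    values,
    labels,
    method: CutMethod,
    direction: CutDirection = CutDirection.GE_POSITIVE,
    variable: str = "",
) -> CutpointResult:
    """Optimal threshold for one predictor under one criterion.

    ``labels`` are success (1/True) vs failure (0/False); rows with missing
    values are dropped.  LRmax and the KL criteria fall back to the Youden
    cut (flagged) when no admissible threshold exists.
    """
    values, labels = _clean(values, labels)
    cuts = _candidate_cuts(values)
    se, sp = _se_sp_at_cuts(values, labels, cuts, direction)
    j = se + sp - 1.0
    fallback = False

    if method is CutMethod.MD:
        cut = float(np.median(values))
    else:
        if method is CutMethod.ROC:
            idx = _pick(cuts, (1 - se) ** 2 + (1 - sp) ** 2, j, better_is_larger=False)
        elif method is CutMethod.YI:
            idx = _pick(cuts, j, j)
        elif method is CutMethod.DMINSNSP:
            idx = _pick(cuts, np.abs(se - sp), j, better_is_larger=False)
        elif method is CutMethod.LRMAX:
            n0 = int((~labels).sum())
            fp = np.round((1.0 - sp) * n0).astype(int)
            with np.errstate(divide="ignore", invalid="ignore"):
                lr = np.where(fp >= 1, se / (1 - sp), -math.inf)
            idx = _pick(cuts, lr, j, admissible=fp >= 1)
        elif method in (CutMethod.KLFG, CutMethod.KLGF):
            d = _kl(se, sp, mirrored=(method is CutMethod.KLGF))
            idx = _pick(cuts, d, j, admissible=np.isfinite(d))
        else:  # pragma: no cover
            raise ValueError(f"unknown method {method}")
        if idx is None:
            fallback = True
            idx = _pick(cuts, j, j)
        cut = float(cuts[idx])

    table = _table_at(values, labels, cut, direction)
    kf = _kl(np.array([table.se]), np.array([table.sp]), mirrored=False)[0]
    kg = _kl(np.array([table.se]), np.array([table.sp]), mirrored=True)[0]
    return CutpointResult(
        variable=variable,
        method=method,
        cut=cut,
        direction=direction,
        table=table,
        youden_j=table.youden_j,
        lr_pos=table.lr_pos,
        kl_fg=float(kf),
        kl_gf=float(kg),
        fallback_to_yi=fallback,
    )


def _table_at(values, labels, cut, direction: CutDirection) -> TwoByTwo:
    if direction is CutDirection.GE_POSITIVE:
        positive = values >= cut
    else:
        positive = values <= cut
    return TwoByTwo.from_binary(positive, labels)


def select_cutpoint_auto(
    values,
    labels,
    method: CutMethod,
    hint: DirectionHint = DirectionHint.UNKNOWN,
    variable: str = "",
) -> CutpointResult:
    """Like :func:`select_cutpoint`, resolving the test direction.

    A stated hint is honored; otherwise both directions are scanned and the
    one whose optimum gives LR+ > 1 (larger Youden J as arbiter) is kept,
    so a positive test always points toward treatment success.
    """
    if hint is DirectionHint.HIGH_IS_POSITIVE:
        return select_cutpoint(values, labels, method, CutDirection.GE_POSITIVE, variable)
    if hint is DirectionHint.LOW_IS_POSITIVE:
        return select_cutpoint(values, labels, method, CutDirection.LE_POSITIVE, variable)
    a = select_cutpoint(values, labels, method, CutDirection.GE_POSITIVE, variable)
    b = select_cutpoint(values, labels, method, CutDirection.LE_POSITIVE, variable)
    return a if a.youden_j >= b.youden_j else b


def dichotomize(
    cohort: Cohort | pd.DataFrame,
    variable: str,
    cut: float,
    direction: CutDirection,
) -> pd.Series:
    """Binary test column (1/0, NaN propagates missingness).

    ``ge_positive``: value >= cut is positive; ``le_positive``: value <= cut.
    Strict printed rules on integer scales (e.g. a 0–9 laxity score "< 5")
    are expressed exactly as ``le_positive`` at the next lower integer.
    """
    df = cohort.to_frame() if isinstance(cohort, Cohort) else cohort
    col = df[variable].astype(float)
    if direction is CutDirection.GE_POSITIVE:
        out = (col >= cut).astype(float)
    else:
        out = (col <= cut).astype(float)
    out[col.isna()] = np.nan
    out.name = variable
    return out


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    p: float
    degenerate: bool = False

    def __iter__(self):
        return iter((self.chi2, self.p))


def chi_square_2x2(table: TwoByTwo) -> ChiSquareResult:
    """Pearson chi-square (df=1, no continuity correction).

    A zero margin makes independence untestable; returns chi2=0, p=1 with
    the degenerate flag set.
    """
    a, b, c, d = table.tp, table.fp, table.fn, table.tn
    n = table.n
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return ChiSquareResult(0.0, 1.0, degenerate=True)
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return ChiSquareResult(float(chi2), float(stats.chi2.sf(chi2, df=1)))


def _screen_lr_pos(table: TwoByTwo) -> tuple[float, bool]:
    """LR+ with a Haldane–Anscombe 0.5 correction when any cell is zero."""
    if min(table.tp, table.fp, table.fn, table.tn) == 0:
        tp, fp = table.tp + 0.5, table.fp + 0.5
        fn, tn = table.fn + 0.5, table.tn + 0.5
        se = tp / (tp + fn)
        fpr = fp / (fp + tn)
        return se / fpr, True
    return table.lr_pos, False


def screen_variables(
    tests: pd.DataFrame,
    success: pd.Series,
    alpha: float = 0.20,
    lr_threshold: float = 2.0,
) -> list[ScreenResult]:
    """Univariate screen of dichotomous tests against success vs failure.

    ``tests`` holds 0/1 columns (NaN = missing, dropped per test);
    ``success`` is boolean over the same index and must already exclude the
    improvement class.  A test is accepted when p < ``alpha`` or
    LR+ >= ``lr_threshold``.
    """
    results = []
    succ = success.astype(bool)
    for name in tests.columns:
        col = tests[name]
        keep = col.notna()
        table = TwoByTwo.from_binary(
            col[keep].to_numpy(dtype=float) > 0.5, succ[keep].to_numpy()
        )
        chi = chi_square_2x2(table)
        lr, corrected = _screen_lr_pos(table)
        if chi.p < alpha:
            reason = "p_lt_020"
        elif lr >= lr_threshold:
            reason = "lr_ge_2"
        else:
            reason = "rejected"
        results.append(
            ScreenResult(
                variable=name,
                chi2=chi.chi2,
                p=chi.p,
                lr_pos=float(lr),
                accepted=reason != "rejected",
                acceptance_reason=reason,
                haldane_corrected=corrected,
                table=table,
            )
        )
    return results
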