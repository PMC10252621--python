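"""Diagnostic-accuracy engine for ordinal test scores.

Confusion matrices, operating-point metrics, empirical ROC curves, the
tie-aware concordance AUC, Youden-index and 100%-NPV cut-off selection,
the DeLong test for paired AUCs, median/IQR summaries, and an exhaustive
integer-search oracle that reconstructs confusion matrices from printed
summary metrics.

Conventions
-----------
* Truth labels are the strings ``"benign"`` / ``"malignant"`` (booleans or
  0/1 integers are also accepted, truthy meaning malignant).
* A lesion is test-positive iff its score is **greater than or equal to**
  the cut-off.  Under this convention a reported cut-off of c means
  "scores of c or more are called malignant".
* AUC is the concordance probability: over all (malignant, benign) pairs,
  the fraction in which the malignant lesion scores higher, with half
  credit for ties.  This equals the trapezoidal area under the empirical
  ROC staircase.
* Undefined ratios (zero denominators) are reported as NaN and flagged in
  ``DiagnosticMetrics.undefined`` — never silently coerced to 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "ConfusionMatrix",
    "DiagnosticMetrics",
    "ROCSummary",
    "DeLongResult",
    "SummaryStats",
    "ReconstructionResult",
    "DegenerateCutoffWarning",
    "confusion_at_cutoff",
    "metrics",
    "roc_points",
    "auc",
    "youden_optimal_cutoff",
    "clinical_cutoff_100npv",
    "delong_paired_test",
    "summarize_scores",
    "reconstruct_confusion",
    "evaluate_scores",
    "table_report",
    "round_half_up",
]


class DegenerateCutoffWarning(UserWarning):
    """The 100%-NPV cut-off leaves no true negatives."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts; rows are truth, columns the test call."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Operating-point metrics; NaN entries are listed in ``undefined``."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    youden_j: float
    undefined: frozenset[str] = frozenset()


@dataclass(frozen=True)
class SummaryStats:
    median: float
    iqr_low: float
    iqr_high: float


@dataclass(frozen=True)
class ROCSummary:
    auc: float
    youden_cutoff: float
    clinical_cutoff_100npv: float
    metrics_at_youden: DiagnosticMetrics
    metrics_at_clinical: DiagnosticMetrics
    cm_at_youden: ConfusionMatrix
    cm_at_clinical: ConfusionMatrix


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    cov_ab: float
    z: float
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class ReconstructionResult:
    """Outcome of the exhaustive confusion-matrix search.

    ``consistent`` is False when no matrix satisfies all constraints —
    i.e. the printed metrics contradict each other at the stated margins.
    """

    matrices: tuple[ConfusionMatrix, ...]
    n_positive: int
    n_negative: int

    @property
    def unique(self) -> bool:
        return len(self.matrices) == 1

    @property
    def consistent(self) -> bool:
        return len(self.matrices) > 0


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    if s.shape != lab.shape:
        raise ValueError(
            f"scores and labels differ in length ({s.size} vs {lab.size})"
        )
    if lab.dtype.kind in "USO":
        valid = np.isin(lab, ("benign", "malignant"))
        if not valid.all():
            bad = sorted(set(np.asarray(lab)[~valid]))
            raise ValueError(f"unknown truth label(s) {bad}")
        pos = lab == "malignant"
    else:
        pos = lab.astype(bool)
    x, y = s[pos], s[~pos]
    if x.size == 0 or y.size == 0:
        raise ValueError("need at least one malignant and one benign lesion")
    return x, y


def confusion_at_cutoff(scores, labels, cutoff) -> ConfusionMatrix:
    """Count TP/FP/FN/TN with test-positive defined as score >= cutoff."""
    x, y = _split(scores, labels)
    return ConfusionMatrix(
        tp=int((x >= cutoff).sum()),
        fp=int((y >= cutoff).sum()),
        fn=int((x < cutoff).sum()),
        tn=int((y < cutoff).sum()),
    )


def _ratio(num: int, den: int, name: str, undefined: set[str]) -> float:
    if den == 0:
        undefined.add(name)
        return math.nan
    return num / den


def metrics(cm: ConfusionMatrix) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV, accuracy and Youden's
    J = sensitivity + specificity - 1."""
    und: set[str] = set()
    sens = _ratio(cm.tp, cm.tp + cm.fn, "sensitivity", und)
    spec = _ratio(cm.tn, cm.tn + cm.fp, "specificity", und)
    ppv = _ratio(cm.tp, cm.tp + cm.fp, "ppv", und)
    npv = _ratio(cm.tn, cm.tn + cm.fn, "npv", und)
    acc = _ratio(cm.tp + cm.tn, cm.total, "accuracy", und)
    j = sens + spec - 1.0
    if math.isnan(j):
        und.add("youden_j")
    return DiagnosticMetrics(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        accuracy=acc,
        youden_j=j,
        undefined=frozenset(und),
    )


def roc_points(scores, labels) -> np.ndarray:
    """Empirical ROC staircase as an array of (1 - specificity,
    sensitivity) pairs, one per distinct score threshold plus the (0, 0)
    anchor, ordered from (0, 0) to (1, 1)."""
    x, y = _split(scores, labels)
    cuts = np.unique(np.concatenate([x, y]))[::-1]  # descending
    pts = [(0.0, 0.0)]
    for c in cuts:
        pts.append((float((y >= c).mean()), float((x >= c).mean())))
    return np.asarray(pts)


def auc(scores, labels) -> float:
    """Concordance-probability AUC with half credit for ties.

    Computed through mid-ranks (Mann-Whitney), which is algebraically
    identical to averaging over all malignant/benign pairs and to the
    trapezoidal area under :func:`roc_points`.
    """
    x, y = _split(scores, labels)
    m, n = x.size, y.size
    ranks = rankdata(np.concatenate([x, y]))
    return float((ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n))


def _candidate_cutoffs(scores) -> np.ndarray:
    uniq = np.unique(np.asarray(scores, dtype=float))
    step = 1.0 if np.allclose(uniq, np.round(uniq)) else np.min(np.diff(uniq), initial=1.0)
    return np.append(uniq, uniq[-1] + step)


def youden_optimal_cutoff(scores, labels):
    """Cut-off maximizing J = sensitivity + specificity - 1.

    Candidates are the distinct observed scores plus one value above the
    maximum (the all-negative rule).  Ties are broken toward the smallest
    cut-off, which maximizes sensitivity at equal J.
    """
    _split(scores, labels)  # validates
    best_c, best_j = None, -math.inf
    for c in _candidate_cutoffs(scores):
        m = metrics(confusion_at_cutoff(scores, labels, c))
        if m.youden_j > best_j + 1e-12:
            best_c, best_j = c, m.youden_j
    return int(best_c) if float(best_c).is_integer() else float(best_c)


def clinical_cutoff_100npv(scores, labels):
    """Largest cut-off at which every test-negative lesion is benign.

    With the >= positivity convention this is exactly the minimum
    malignant score: at that cut-off no malignant lesion tests negative,
    so NPV is 100% (the clinically acceptable rule-out point).  If no
    benign lesion scores below it there are no true negatives at all;
    the cut-off is still returned but a
    :class:`DegenerateCutoffWarning` is emitted.
    """
    x, y = _split(scores, labels)
    c = x.min()
    if (y < c).sum() == 0:
        warnings.warn(
            "100%-NPV cut-off leaves no true negatives (no benign lesion "
            "scores below the minimum malignant score)",
            DegenerateCutoffWarning,
            stacklevel=2,
        )
    return int(c) if float(c).is_integer() else float(c)


def _structural_components(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-observation DeLong components via mid-ranks.

    V10[i] = P-hat(Y < x_i) + .5 P-hat(Y = x_i); V01[j] analogous.
    """
    m, n = x.size, y.size
    allr = rankdata(np.concatenate([x, y]))
    rx = rankdata(x)
    ry = rankdata(y)
    v10 = (allr[:m] - rx) / n
    v01 = 1.0 - (allr[m:] - ry) / m
    a = float((allr[:m].sum() - m * (m + 1) / 2.0) / (m * n))
    return v10, v01, a


def delong_paired_test(scores_a, scores_b, labels) -> DeLongResult:
    """DeLong test for two correlated (paired) AUCs.

    Both score vectors must refer to the same lesions in the same order.
    Variances and the covariance come from the per-observation structural
    components (mid-rank formulation);
    z = (AUC_a - AUC_b) / sqrt(var_a + var_b - 2 cov) with a two-sided
    normal p-value and no continuity correction.  When the variance of
    the difference is zero the test is degenerate: p = 1 if the AUCs are
    equal (z = 0), otherwise p is NaN and flagged.
    """
    xa, ya = _split(scores_a, labels)
    xb, yb = _split(scores_b, labels)
    if xa.size != xb.size or ya.size != yb.size:
        raise ValueError("paired score vectors must cover the same lesions")
    v10a, v01a, auc_a = _structural_components(xa, ya)
    v10b, v01b, auc_b = _structural_components(xb, yb)
    m, n = xa.size, ya.size
    if m < 2 or n < 2:
        raise ValueError("need at least two lesions per class for the variance")
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    s = s10 / m + s01 / n
    var_a, var_b, cov_ab = float(s[0, 0]), float(s[1, 1]), float(s[0, 1])
    var_diff = var_a + var_b - 2.0 * cov_ab
    diff = auc_a - auc_b
    if var_diff <= 0 or math.isclose(var_diff, 0.0, abs_tol=1e-300):
        if math.isclose(diff, 0.0, abs_tol=1e-15):
            return DeLongResult(auc_a, auc_b, var_a, var_b, cov_ab,
                                z=0.0, p=1.0, degenerate=True)
        return DeLongResult(auc_a, auc_b, var_a, var_b, cov_ab,
                            z=math.nan, p=math.nan, degenerate=True)
    z = diff / math.sqrt(var_diff)
    p = float(2.0 * norm.sf(abs(z)))
    return DeLongResult(auc_a, auc_b, var_a, var_b, cov_ab, z=z, p=p)


def summarize_scores(scores) -> SummaryStats:
    """Median and interquartile range (25th/75th percentiles, linear
    interpolation between order statistics)."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("cannot summarize an empty score vector")
    lo, med, hi = np.percentile(s, [25, 50, 75])
    return SummaryStats(median=float(med), iqr_low=float(lo), iqr_high=float(hi))


def round_half_up(value, decimals: int) -> Decimal:
    """Decimal round-half-up, the convention of printed clinical tables."""
    q = Decimal(1).scaleb(-decimals)
    return Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP)


_METRIC_COUNTS = {
    "sensitivity": lambda c: (c.tp, c.tp + c.fn),
    "specificity": lambda c: (c.tn, c.tn + c.fp),
    "ppv": lambda c: (c.tp, c.tp + c.fp),
    "npv": lambda c: (c.tn, c.tn + c.fn),
    "accuracy": lambda c: (c.tp + c.tn, c.total),
}


def _percent(num: int, den: int, decimals: int) -> Decimal | None:
    if den == 0:
        return None
    return (Decimal(num) * 100 / Decimal(den)).quantize(
        Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP
    )


def reconstruct_confusion(
    n_pos: int,
    n_neg: int,
    constraints: Iterable[tuple[str, float | str, int]],
) -> ReconstructionResult:
    """Exhaustively search confusion matrices matching printed metrics.

    Enumerates every (TP, FN, TN, FP) with TP + FN = ``n_pos`` and
    TN + FP = ``n_neg`` and keeps those whose metrics, expressed as
    percentages and rounded half-up to the stated number of decimals,
    equal every ``(metric_name, printed_value, decimals)`` constraint.
    An empty result signals that the printed values are mutually
    inconsistent at these margins (``consistent`` is False); multiple
    survivors mean the constraints underdetermine the matrix.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("both margins must be positive")
    cons = list(constraints)
    if not cons:
        raise ValueError("at least one constraint is required")
    parsed = []
    for name, value, decimals in cons:
        if name not in _METRIC_COUNTS:
            raise ValueError(f"unknown metric {name!r}")
        parsed.append((name, Decimal(str(value)), int(decimals)))
    hits = []
    for tp in range(n_pos + 1):
        for tn in range(n_neg + 1):
            cm = ConfusionMatrix(tp=tp, fp=n_neg - tn, fn=n_pos - tp, tn=tn)
            ok = True
            for name, target, decimals in parsed:
                got = _percent(*_METRIC_COUNTS[name](cm), decimals)
                if got is None or got != target.quantize(got):
                    ok = False
                    break
            if ok:
                hits.append(cm)
    return ReconstructionResult(tuple(hits), n_pos, n_neg)


def evaluate_scores(scores, labels) -> ROCSummary:
    """Full single-modality evaluation: AUC, both cut-offs, and the
    operating-point metrics at each."""
    yc = youden_optimal_cutoff(scores, labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateCutoffWarning)
        cc = clinical_cutoff_100npv(scores, labels)
    cm_y = confusion_at_cutoff(scores, labels, yc)
    cm_c = confusion_at_cutoff(scores, labels, cc)
    return ROCSummary(
        auc=auc(scores, labels),
        youden_cutoff=yc,
        clinical_cutoff_100npv=cc,
        metrics_at_youden=metrics(cm_y),
        metrics_at_clinical=metrics(cm_c),
        cm_at_youden=cm_y,
        cm_at_clinical=cm_c,
    )


def table_report(scores, labels, decimals: int = 2) -> dict:
    """Evaluation report as a JSON-ready dict keyed by the conventional
    ROC-table row names (percentages rounded half-up to ``decimals``)."""
    s = evaluate_scores(scores, labels)

    def pct(v: float) -> float:
        return float(round_half_up(100.0 * v, decimals)) if math.isfinite(v) else None

    my, mc = s.metrics_at_youden, s.metrics_at_clinical
    return {
        "AUC-ROC": float(round_half_up(s.auc, 3)),
        "Youden cut-off value of Kaiser score": s.youden_cutoff,
        "100% TN Kaiser score": s.clinical_cutoff_100npv,
        "Sensitivity at Youden cut-off": pct(my.sensitivity),
        "Specificity at Youden cut-off": pct(my.specificity),
        "Accuracy at Youden cut-off": pct(my.accuracy),
        "PPV at Youden cut-off": pct(my.ppv),
        "NPV at Youden cut-off": pct(my.npv),
        "Specificity at 100% NPV": pct(mc.specificity),
        "PPV at 100% NPV": pct(mc.ppv),
    }
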