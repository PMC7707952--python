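"""Diagnostic performance statistics.

Everything is computed with malignant as the positive class and from raw
counts, never from rounded percentages: the likelihood ratios and odds ratio
are exact functions of the confusion matrix, and display rounding (half-up,
two decimals) is applied only when formatting a report.

Included: the standard index panel (sensitivity, specificity, PPV, NPV, FPR,
FNR, overall accuracy, PLR, NLR, diagnostic odds ratio), a two-proportion
z-test, ROC curves with trapezoidal AUC, and DeLong variance for AUC
confidence intervals and paired AUC comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import stats as _stats
from sklearn import metrics as _skm

from .rbf import BENIGN, MALIGNANT

__all__ = [
    "ConfusionMatrix",
    "PerformanceReport",
    "ProportionComparison",
    "ROCCurve",
    "confusion",
    "performance_indices",
    "two_proportion_test",
    "roc_curve",
    "delong_auc_variance",
    "auc_ci",
    "auc_ci_and_compare",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Half-up rounding for display (so 82.505 → 82.51, not banker's 82.5)."""
    if not math.isfinite(x):
        return x
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 truth-vs-prediction counts; positive class = malignant."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


def confusion(truth: Sequence[str], predicted: Sequence[str]) -> ConfusionMatrix:
    """Tally a confusion matrix from aligned benign/malignant label sequences."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape or truth.size == 0:
        raise ValueError("truth and predicted must be non-empty and aligned")
    known = {BENIGN, MALIGNANT}
    bad = (set(np.unique(truth)) | set(np.unique(predicted))) - known
    if bad:
        raise ValueError(f"unknown label value(s): {sorted(bad)}")
    t_mal = truth == MALIGNANT
    p_mal = predicted == MALIGNANT
    return ConfusionMatrix(
        tp=int((t_mal & p_mal).sum()),
        fp=int((~t_mal & p_mal).sum()),
        tn=int((~t_mal & ~p_mal).sum()),
        fn=int((t_mal & ~p_mal).sum()),
    )


@dataclass(frozen=True)
class PerformanceReport:
    """Index panel in percent (proportions) and raw ratio units (PLR/NLR/OR).

    Undefined proportions (zero denominator) are NaN; ratios with a zero
    denominator are +inf.
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    fpr: float
    fnr: float
    oa: float
    plr: float
    nlr: float
    odds_ratio: float

    def as_dict(self, rounded: bool = False) -> dict[str, float]:
        d = {k: getattr(self, k) for k in (
            "sensitivity", "specificity", "ppv", "npv",
            "fpr", "fnr", "oa", "plr", "nlr", "odds_ratio")}
        if rounded:
            d = {k: round_half_up(v) for k, v in d.items()}
        return d


def _ratio(num: float, den: float) -> float:
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def performance_indices(cm: ConfusionMatrix) -> PerformanceReport:
    """All ten indices from exact counts.

    PLR = sens/(1−spec) and NLR = (1−sens)/spec are ratios of raw fractions;
    odds ratio = tp·tn/(fp·fn) = PLR/NLR.
    """
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    return PerformanceReport(
        sensitivity=100.0 * sens,
        specificity=100.0 * spec,
        ppv=100.0 * _ratio(cm.tp, cm.tp + cm.fp),
        npv=100.0 * _ratio(cm.tn, cm.tn + cm.fn),
        fpr=100.0 * (1.0 - spec),
        fnr=100.0 * (1.0 - sens),
        oa=100.0 * _ratio(cm.tp + cm.tn, cm.total),
        plr=_ratio(sens, 1.0 - spec),
        nlr=_ratio(1.0 - sens, spec),
        odds_ratio=_ratio(cm.tp * cm.tn, cm.fp * cm.fn),
    )


@dataclass(frozen=True)
class ProportionComparison:
    difference: float  # percentage points
    ci_low: float
    ci_high: float
    z: float
    p_value: float


def two_proportion_test(
    x1: int, n1: int, x2: int, n2: int,
    se_n1: int | None = None, se_n2: int | None = None,
) -> ProportionComparison:
    """Two-proportion z-test for p1 = x1/n1 vs p2 = x2/n2.

    The 95% CI uses the unpooled standard error (±1.96·SE); z and the
    two-sided p use the pooled standard error.  ``se_n1``/``se_n2`` override
    the sample sizes entering the standard errors only (the proportions keep
    n1/n2), which reproduces report styles that normalize the variance by the
    whole study size rather than the class-specific denominator.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("successes must lie in [0, n]")
    m1 = se_n1 if se_n1 is not None else n1
    m2 = se_n2 if se_n2 is not None else n2
    p1, p2 = x1 / n1, x2 / n2
    diff = p1 - p2
    se_un = math.sqrt(p1 * (1 - p1) / m1 + p2 * (1 - p2) / m2)
    pbar = (x1 + x2) / (n1 + n2)
    se_pool = math.sqrt(pbar * (1 - pbar) * (1 / m1 + 1 / m2))
    if se_pool == 0:
        z = 0.0 if diff == 0 else math.copysign(math.inf, diff)
    else:
        z = diff / se_pool
    p_value = 2.0 * _stats.norm.sf(abs(z)) if math.isfinite(z) else 0.0
    return ProportionComparison(
        difference=100.0 * diff,
        ci_low=100.0 * (diff - 1.96 * se_un),
        ci_high=100.0 * (diff + 1.96 * se_un),
        z=z,
        p_value=min(p_value, 1.0),
    )


@dataclass
class ROCCurve:
    """ROC points (fpr, tpr in [0,1]) and trapezoidal AUC in percent."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    auc_ci_low: float | None = None
    auc_ci_high: float | None = None


def _binary_truth(truth: Sequence[str]) -> np.ndarray:
    y = (np.asarray(truth) == MALIGNANT).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present for a ROC curve")
    return y


def roc_curve(scores: Sequence[float], truth: Sequence[str]) -> ROCCurve:
    """ROC by threshold sweep over unique scores (ties grouped), AUC by trapezoid."""
    y = _binary_truth(truth)
    fpr, tpr, thr = _skm.roc_curve(y, np.asarray(scores, dtype=float))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr,
                    auc=100.0 * float(_skm.auc(fpr, tpr)))


def _midrank(x: np.ndarray) -> np.ndarray:
    return _stats.rankdata(x, method="average")


def delong_auc_variance(
    score_sets: np.ndarray, truth: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """DeLong AUC estimates and covariance matrix for one or more score sets.

    ``score_sets`` is (n_classifiers, n_cases); AUCs are on the [0, 1] scale.
    Uses the midrank formulation (structural components of the Mann–Whitney
    statistic).
    """
    y = _binary_truth(truth)
    scores = np.atleast_2d(np.asarray(score_sets, dtype=float))
    pos = scores[:, y == 1]
    neg = scores[:, y == 0]
    m, n = pos.shape[1], neg.shape[1]
    k = scores.shape[0]
    aucs = np.empty(k)
    v_pos = np.empty((k, m))
    v_neg = np.empty((k, n))
    for r in range(k):
        all_ranks = _midrank(np.concatenate([pos[r], neg[r]]))
        pos_ranks = _midrank(pos[r])
        neg_ranks = _midrank(neg[r])
        aucs[r] = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v_pos[r] = (all_ranks[:m] - pos_ranks) / n
        v_neg[r] = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s_pos = np.cov(v_pos) if k > 1 else np.atleast_2d(np.var(v_pos[0], ddof=1))
    s_neg = np.cov(v_neg) if k > 1 else np.atleast_2d(np.var(v_neg[0], ddof=1))
    cov = np.atleast_2d(s_pos) / m + np.atleast_2d(s_neg) / n
    return aucs, cov


def auc_ci(scores: Sequence[float], truth: Sequence[str]) -> ROCCurve:
    """ROC curve with a DeLong 95% CI on the AUC, clipped to [0, 100]."""
    curve = roc_curve(scores, truth)
    aucs, cov = delong_auc_variance(np.asarray(scores, dtype=float)[None, :], truth)
    se = math.sqrt(max(cov[0, 0], 0.0))
    curve.auc_ci_low = float(np.clip(100.0 * (aucs[0] - 1.96 * se), 0.0, 100.0))
    curve.auc_ci_high = float(np.clip(100.0 * (aucs[0] + 1.96 * se), 0.0, 100.0))
    return curve


@dataclass(frozen=True)
class AUCComparison:
    auc_a: float
    ci_a: tuple[float, float]
    auc_b: float
    ci_b: tuple[float, float]
    difference: float
    z: float
    p_value: float


def auc_ci_and_compare(
    scores_a: Sequence[float], scores_b: Sequence[float], truth: Sequence[str]
) -> AUCComparison:
    """Paired DeLong comparison of two classifiers scored on the same cases."""
    scores = np.vstack([np.asarray(scores_a, float), np.asarray(scores_b, float)])
    aucs, cov = delong_auc_variance(scores, truth)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = aucs[0] - aucs[1]
    if var_diff <= 0:
        z = 0.0 if diff == 0 else math.copysign(math.inf, diff)
    else:
        z = diff / math.sqrt(var_diff)
    p = 1.0 if (z == 0.0) else (2.0 * _stats.norm.sf(abs(z)) if math.isfinite(z) else 0.0)
    ci = lambda i: (
        float(np.clip(100.0 * (aucs[i] - 1.96 * se[i]), 0.0, 100.0)),
        float(np.clip(100.0 * (aucs[i] + 1.96 * se[i]), 0.0, 100.0)),
    )
    return AUCComparison(
        auc_a=100.0 * aucs[0], ci_a=ci(0),
        auc_b=100.0 * aucs[1], ci_b=ci(1),
        difference=100.0 * diff, z=z, p_value=min(p, 1.0),
    )
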