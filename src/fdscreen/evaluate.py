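"""Cohort-level screening evaluation.

Given labeled risk factors, this module builds the confusion matrix at a
cut-off (predicted positive iff risk factor >= cut-off), derives accuracy,
precision, recall/sensitivity, specificity and F1, sweeps cut-offs, computes
ROC (trapezoidal area) and precision-recall (step-wise area) curves, the
case enrichment of the flagged group relative to population prevalence, and
Mann-Whitney / chi-squared / Fisher group comparisons of cohort
characteristics. Rates with a zero denominator are reported as NaN and
flagged undefined rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "EvaluationMetrics",
    "EnrichmentResult",
    "CohortEvaluation",
    "confusion_at_cutoff",
    "metrics",
    "sweep_cutoffs",
    "roc_pr_curves",
    "enrichment_ratio",
    "compare_cohort_characteristics",
    "evaluate_cohort",
]

CASE = "case"
CONTROL = "control"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion matrix cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class EvaluationMetrics:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    undefined: frozenset[str] = frozenset()

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "undefined": sorted(self.undefined),
        }


def _labels_to_bool(labels: Sequence) -> np.ndarray:
    out = np.empty(len(labels), dtype=bool)
    for i, lab in enumerate(labels):
        if lab is None or (isinstance(lab, float) and math.isnan(lab)):
            raise ValueError(f"missing true label at position {i}")
        if isinstance(lab, str):
            out[i] = lab == CASE
        else:
            out[i] = bool(lab)
    return out


def confusion_at_cutoff(
    scores: Sequence[float], labels: Sequence, cutoff: float
) -> ConfusionMatrix:
    """Confusion matrix with predicted positive iff score >= cutoff.

    ``labels`` may be booleans (True = case) or the strings
    ``"case"``/``"control"``. Missing labels raise.
    """
    if len(scores) != len(labels):
        raise ValueError("scores and labels must have equal length")
    y = _labels_to_bool(labels)
    s = np.asarray(scores, dtype=float)
    pred = s >= cutoff
    return ConfusionMatrix(
        tp=int(np.sum(pred & y)),
        fp=int(np.sum(pred & ~y)),
        tn=int(np.sum(~pred & ~y)),
        fn=int(np.sum(~pred & y)),
    )


def metrics(matrix: ConfusionMatrix) -> EvaluationMetrics:
    """Accuracy, precision, recall, specificity and F1 from a matrix.

    accuracy = (TP+TN)/(TP+TN+FP+FN); precision = TP/(TP+FP);
    recall = TP/(TP+FN); specificity = TN/(TN+FP);
    F1 = 2*precision*recall/(precision+recall).
    A metric whose denominator is zero is NaN and listed in ``undefined``.
    """
    tp, fp, tn, fn = matrix.tp, matrix.fp, matrix.tn, matrix.fn
    undefined: set[str] = set()

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.add(name)
            return math.nan
        return num / den

    accuracy = ratio(tp + tn, matrix.total, "accuracy")
    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    specificity = ratio(tn, tn + fp, "specificity")
    if "precision" in undefined or "recall" in undefined:
        undefined.add("f1")
        f1 = math.nan
    else:
        f1 = ratio(2 * precision * recall, precision + recall, "f1")
    return EvaluationMetrics(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
        undefined=frozenset(undefined),
    )


def sweep_cutoffs(
    scores: Sequence[float], labels: Sequence, cutoff_range: tuple[int, int]
) -> pd.DataFrame:
    """One row of counts and rates per integer cut-off in the inclusive range.

    Sensitivity is non-increasing and specificity non-decreasing in the
    cut-off (predicted positive iff score >= cut-off).
    """
    lo, hi = cutoff_range
    if hi < lo:
        raise ValueError("cutoff range must be non-empty")
    rows = []
    for cutoff in range(int(lo), int(hi) + 1):
        cm = confusion_at_cutoff(scores, labels, cutoff)
        m = metrics(cm)
        rows.append(
            {
                "cutoff": cutoff,
                "tp": cm.tp,
                "fp": cm.fp,
                "tn": cm.tn,
                "fn": cm.fn,
                "sensitivity": m.recall,
                "specificity": m.specificity,
                "precision": m.precision,
                "f1": m.f1,
            }
        )
    return pd.DataFrame(rows)


def roc_pr_curves(
    scores: Sequence[float], labels: Sequence
) -> tuple[list[tuple[float, float]], list[tuple[float, float]], float, float]:
    """ROC and precision-recall curves over all distinct score thresholds.

    Returns ``(roc_points, pr_points, auc_roc, auc_pr)`` where roc points are
    (FPR, TPR) pairs including the (0,0) and (1,1) endpoints, the ROC area is
    trapezoidal, and the PR area uses the step-wise precision-at-recall
    convention sum_i (R_i - R_{i-1}) * P_i. Raises on a single-class cohort.
    """
    y = _labels_to_bool(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute curves")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    # keep the last index of each tie group (one operating point per threshold)
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tpr = tps[distinct] / n_pos
    fpr = fps[distinct] / n_neg
    prec = tps[distinct] / (tps[distinct] + fps[distinct])
    roc_fpr = np.r_[0.0, fpr]
    roc_tpr = np.r_[0.0, tpr]
    auc_roc = float(np.trapezoid(roc_tpr, roc_fpr))
    recall_steps = np.r_[0.0, tpr]
    auc_pr = float(np.sum(np.diff(recall_steps) * prec))
    roc_points = list(zip(roc_fpr.tolist(), roc_tpr.tolist()))
    pr_points = [(0.0, 1.0)] + list(zip(tpr.tolist(), prec.tolist()))
    return roc_points, pr_points, auc_roc, auc_pr


@dataclass(frozen=True)
class EnrichmentResult:
    """Case:control ratio in the flagged group vs the population rate.

    ``ratio_k`` is the k of "1 case per k flagged controls"; ``fold`` is how
    many times that exceeds the 1-in-N population rate.
    """

    ratio_k: Optional[int]
    fold: Optional[float]
    flag: Optional[str] = None


def enrichment_ratio(matrix: ConfusionMatrix, population_rate: float = 40_000) -> EnrichmentResult:
    """Enrichment of true cases among flagged patients: k = round(FP/TP),
    fold = N/k for a 1-in-N population prevalence."""
    if matrix.tp == 0:
        return EnrichmentResult(ratio_k=None, fold=None, flag="undefined")
    k = round(matrix.fp / matrix.tp)
    if k == 0:
        return EnrichmentResult(ratio_k=0, fold=None, flag="all_true_positive")
    return EnrichmentResult(ratio_k=int(k), fold=population_rate / k)


def compare_cohort_characteristics(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    numeric: Sequence[str] = ("age",),
    categorical: Sequence[str] = (),
) -> pd.DataFrame:
    """Group comparison of cohort attributes.

    Numeric attributes are compared with the two-sided Mann-Whitney test;
    binary categorical attributes with the chi-squared test when every
    expected count is at least 5, and Fisher's exact test otherwise. An
    attribute with zero incidence in either group is reported untested.
    """
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for col in numeric:
        a = pd.to_numeric(cases[col]).to_numpy()
        b = pd.to_numeric(controls[col]).to_numpy()
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {"attribute": col, "test": "mann-whitney", "statistic": float(stat),
             "p_value": float(p), "tested": True, "note": ""}
        )
    for col in categorical:
        a_yes = int(cases[col].astype(bool).sum())
        b_yes = int(controls[col].astype(bool).sum())
        a_no = len(cases) - a_yes
        b_no = len(controls) - b_yes
        if a_yes == 0 or b_yes == 0:
            rows.append(
                {"attribute": col, "test": "", "statistic": math.nan,
                 "p_value": math.nan, "tested": False,
                 "note": "zero incidence in a group"}
            )
            continue
        table = np.array([[a_yes, a_no], [b_yes, b_no]])
        expected = stats.contingency.expected_freq(table)
        if (expected >= 5).all():
            stat, p, _, _ = stats.chi2_contingency(table)
            test_name = "chi-squared"
        else:
            stat, p = stats.fisher_exact(table)
            test_name = "fisher-exact"
        rows.append(
            {"attribute": col, "test": test_name, "statistic": float(stat),
             "p_value": float(p), "tested": True, "note": ""}
        )
    return pd.DataFrame(rows)


@dataclass
class CohortEvaluation:
    """Everything the screening evaluation produces at one cut-off."""

    cutoff: int
    matrix: ConfusionMatrix
    metrics: EvaluationMetrics
    sweep: pd.DataFrame
    roc_points: list[tuple[float, float]]
    pr_points: list[tuple[float, float]]
    auc_roc: float
    auc_pr: float
    enrichment: EnrichmentResult
    population_rate: float = 40_000

    def as_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "confusion_matrix": {
                "tp": self.matrix.tp, "fp": self.matrix.fp,
                "tn": self.matrix.tn, "fn": self.matrix.fn,
            },
            "metrics": self.metrics.as_dict(),
            "cutoff_sweep": self.sweep.to_dict(orient="records"),
            "roc_points": self.roc_points,
            "pr_points": self.pr_points,
            "auc_roc": self.auc_roc,
            "auc_pr": self.auc_pr,
            "enrichment": {
                "ratio_k": self.enrichment.ratio_k,
                "fold": self.enrichment.fold,
                "flag": self.enrichment.flag,
                "population_rate": self.population_rate,
            },
        }


def evaluate_cohort(
    scores: Sequence[float],
    labels: Sequence,
    cutoff: int = 4,
    sweep_range: tuple[int, int] = (3, 11),
    population_rate: float = 40_000,
) -> CohortEvaluation:
    """Full evaluation of a labeled, scored cohort at one cut-off."""
    cm = confusion_at_cutoff(scores, labels, cutoff)
    roc_points, pr_points, auc_roc, auc_pr = roc_pr_curves(scores, labels)
    return CohortEvaluation(
        cutoff=int(cutoff),
        matrix=cm,
        metrics=metrics(cm),
        sweep=sweep_cutoffs(scores, labels, sweep_range),
        roc_points=roc_points,
        pr_points=pr_points,
        auc_roc=auc_roc,
        auc_pr=auc_pr,
        enrichment=enrichment_ratio(cm, population_rate),
        population_rate=population_rate,
    )


def plot_score_distributions(scores, labels, path, bins=None):  # pragma: no cover
    """Optional histogram of risk-factor distributions per group (thin layer
    over matplotlib; requires the ``plots`` extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    y = _labels_to_bool(labels)
    s = np.asarray(scores, dtype=float)
    if bins is None:
        bins = np.arange(s.min(), s.max() + 2) - 0.5
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.hist(s[~y], bins=bins, alpha=0.6, label="controls", density=True)
    ax.hist(s[y], bins=bins, alpha=0.6, label="cases", density=True)
    ax.set_xlabel("risk factor")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
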