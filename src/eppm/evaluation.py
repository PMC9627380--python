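"""ROC analysis and threshold metrics for the EPPM score.

"Positive" throughout means poor early prognosis: a patient is predicted
poor when the score strictly exceeds the threshold. The ROC sweeps
thresholds at the midpoints between consecutive distinct scores, plus a
below-minimum sentinel (everyone positive: sensitivity 1, specificity 0)
and an above-maximum sentinel (nobody positive: sensitivity 0,
specificity 1), so the curve always spans both endpoints.

The AUC is the trapezoidal area of that curve, which for this threshold
family equals the tie-adjusted concordance probability: the chance a random
poor-outcome patient scores above a random good-outcome patient, ties
counted one half. Its 95% CI uses the Hanley–McNeil standard error with a
normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import Cohort
from .scoring import GradingRules, Threshold, classify, default_rules, score_patient

__all__ = [
    "ROCCurve",
    "ConfusionMetrics",
    "roc_curve",
    "youden_threshold",
    "confusion_metrics",
    "evaluate_model",
    "score_cohort",
]


@dataclass
class ROCCurve:
    """Thresholds with (sensitivity, specificity) pairs plus AUC and its CI.

    ``points`` is ordered by increasing threshold, so sensitivity is
    non-increasing and specificity non-decreasing along the list.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci95: tuple[float, float]
    n_poor: int
    n_good: int

    @property
    def points(self) -> list[tuple[float, float, float]]:
        return list(zip(self.thresholds.tolist(), self.sensitivity.tolist(), self.specificity.tolist()))


@dataclass
class ConfusionMetrics:
    """Confusion counts and derived rates at one threshold (positive = poor)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fp + self.tn + self.fn)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def _as_poor_mask(labels: Sequence[str]) -> np.ndarray:
    arr = np.asarray(labels)
    bad = set(arr.tolist()) - {"poor", "good"}
    if bad:
        raise ValueError(f"labels must be 'poor'/'good', got {sorted(bad)}")
    return arr == "poor"


def _hanley_mcneil_ci(auc: float, n_poor: int, n_good: int) -> tuple[float, float]:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_poor - 1) * (q1 - auc * auc)
        + (n_good - 1) * (q2 - auc * auc)
    ) / (n_poor * n_good)
    se = float(np.sqrt(max(var, 0.0)))
    return (max(0.0, auc - 1.959963984540054 * se), min(1.0, auc + 1.959963984540054 * se))


def roc_curve(scores: Sequence[float], labels: Sequence[str]) -> ROCCurve:
    """ROC of a score as a classifier of poor prognosis.

    Raises ``ValueError`` when only one class is present (the ROC is then
    undefined).
    """
    scores = np.asarray(scores, dtype=float)
    poor = _as_poor_mask(labels)
    if scores.shape[0] != poor.shape[0]:
        raise ValueError("scores and labels differ in length")
    n_poor = int(poor.sum())
    n_good = int((~poor).sum())
    if n_poor == 0 or n_good == 0:
        raise ValueError("ROC undefined: both outcome classes must be present")

    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([distinct[0] - 0.5], mids, [distinct[-1] + 0.5]))

    # predicted poor iff score > threshold
    pred = scores[None, :] > thresholds[:, None]
    sens = (pred & poor[None, :]).sum(axis=1) / n_poor
    spec = ((~pred) & (~poor)[None, :]).sum(axis=1) / n_good

    # trapezoid over the (FPR, TPR) polyline; thresholds ascend so FPR descends
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    return ROCCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_ci95=_hanley_mcneil_ci(auc, n_poor, n_good),
        n_poor=n_poor,
        n_good=n_good,
    )


def youden_threshold(curve: ROCCurve) -> Threshold:
    """Threshold maximizing the Youden index J = sensitivity + specificity − 1.

    Ties are broken toward higher specificity, then toward the higher
    threshold.
    """
    j = curve.sensitivity + curve.specificity - 1.0
    best = 0
    for i in range(1, len(curve.thresholds)):
        key = (j[i], curve.specificity[i], curve.thresholds[i])
        if key >= (j[best], curve.specificity[best], curve.thresholds[best]):
            best = i
    return Threshold(value=float(curve.thresholds[best]))


def confusion_metrics(
    scores: Sequence[float],
    labels: Sequence[str],
    threshold: Threshold | float,
) -> ConfusionMetrics:
    """Confusion counts of the score-threshold classifier against the labels."""
    scores = np.asarray(scores, dtype=float)
    poor = _as_poor_mask(labels)
    if scores.shape[0] != poor.shape[0]:
        raise ValueError("scores and labels differ in length")
    if scores.shape[0] == 0:
        raise ValueError("empty input")
    cut = threshold.value if isinstance(threshold, Threshold) else float(threshold)
    pred = scores > cut
    return ConfusionMetrics(
        tp=int((pred & poor).sum()),
        fp=int((pred & ~poor).sum()),
        tn=int((~pred & ~poor).sum()),
        fn=int((~pred & poor).sum()),
    )


def score_cohort(
    cohort: Cohort,
    rules: GradingRules | None = None,
    threshold: Threshold | float = Threshold(),
    predictors: Sequence[str] | None = None,
):
    """Score every record; returns a DataFrame with per-predictor points,
    the total, and the predicted outcome."""
    import pandas as pd

    rules = rules if rules is not None else default_rules()
    names = tuple(predictors) if predictors is not None else rules.predictors
    rows = []
    for rec in cohort:
        bd = score_patient(rec, rules, names)
        row: dict[str, object] = {"patient_id": rec.patient_id}
        row.update({f"points_{k}": v for k, v in bd.points.items()})
        row["total"] = bd.total
        row["predicted_outcome"] = classify(bd.total, threshold)
        if rec.outcome is not None:
            row["outcome"] = rec.outcome
        rows.append(row)
    return pd.DataFrame(rows)


def _evaluate_set(cohort: Cohort, rules: GradingRules, threshold: Threshold) -> dict:
    scores = []
    labels = []
    for rec in cohort:
        if rec.outcome is None:
            raise ValueError(f"record {rec.patient_id} lacks an outcome label")
        scores.append(score_patient(rec, rules).total)
        labels.append(rec.outcome)
    curve = roc_curve(scores, labels)
    cm = confusion_metrics(scores, labels, threshold)
    return {
        "set_label": cohort.label,
        "n": len(cohort),
        "n_poor": curve.n_poor,
        "n_good": curve.n_good,
        "auc": curve.auc,
        "auc_ci95": list(curve.auc_ci95),
        "threshold": threshold.value,
        "metrics": cm.as_dict(),
        "roc": {
            "thresholds": curve.thresholds.tolist(),
            "sensitivity": curve.sensitivity.tolist(),
            "specificity": curve.specificity.tolist(),
        },
    }


def evaluate_model(
    train: Cohort,
    validation: Cohort,
    testing: Cohort,
    rules: GradingRules | None = None,
    threshold: Threshold | float = Threshold(),
) -> dict:
    """Evaluate the EPPM on the training/validation/testing sets.

    The decision threshold is fixed from the caller (it is chosen on the
    training data and then frozen; validation and testing metrics never
    re-optimize it on their own labels). The report also records the
    Youden-optimal threshold of the training ROC for reference.
    """
    rules = rules if rules is not None else default_rules()
    thr = threshold if isinstance(threshold, Threshold) else Threshold(float(threshold))
    thr.validate_for(rules)
    report = {
        "threshold": thr.value,
        "sets": {
            name: _evaluate_set(cohort, rules, thr)
            for name, cohort in (("train", train), ("validation", validation), ("testing", testing))
        },
    }
    train_curve = ROCCurve(
        thresholds=np.asarray(report["sets"]["train"]["roc"]["thresholds"]),
        sensitivity=np.asarray(report["sets"]["train"]["roc"]["sensitivity"]),
        specificity=np.asarray(report["sets"]["train"]["roc"]["specificity"]),
        auc=report["sets"]["train"]["auc"],
        auc_ci95=tuple(report["sets"]["train"]["auc_ci95"]),
        n_poor=report["sets"]["train"]["n_poor"],
        n_good=report["sets"]["train"]["n_good"],
    )
    report["train_youden_threshold"] = youden_threshold(train_curve).value
    return report


def plot_roc(report: dict, path) -> None:
    """Plot the ROC curves of an :func:`evaluate_model` report to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, entry in report["sets"].items():
        fpr = 1.0 - np.asarray(entry["roc"]["specificity"])
        tpr = np.asarray(entry["roc"]["sensitivity"])
        order = np.argsort(fpr)
        ax.plot(fpr[order], tpr[order], label=f"{name} (AUC {entry['auc']:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
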