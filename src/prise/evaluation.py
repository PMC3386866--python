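"""Scoring predictions against interface labels.

Confusion-table metrics (precision, recall, F1, accuracy, Matthews
correlation), a precision–recall curve with one point per distinct
score (a residue is called interface when its score reaches the
threshold), and ROC AUC.  Residues for which the predictor had no
samples are scored as negative predictions with score 0, so the
predictor answers for every surface residue; their count is reported.

Undefined ratios (zero denominators) are reported as ``None`` / "NA",
never silently as 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass
class EvaluationReport:
    """Confusion counts, derived metrics, and optional curves."""

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float | None
    recall: float | None
    f1: float | None
    accuracy: float | None
    cc: float | None
    auc_roc: float | None = None
    pr_curve: list[tuple[float, float | None, float]] = field(
        default_factory=list)
    n_no_samples: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_json(self) -> str:
        payload = {
            "TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn,
            "precision": self.precision, "recall": self.recall,
            "F1": self.f1, "accuracy": self.accuracy, "CC": self.cc,
            "auc_roc": self.auc_roc, "n_no_samples": self.n_no_samples,
        }
        return json.dumps(payload, indent=1)


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def confusion_metrics(predicted: list[bool], labels: list[bool],
                      n_no_samples: int = 0) -> EvaluationReport:
    """Metrics from binary predictions and true labels.

    precision = TP/(TP+FP);  recall = TP/(TP+FN);
    F1 = 2·precision·recall/(precision+recall);
    accuracy = (TP+TN)/N;
    CC = (TP·TN − FP·FN)/√((TP+FN)(TP+FP)(TN+FP)(TN+FN)).
    """
    if len(predicted) != len(labels):
        raise ValueError("predictions and labels differ in length")
    if not labels:
        raise ValueError("cannot evaluate an empty input")
    tp = sum(1 for p, t in zip(predicted, labels) if p and t)
    fp = sum(1 for p, t in zip(predicted, labels) if p and not t)
    fn = sum(1 for p, t in zip(predicted, labels) if not p and t)
    tn = sum(1 for p, t in zip(predicted, labels) if not p and not t)
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    accuracy = _ratio(tp + tn, tp + fp + fn + tn)
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    cc = None if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return EvaluationReport(tp=tp, fp=fp, fn=fn, tn=tn, precision=precision,
                            recall=recall, f1=f1, accuracy=accuracy, cc=cc,
                            n_no_samples=n_no_samples)


def _check_degenerate(labels) -> np.ndarray:
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("labels must contain at least one positive and one "
                         "negative")
    return y


def pr_curve(scores, labels) -> list[tuple[float, float | None, float]]:
    """Precision–recall points, one per distinct score value.

    At threshold t (each distinct score), a residue is predicted
    interface iff its score ≥ t.  Recall is non-increasing as the
    threshold rises.
    """
    y = _check_degenerate(labels)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    points = []
    for t in sorted(set(s.tolist()), reverse=True):
        pred = s >= t
        tp = int((pred & y).sum())
        fp = int((pred & ~y).sum())
        fn = int((~pred & y).sum())
        points.append((float(t), _ratio(tp, tp + fp), tp / (tp + fn)))
    return points


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (ties contribute 1/2)."""
    y = _check_degenerate(labels)
    return float(roc_auc_score(y.astype(int), np.asarray(scores, float)))


def curves_to_csv(points, header: str) -> str:
    """Serialize curve points as CSV text."""
    lines = [header]
    for row in points:
        lines.append(",".join("NA" if v is None else f"{v:.6f}" for v in row))
    return "\n".join(lines) + "\n"


def evaluate_predictions(predictions, truth: dict, threshold_applied=True,
                         with_curves: bool = True) -> EvaluationReport:
    """Score a list of :class:`~prise.prediction.ResiduePrediction`.

    ``truth`` maps residue keys to boolean interface labels.  Residues
    flagged ``no_samples`` count as negative predictions with score 0.
    """
    predicted, labels, scores = [], [], []
    n_no_samples = 0
    for p in predictions:
        if p.key not in truth:
            raise KeyError(f"no truth label for residue {p.key}")
        labels.append(bool(truth[p.key]))
        if p.probability is None:
            n_no_samples += 1
            predicted.append(False)
            scores.append(0.0)
        else:
            predicted.append(bool(p.label))
            scores.append(float(p.probability))
    report = confusion_metrics(predicted, labels, n_no_samples=n_no_samples)
    if with_curves:
        y = np.asarray(labels, dtype=bool)
        if y.any() and not y.all():
            report.auc_roc = roc_auc(scores, labels)
            report.pr_curve = pr_curve(scores, labels)
    return report
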