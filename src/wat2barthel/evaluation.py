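"""Scoring: regression errors, dependence classes, classification reports.

The Barthel Index is predicted as a continuous value and only then mapped to
its dependence class — A (total dependence, BI <= 20), B (severe,
20 < BI <= 60), C (moderate/mild dependence or independent, BI > 60) — so
the class report reflects the regression's clinically meaningful errors.
The median absolute error (MAD) is the headline regression metric: wrist
step counts are noisy and cohorts small, so a robust location of the error
distribution is more trustworthy than mean-based metrics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

CLASS_LABELS = ("A", "B", "C")


def regression_metrics(y_true, y_pred) -> dict[str, float]:
    """MAE, MAD (median absolute error), RMSE and R^2 of the predictions."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise ValueError("cannot score an empty prediction set")
    err = y_true - y_pred
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    ss_res = float(np.sum(err**2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return {
        "mae": float(np.mean(np.abs(err))),
        "mad": float(np.median(np.abs(err))),
        "rmse": float(np.sqrt(np.mean(err**2))),
        "r2": r2,
    }


def bi_to_class(bi) -> np.ndarray | str:
    """Map BI value(s) to dependence class: A if <= 20, B if <= 60, else C.

    Applied identically to true and (possibly non-integer) predicted values.
    """
    arr = np.asarray(bi, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("BI values must be finite")
    out = np.where(arr <= 20, "A", np.where(arr <= 60, "B", "C"))
    if np.isscalar(bi) or arr.ndim == 0:
        return str(out)
    return out


@dataclass
class EvalReport:
    """Regression and classification quality for one dataset role."""

    mae: float
    mad: float
    rmse: float
    r2: float
    accuracy: float
    per_class: dict[str, dict[str, float]]  # label -> precision/recall/f1/support
    confusion: np.ndarray  # 3x3 counts, rows = true, cols = predicted
    n: int
    role: str = "validation"

    def to_dict(self) -> dict:
        return {
            "role": self.role,
            "n": self.n,
            "mae": self.mae,
            "mad": self.mad,
            "rmse": self.rmse,
            "r2": self.r2,
            "accuracy": self.accuracy,
            "accuracy_percent": round(100 * self.accuracy),
            "per_class": self.per_class,
            "confusion": np.asarray(self.confusion).tolist(),
            "confusion_labels": list(CLASS_LABELS),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        """Plain-text table: error block plus a per-class block."""
        lines = [
            f"=== {self.role} set (n={self.n}) ===",
            f"Accuracy  {round(100 * self.accuracy)}%",
            f"MAE       {self.mae:.2f}",
            f"MAD       {self.mad:.2f}",
            f"RMSE      {self.rmse:.2f}",
            "",
            "class  precision  recall  f1  support",
        ]
        for c in CLASS_LABELS:
            m = self.per_class[c]
            lines.append(
                f"{c}      {m['precision']:.2f}       {m['recall']:.2f}    "
                f"{m['f1']:.2f}  {int(m['support'])}"
            )
        lines.append("")
        lines.append("confusion (rows=true, cols=predicted, order A,B,C):")
        for r, row in enumerate(np.asarray(self.confusion)):
            lines.append(f"  {CLASS_LABELS[r]}  " + "  ".join(f"{int(v):3d}" for v in row))
        return "\n".join(lines)


def classification_report(
    y_true_labels, y_pred_labels
) -> tuple[dict[str, dict[str, float]], float, np.ndarray]:
    """Per-class precision/recall/F1, accuracy and the 3x3 confusion matrix.

    Undefined ratios (an empty denominator, e.g. a class never predicted)
    are reported as 0.0 with a warning rather than NaN, so classes with
    negligible support still appear in the report.
    """
    t = np.asarray(y_true_labels, dtype=str)
    p = np.asarray(y_pred_labels, dtype=str)
    if t.size == 0:
        raise ValueError("cannot build a classification report from empty inputs")
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    bad = set(np.unique(np.concatenate([t, p]))) - set(CLASS_LABELS)
    if bad:
        raise ValueError(f"labels outside {CLASS_LABELS}: {sorted(bad)}")

    k = len(CLASS_LABELS)
    index = {c: i for i, c in enumerate(CLASS_LABELS)}
    confusion = np.zeros((k, k), dtype=int)
    for ti, pi in zip(t, p):
        confusion[index[ti], index[pi]] += 1

    per_class: dict[str, dict[str, float]] = {}
    for c in CLASS_LABELS:
        i = index[c]
        tp = confusion[i, i]
        predicted = confusion[:, i].sum()
        actual = confusion[i, :].sum()
        if predicted == 0 and actual > 0:
            warnings.warn(f"class {c}: never predicted; precision reported as 0.00")
        precision = tp / predicted if predicted else 0.0
        recall = tp / actual if actual else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if (precision + recall) > 0
            else 0.0
        )
        per_class[c] = {
            "precision": float(precision),
            "recall": float(recall),
            "f1": float(f1),
            "support": int(actual),
        }
    accuracy = float(np.trace(confusion) / confusion.sum())
    return per_class, accuracy, confusion


def evaluate_predictions(
    y_true, y_pred, role: str = "validation"
) -> EvalReport:
    """Full report: regression metrics plus class metrics after conversion."""
    reg = regression_metrics(y_true, y_pred)
    true_labels = bi_to_class(np.asarray(y_true, dtype=float))
    pred_labels = bi_to_class(np.asarray(y_pred, dtype=float))
    per_class, accuracy, confusion = classification_report(true_labels, pred_labels)
    return EvalReport(
        mae=reg["mae"],
        mad=reg["mad"],
        rmse=reg["rmse"],
        r2=reg["r2"],
        accuracy=accuracy,
        per_class=per_class,
        confusion=confusion,
        n=int(np.asarray(y_true).size),
        role=role,
    )


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision < 0 or recall < 0:
        raise ValueError("precision and recall must be nonnegative")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
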