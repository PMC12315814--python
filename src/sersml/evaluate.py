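"""Dataset splitting and classification metrics.

The split is a seeded shuffle of the pooled set (non-stratified): sizes are
``round(n * fraction)`` for train and validation, with the test set absorbing
the rounding remainder.  Metrics: confusion matrix (rows = true class),
per-class recall/precision in percent, overall accuracy, per-class ROC/AUC.
Reported percentages are rounded half-up to one decimal; raw fractions are
kept alongside so rounding never feeds downstream computation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

from .exceptions import ConfigurationError, InputError, LabelError
from .io import SpectrumSet


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (97.55 -> 97.6)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def split_dataset(
    spectra: SpectrumSet,
    fractions: tuple[float, float, float] = (0.6, 0.1, 0.3),
    seed: int = 0,
    stratified: bool = False,
) -> tuple[SpectrumSet, SpectrumSet, SpectrumSet]:
    """Seeded random train/validation/test partition of the pooled set.

    Non-stratified by default (the whole pool is shuffled, not each class);
    ``stratified=True`` splits each class separately for robustness
    experiments.
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ConfigurationError("fractions must be three positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError("fractions must sum to 1 within 1e-9")
    n = spectra.n_samples
    if n < 10:
        raise ConfigurationError("need at least 10 samples to split")

    def _partition(indices: np.ndarray, rng: np.random.Generator):
        shuffled = rng.permutation(indices)
        m = shuffled.size
        n_train = int(round(fractions[0] * m))
        n_val = int(round(fractions[1] * m))
        return (
            shuffled[:n_train],
            shuffled[n_train : n_train + n_val],
            shuffled[n_train + n_val :],
        )

    rng = np.random.default_rng(seed)
    if stratified:
        parts = ([], [], [])
        labels = spectra.labels.astype(str)
        for cls in sorted(np.unique(labels)):
            for bucket, chunk in zip(parts, _partition(np.flatnonzero(labels == cls), rng)):
                bucket.append(chunk)
        train_idx, val_idx, test_idx = (np.concatenate(p) for p in parts)
    else:
        train_idx, val_idx, test_idx = _partition(np.arange(n), rng)
    if min(train_idx.size, val_idx.size, test_idx.size) == 0:
        raise ConfigurationError("a split received 0 samples; adjust fractions or n")
    return spectra.subset(train_idx), spectra.subset(val_idx), spectra.subset(test_idx)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    class_order: list[str]
    confusion: np.ndarray                      # (d, d) counts, rows = true
    recall_pct: list[float | None]             # rounded, one decimal
    precision_pct: list[float | None]
    overall_pct: float
    recall_raw: list[float | None] = field(default_factory=list)
    precision_raw: list[float | None] = field(default_factory=list)
    overall_raw: float = 0.0
    roc: dict[str, list[list[float]]] = field(default_factory=dict)   # class -> [[fpr], [tpr]]
    auc: dict[str, float] = field(default_factory=dict)
    cv_loss: float | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        data = {
            "class_order": self.class_order,
            "confusion": self.confusion.tolist(),
            "recall_pct": self.recall_pct,
            "precision_pct": self.precision_pct,
            "overall_pct": self.overall_pct,
            "recall_raw": self.recall_raw,
            "precision_raw": self.precision_raw,
            "overall_raw": self.overall_raw,
            "roc": self.roc,
            "auc": self.auc,
            "cv_loss": self.cv_loss,
        }
        text = json.dumps(data, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "EvaluationReport":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = json.loads(text)
        data["confusion"] = np.asarray(data["confusion"], dtype=int)
        return cls(**data)


def evaluate(
    y_true: np.ndarray, y_pred: np.ndarray, class_order: list[str]
) -> EvaluationReport:
    """Confusion matrix, per-class recall/precision (%), overall accuracy (%).

    A class absent from ``y_true`` gets recall ``None`` (undefined, not 0);
    likewise precision for a class never predicted.
    """
    y_true = np.asarray(y_true).astype(str)
    y_pred = np.asarray(y_pred).astype(str)
    if y_true.size != y_pred.size:
        raise InputError("y_true and y_pred lengths differ")
    unknown = set(y_true) | set(y_pred)
    if not unknown <= set(class_order):
        raise LabelError(f"labels {sorted(unknown - set(class_order))} not in class_order")
    cm = _sk_confusion(y_true, y_pred, labels=class_order)
    row_sums = cm.sum(axis=1)
    col_sums = cm.sum(axis=0)
    recall_raw = [
        cm[i, i] / row_sums[i] if row_sums[i] > 0 else None
        for i in range(len(class_order))
    ]
    precision_raw = [
        cm[i, i] / col_sums[i] if col_sums[i] > 0 else None
        for i in range(len(class_order))
    ]
    overall_raw = float(np.trace(cm) / y_true.size)
    return EvaluationReport(
        class_order=list(class_order),
        confusion=cm,
        recall_pct=[None if r is None else round_half_up(100 * r) for r in recall_raw],
        precision_pct=[None if p is None else round_half_up(100 * p) for p in precision_raw],
        overall_pct=round_half_up(100 * overall_raw),
        recall_raw=recall_raw,
        precision_raw=precision_raw,
        overall_raw=overall_raw,
    )


def roc_auc(scores: np.ndarray, y_true: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC over all score thresholds and trapezoidal AUC for binary labels.

    ``y_true`` must be boolean/0-1 (1 = positive).  The AUC equals the
    probability that a random positive outscores a random negative, ties
    counting one half.
    """
    scores = np.asarray(scores, float)
    y = np.asarray(y_true).astype(int)
    if not np.all(np.isfinite(scores)):
        raise InputError("scores must be finite")
    if len(np.unique(y)) < 2:
        raise LabelError("both classes must be present for ROC")
    fpr, tpr, _ = _sk_roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def attach_roc(
    report: EvaluationReport,
    scores: np.ndarray,
    y_true: np.ndarray,
    class_order: list[str] | None = None,
) -> EvaluationReport:
    """Add one-vs-rest ROC/AUC per class.

    ``scores`` is (n, d) — one column of class scores per class in
    ``class_order`` — or a 1-D vector for binary problems (score of the
    second class)."""
    class_order = class_order or report.class_order
    y_true = np.asarray(y_true).astype(str)
    scores = np.asarray(scores, float)
    if scores.ndim == 1:
        if len(class_order) != 2:
            raise InputError("1-D scores only valid for binary problems")
        scores = np.column_stack([-scores, scores])
    for j, cls in enumerate(class_order):
        y_bin = (y_true == cls).astype(int)
        if len(np.unique(y_bin)) < 2:
            continue
        points, auc = roc_auc(scores[:, j], y_bin)
        report.roc[cls] = [points[:, 0].tolist(), points[:, 1].tolist()]
        report.auc[cls] = auc
    return report
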