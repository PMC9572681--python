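"""Confusion matrices and classification metrics: CCR, sensitivity, specificity, precision.

All per-class metrics collapse the K-class problem one-vs-rest: for class k,
TP are class-k samples predicted k, FN class-k samples predicted otherwise,
FP other samples predicted k, TN the rest.  The overall correct
classification rate (CCR) is 100 * trace / total; a class's CCR equals its
sensitivity times 100.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sklearn.decomposition import PCA

from .classifiers import (
    ClassifierModel,
    venetian_folds,
    _plsda_train,
    _plsda_responses,
    _assign,
    _lda_equal_priors,
    plsda_predict,
    pcada_predict,
)
from .spectra import SpectrumTable

__all__ = ["ConfusionReport", "confusion", "evaluate_splits", "round_reported"]


def round_reported(value: float, decimals: int) -> float:
    """Round a metric for table display.

    Uses Python's correctly-rounded float rounding (not numpy's
    scale-and-rint, which can flip ties-adjacent values like 0.955 stored as
    0.95499...).
    """
    if not np.isfinite(value):
        return value
    return round(float(value), decimals)


@dataclass
class ConfusionReport:
    """K x K confusion counts (rows = actual, cols = predicted) with per-class metrics.

    ``per_class`` keeps unrounded ratios; :meth:`formatted` renders the
    table-style view with percentages to 1 decimal and ratios to 2 decimals.
    Precision is NaN (with a note) for a class that is never predicted.
    """

    counts: np.ndarray
    classes: np.ndarray
    per_class: pd.DataFrame
    overall_ccr: float
    notes: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def formatted(self) -> pd.DataFrame:
        df = self.per_class.copy()
        df["ccr_pct"] = df["ccr_pct"].map(lambda v: round_reported(v, 1))
        for col in ("sensitivity", "specificity", "precision"):
            df[col] = df[col].map(lambda v: round_reported(v, 2))
        return df

    def to_text(self) -> str:
        """Pretty-print mirroring the usual confusion-matrix table layout."""
        labels = [f"S{c}" for c in self.classes]
        counts = pd.DataFrame(self.counts, index=labels, columns=labels)
        block = pd.concat([counts, self.formatted().set_index(pd.Index(labels))], axis=1)
        lines = [block.to_string(), f"overall CCR: {round_reported(self.overall_ccr, 1)}%"]
        lines.extend(self.notes)
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "counts": self.counts.tolist(),
                "classes": self.classes.tolist(),
                "per_class": self.per_class.to_dict(orient="list"),
                "overall_ccr": self.overall_ccr,
                "notes": self.notes,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def confusion(actual: np.ndarray, predicted: np.ndarray, n_classes: int = 5) -> ConfusionReport:
    """Confusion report from label vectors (labels in 1..n_classes)."""
    actual = np.asarray(actual, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted label vectors differ in length")
    for name, arr in (("actual", actual), ("predicted", predicted)):
        if arr.size and (arr.min() < 1 or arr.max() > n_classes):
            raise ValueError(f"{name} labels outside 1..{n_classes}")
    classes = np.arange(1, n_classes + 1)
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (actual - 1, predicted - 1), 1)
    return confusion_from_counts(counts, classes)


def confusion_from_counts(counts: np.ndarray, classes: np.ndarray | None = None) -> ConfusionReport:
    """Confusion report directly from a printed/stored K x K count matrix."""
    counts = np.asarray(counts, dtype=int)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("counts must be a square matrix")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    K = counts.shape[0]
    if classes is None:
        classes = np.arange(1, K + 1)
    total = counts.sum()
    notes: list[str] = []
    rows = []
    for k in range(K):
        tp = counts[k, k]
        fn = counts[k].sum() - tp
        fp = counts[:, k].sum() - tp
        tn = total - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        if tp + fp:
            prec = tp / (tp + fp)
        else:
            prec = np.nan
            notes.append(f"precision undefined for class {classes[k]}: never predicted")
        rows.append(
            {
                "class": classes[k],
                "ccr_pct": 100.0 * sens if np.isfinite(sens) else np.nan,
                "sensitivity": sens,
                "specificity": spec,
                "precision": prec,
            }
        )
    overall = 100.0 * np.trace(counts) / total if total else np.nan
    return ConfusionReport(
        counts=counts,
        classes=np.asarray(classes),
        per_class=pd.DataFrame(rows),
        overall_ccr=float(overall),
        notes=notes,
    )


def evaluate_splits(model: ClassifierModel, table: SpectrumTable) -> dict[str, ConfusionReport]:
    """Calibration (resubstitution), cross-validation, and prediction reports.

    The CV report re-runs the model's venetian-blinds folds at its chosen
    dimension, so every calibration sample is predicted exactly once by a
    submodel that did not see it.  The prediction report uses held-out rows
    only; an empty prediction split is an error rather than a silent
    omission.
    """
    if table.split is None:
        raise ValueError("table carries no split flags; call assign_split first")
    cal, pred = table.calibration(), table.prediction()
    if pred.n_samples == 0:
        raise ValueError("prediction split is empty")
    n_classes = int(table.y.max())
    reports: dict[str, ConfusionReport] = {}

    def _predict(m: ClassifierModel, X: np.ndarray) -> np.ndarray:
        return plsda_predict(m, X)[0] if m.method == "plsda" else pcada_predict(m, X)

    reports["calibration"] = confusion(cal.y, _predict(model, cal.X), n_classes)
    cv_folds = int(model.meta.get("cv_folds", 10))
    cv_pred = np.zeros(cal.n_samples, dtype=int)
    for fold in venetian_folds(cal.n_samples, cv_folds):
        train = np.setdiff1d(np.arange(cal.n_samples), fold)
        sub = cal.subset(train)
        if model.method == "plsda":
            B, b0 = _plsda_train(sub.X, sub.y, model.classes, model.n_components)
            scores = _plsda_responses(cal.X[fold], B, b0, model.n_components)
            cv_pred[fold] = _assign(scores, model.classes)
        else:
            p = min(model.n_components, sub.n_samples - 1, sub.n_bands)
            pca = PCA(n_components=p, svd_solver="full").fit(sub.X)
            lda = _lda_equal_priors(pca.transform(sub.X), sub.y, model.classes)
            cv_pred[fold] = lda.predict(pca.transform(cal.X[fold]))
    reports["cross_validation"] = confusion(cal.y, cv_pred, n_classes)
    reports["prediction"] = confusion(pred.y, _predict(model, pred.X), n_classes)
    return reports
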